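"""End-to-end pipeline: reads/proteomes manifest -> distance matrix -> tree.

The stages mirror the method's framework: optional 3'-trimming, random
down-sampling of every sample to the smallest read count, external
assembly/gene-calling hooks (declared, never bundled), protein filtering,
coverage-weighted distance matrix, neighbor-joining tree, and the optional
environment-ranking and gene-trace analyses. The pipeline is fully runnable
without external tools by listing proteome FASTA files directly in the
manifest; per-stage counts and parameters go to a JSON run log, and all
randomness flows from one seed, so a rerun writes byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

from . import envcompare, genetrace, phylo, seqio, similarity
from .errors import MpassError, UserInputError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_len: int = 100
    require_complete: bool = True
    trim_to: int | None = None  # e.g. 200 to emulate fixed-length trimming
    downsample: bool = True
    seed: int = 0
    dialect: str = "native"
    const1: float = similarity.DEFAULT_CONST1
    const2: float = similarity.DEFAULT_CONST2
    linkage: str = "average"
    top_n: int = 1000
    r_cutoff: float = 0.7
    assembly_hook: str | None = None  # command template: {reads} {out}
    scoring: dict = field(default_factory=dict)

    def distance_params(self) -> similarity.DistanceParams:
        return similarity.DistanceParams(const1=self.const1, const2=self.const2)

    def scoring_scheme(self) -> similarity.ScoringScheme:
        return similarity.ScoringScheme(**self.scoring)


def run_pipeline(
    manifest: "list[dict] | str | Path",
    outdir: str | Path,
    config: PipelineConfig | None = None,
    env_table: str | Path | None = None,
    genetrace_focal: str | None = None,
) -> dict:
    """Run the full pipeline over a sample manifest.

    ``manifest`` is a list of ``{"sample": label, "proteome": path}`` or
    ``{"sample": label, "reads": path}`` entries (or a path to a JSON file
    with such a list). Reads-based samples require ``config.assembly_hook``.
    Writes ``dist.phy``, ``dist.tsv``, ``tree.nwk`` and ``run_log.json``
    into ``outdir``; returns the run log as a dict.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = _load_manifest(manifest)
    log: dict = {"config": {k: v for k, v in vars(config).items()}, "samples": {}, "stages": {}}

    read_sets = {}
    for e in entries:
        if "reads" in e:
            read_sets[e["sample"]] = seqio.read_fastq(e["reads"], sample_id=e["sample"])

    if read_sets:
        if config.trim_to:
            read_sets = {
                s: seqio.trim_reads(rs, config.trim_to) for s, rs in read_sets.items()
            }
            log["stages"]["trim"] = {"trim_to": config.trim_to}
        if config.downsample:
            n_min = min(len(rs) for rs in read_sets.values())
            read_sets = {
                s: seqio.downsample_reads(rs, n_min, config.seed + i)
                for i, (s, rs) in enumerate(sorted(read_sets.items()))
            }
            log["stages"]["downsample"] = {"n_reads": n_min}

    proteomes = []
    for e in entries:
        sample = e["sample"]
        if "proteome" in e:
            p = seqio.read_fasta(e["proteome"], sample_id=sample, dialect=config.dialect)
        elif "reads" in e:
            p = _assemble_and_call(read_sets[sample], outdir, config)
        else:
            raise UserInputError(
                f"sample {sample!r}: manifest entry has neither 'proteome' nor 'reads'"
            )
        filtered, report = seqio.filter_proteome(
            p, min_len=config.min_len, require_complete=config.require_complete
        )
        log["samples"][sample] = {
            "input_proteins": len(p),
            "kept": report.kept,
            "removed_short": report.removed_short,
            "removed_partial": report.removed_partial,
        }
        if len(filtered) == 0:
            raise UserInputError(f"sample {sample!r}: no proteins left after filtering")
        proteomes.append(filtered)

    dm, pair_log = similarity.build_distance_matrix(
        proteomes, scoring=config.scoring_scheme(), params=config.distance_params()
    )
    similarity.write_phylip(dm, outdir / "dist.phy")
    similarity.write_tsv(dm, outdir / "dist.tsv")
    log["stages"]["distance"] = pair_log.to_dict(orient="records")

    tree = phylo.nj_tree(dm)
    phylo.write_newick(tree, outdir / "tree.nwk")
    log["stages"]["tree"] = {"n_leaves": len(list(tree.tips()))}

    if env_table is not None:
        env = envcompare.read_env_table(env_table)
        ranking = envcompare.rank_env_parameters(tree, env, method=config.linkage)
        ranking.to_csv(outdir / "env_ranking.tsv", sep="\t", index=False)
        log["stages"]["envrank"] = ranking.to_dict(orient="records")

    if genetrace_focal is not None:
        by_id = {p.sample_id: p for p in proteomes}
        if genetrace_focal not in by_id:
            raise UserInputError(f"genetrace focal sample {genetrace_focal!r} not in manifest")
        focal = by_id[genetrace_focal]
        others = [p for p in proteomes if p.sample_id != genetrace_focal]
        trace = genetrace.trace_genes(
            focal, others, tree,
            top_n=config.top_n, r_cutoff=config.r_cutoff,
            params=config.distance_params(), scoring=config.scoring_scheme(),
        )
        trace.to_tsv(outdir / f"genetrace_{genetrace_focal}.tsv")
        log["stages"]["genetrace"] = {
            "focal": genetrace_focal,
            "n_traced": int(trace.matrix.shape[0]),
            "n_selected": len(trace.selected),
        }

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


def _load_manifest(manifest) -> list[dict]:
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    if not isinstance(manifest, list) or not manifest:
        raise UserInputError("manifest must be a non-empty list of sample entries")
    labels = [e.get("sample") for e in manifest]
    if None in labels:
        raise UserInputError("every manifest entry needs a 'sample' label")
    if len(labels) != len(set(labels)):
        raise UserInputError("duplicate sample labels in manifest")
    return manifest


def _assemble_and_call(rs: seqio.ReadSet, outdir: Path, config: PipelineConfig):
    """Run the declared external assembly/gene-calling hook on one sample."""
    if not config.assembly_hook:
        raise UserInputError(
            f"sample {rs.sample_id!r} provides reads but no assembly hook is "
            "configured (stage: assembly); supply proteome FASTA instead or set "
            "config.assembly_hook"
        )
    reads_path = outdir / f"{rs.sample_id}.reads.fastq"
    prot_path = outdir / f"{rs.sample_id}.proteins.faa"
    seqio.write_fastq(rs, reads_path)
    cmd = config.assembly_hook.format(reads=reads_path, out=prot_path)
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    if proc.returncode != 0:
        raise MpassError(
            f"assembly hook failed for sample {rs.sample_id!r} "
            f"(exit {proc.returncode}):\n{proc.stderr.strip()}"
        )
    return seqio.read_fasta(prot_path, sample_id=rs.sample_id, dialect=config.dialect)
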