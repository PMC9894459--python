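"""Sequence I/O and preprocessing for metagenome-derived proteomes.

Reads and writes protein FASTA with per-gene metadata (k-tuple coverage of
the encoding contig, completeness flags from the gene caller), plus the
read-level steps that precede assembly: 3'-trimming to a fixed length and
random down-sampling to a common read count.

Header dialects
---------------
``native``
    ``>{id}|cov={float}|complete`` or ``>{id}|cov={float}|partial={2-digit}``.
    In the two-digit flag the first digit marks a missing start codon and the
    second a missing stop codon, so ``partial=00`` means both ends intact.
``assembler``
    Contig-style names such as ``NODE_12_length_3400_cov_8.31``; coverage is
    the number following the ``cov`` token, completeness is unknown and
    defaults to complete.
``gene-caller``
    ``key=value`` fields separated by ``|`` or whitespace, of which
    ``partial`` (two-digit flag) and optionally ``cov`` are read.

Unrecognized headers raise under ``strict=True``; otherwise they fall back
to coverage 1.0 and complete flags with a warning, which lets plain FASTA
flow through the pipeline unweighted.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, UserInputError

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NT_ALPHABET = set("ACGTN")

DIALECTS = ("native", "assembler", "gene-caller")

_ASSEMBLER_COV_RE = re.compile(r"(?:^|_)cov_([0-9]+(?:\.[0-9]+)?)(?:_|$)")
_KV_RE = re.compile(r"(\w+)=([^|\s]+)")


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein with its contig coverage and completeness."""

    id: str
    sequence: str
    coverage: float = 1.0
    has_start: bool = True
    has_stop: bool = True

    def __post_init__(self):
        if self.coverage < 0:
            raise UserInputError(f"{self.id}: coverage must be >= 0, got {self.coverage}")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise UserInputError(f"{self.id}: illegal amino-acid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop


@dataclass
class Proteome:
    """A sample's predicted protein set."""

    sample_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise UserInputError(
                f"sample {self.sample_id!r}: duplicate record ids {sorted(dup)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def coverage_map(self) -> dict[str, float]:
        return {r.id: r.coverage for r in self.records}


@dataclass
class ReadSet:
    """Short sequencing reads of one sample; quality strings optional."""

    sample_id: str
    reads: list[tuple[str, str, str | None]] = field(default_factory=list)

    def __post_init__(self):
        for rid, seq, qual in self.reads:
            if not seq:
                raise UserInputError(f"read {rid!r}: empty sequence")
            bad = set(seq.upper()) - NT_ALPHABET
            if bad:
                raise UserInputError(f"read {rid!r}: illegal nucleotides {sorted(bad)}")
            if qual is not None and len(qual) != len(seq):
                raise UserInputError(f"read {rid!r}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class FilterReport:
    """Counts of records removed by `filter_proteome`, by reason."""

    kept: int = 0
    removed_short: int = 0
    removed_partial: int = 0

    @property
    def removed(self) -> int:
        return self.removed_short + self.removed_partial


def parse_coverage_header(
    header: str, dialect: str = "native", strict: bool = False
) -> tuple[float, bool, bool]:
    """Extract (coverage, has_start, has_stop) from a FASTA header.

    Under ``strict=True`` an unrecognized header raises ``ParseError``;
    otherwise the permissive default (1.0, True, True) is returned with a
    warning so that plain FASTA remains usable.
    """
    if dialect not in DIALECTS:
        raise UserInputError(f"unknown header dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect == "assembler":
        m = _ASSEMBLER_COV_RE.search(header)
        if m:
            return float(m.group(1)), True, True
        return _fallback(header, strict, "no 'cov' token in assembler-style header")

    kv = dict(_KV_RE.findall(header))
    coverage = None
    if "cov" in kv:
        try:
            coverage = float(kv["cov"])
        except ValueError:
            return _fallback(header, strict, f"unparseable cov={kv['cov']!r}")
    has_start = has_stop = None
    if "partial" in kv:
        flag = kv["partial"]
        if len(flag) == 2 and set(flag) <= {"0", "1"}:
            has_start, has_stop = flag[0] == "0", flag[1] == "0"
        else:
            return _fallback(header, strict, f"unparseable partial={flag!r}")
    elif re.search(r"\|complete(\||$|\s)", header + "|"):
        has_start = has_stop = True

    if coverage is None and has_start is None:
        return _fallback(header, strict, "no cov= or partial=/complete fields")
    if coverage is None:
        coverage = 1.0
    if has_start is None:
        has_start = has_stop = True
    return coverage, has_start, has_stop


def _fallback(header: str, strict: bool, why: str) -> tuple[float, bool, bool]:
    if strict:
        raise ParseError(f"cannot parse header {header!r}: {why}")
    logger.warning("header %r: %s; defaulting to coverage=1.0, complete", header, why)
    return 1.0, True, True


def format_header(rec: ProteinRecord) -> str:
    """Native-dialect header for one record (inverse of the native parse)."""
    flag = (
        "complete"
        if rec.is_complete
        else f"partial={int(not rec.has_start)}{int(not rec.has_stop)}"
    )
    return f"{rec.id}|cov={rec.coverage:g}|{flag}"


def read_fasta(
    path: str | Path,
    sample_id: str | None = None,
    dialect: str = "native",
    strict: bool = False,
) -> Proteome:
    """Read a protein FASTA file into a Proteome.

    Header metadata is interpreted with `parse_coverage_header`. A file whose
    first non-blank line is not a FASTA header raises ``ParseError`` with the
    offending line number; an empty file yields an empty proteome.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        cov, start, stop = parse_coverage_header(sr.description, dialect, strict)
        rec_id = sr.id.split("|")[0]
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence=str(sr.seq).upper().rstrip("*"),
                coverage=cov,
                has_start=start,
                has_stop=stop,
            )
        )
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return Proteome(sample_id=sample_id or path.stem, records=records)


def _check_fasta_shape(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: expected FASTA header ('>') before sequence data", line=lineno
                )
            return


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a Proteome as native-dialect protein FASTA."""
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{format_header(rec)}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    path = Path(path)
    reads = [
        (sr.id, str(sr.seq).upper(), _qual_string(sr))
        for sr in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(sample_id=sample_id or path.stem, reads=reads)


def _qual_string(sr: SeqRecord) -> str:
    return "".join(chr(q + 33) for q in sr.letter_annotations["phred_quality"])


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in rs.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


def trim_reads(rs: ReadSet, max_len: int) -> ReadSet:
    """Trim every read to at most ``max_len`` nt, keeping the 5' prefix."""
    if max_len < 1:
        raise UserInputError(f"max_len must be >= 1, got {max_len}")
    return ReadSet(
        sample_id=rs.sample_id,
        reads=[
            (rid, seq[:max_len], qual[:max_len] if qual else None)
            for rid, seq, qual in rs.reads
        ],
    )


def downsample_reads(rs: ReadSet, n: int, seed: int) -> ReadSet:
    """Sample exactly ``n`` reads uniformly without replacement.

    Input order is preserved and the same seed always selects the same reads,
    so repeated runs are byte-identical.
    """
    if n > len(rs):
        raise UserInputError(f"cannot sample {n} reads: only {len(rs)} available")
    idx = sorted(random.Random(seed).sample(range(len(rs)), n))
    return ReadSet(sample_id=rs.sample_id, reads=[rs.reads[i] for i in idx])


def filter_proteome(
    p: Proteome, min_len: int = 100, require_complete: bool = True
) -> tuple[Proteome, FilterReport]:
    """Remove partial and short proteins before proteome comparison.

    Proteins shorter than ``min_len`` residues are removed (a 100-residue
    protein is retained: the cutoff is strict ``< min_len``), as are proteins
    lacking a start or stop codon when ``require_complete`` is set. Returns
    the filtered proteome and removal counts by reason; completeness is
    checked first, so a short partial protein counts as partial.
    """
    report = FilterReport()
    kept = []
    for rec in p:
        if require_complete and not rec.is_complete:
            report.removed_partial += 1
        elif rec.length < min_len:
            report.removed_short += 1
        else:
            kept.append(rec)
    report.kept = len(kept)
    return Proteome(sample_id=p.sample_id, records=kept), report


def translate(nt_sequence: str) -> str:
    """Translate a coding nucleotide sequence, dropping the terminal stop."""
    return str(Seq(nt_sequence).translate()).rstrip("*")
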