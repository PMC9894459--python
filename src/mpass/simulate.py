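"""Synthetic communities, abundance-vector schemes, and read sampling.

This module makes the whole pipeline testable without downloading genomes.
It provides:

* `make_genomes` — synthetic bacterial genomes carrying non-overlapping
  protein-coding ORFs (start codon, stop codon, >= 100 translated residues)
  separated by random intergenic sequence. All species carry mutated copies
  of one base gene set, diverged at a configurable per-site amino-acid rate.
* two abundance-vector generators reproducing the study designs used to
  benchmark the method: `convergent_vectors` (five species' proportions
  drift 5% per step toward each other over 10 steps, three groups of 10)
  and `gaussian_vectors` (half-normal noise of one fifth of each component,
  10 replicates per base vector).
* `sample_reads` — a simple shotgun read simulator (multinomial species
  sampling proportional to abundance x genome length, uniform positions,
  random strand, flat substitution errors).
* `community_proteome` — the assembly-free shortcut: translate the embedded
  ORFs directly, with coverage proportional to species abundance.
* `sequenced_proteome` — a sequencing-aware variant that models what finite
  read depth does to the recovered proteome: per-gene coverage proportional
  to species abundance (times a gene-specific efficiency), with genes below
  a minimum assembly coverage dropped. This is the variant that makes
  abundance differences visible to the distance, the way read sampling +
  assembly do in a real run.

The three base abundance vectors are the module's defaults
(`BASE_ABUNDANCE_VECTORS`); they are the study conditions, not tunables.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .errors import UserInputError
from .seqio import Proteome, ProteinRecord, ReadSet, translate

#: Relative abundances of the five community members for groups G1-G3.
BASE_ABUNDANCE_VECTORS = (
    (0.297, 0.507, 0.116, 0.058, 0.022),
    (0.345, 0.244, 0.281, 0.088, 0.042),
    (0.526, 0.320, 0.042, 0.066, 0.046),
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS = {
    aa: codons
    for aa, codons in {
        "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
        "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
        "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
        "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
        "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
        "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
        "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
        "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
        "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
        "W": ["TGG"], "Y": ["TAT", "TAC"],
    }.items()
}


@dataclass(frozen=True)
class AbundanceVector:
    """Relative proportions of the community members; sums to 1."""

    label: str
    species: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self):
        if len(self.species) != len(self.proportions):
            raise UserInputError(f"{self.label}: species/proportions length mismatch")
        if any(p < 0 for p in self.proportions):
            raise UserInputError(f"{self.label}: negative proportions")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise UserInputError(
                f"{self.label}: proportions sum to {sum(self.proportions)}, not 1"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions)


@dataclass(frozen=True)
class Gene:
    id: str
    start: int  # 0-based, inclusive
    end: int  # exclusive; includes the stop codon
    protein: str
    #: gene-specific sequencing/assembly efficiency: the factor between the
    #: species' nominal depth and this gene's realized k-tuple coverage
    #: (mappability, GC, positional effects); fixed per gene.
    efficiency: float = 1.0


@dataclass(frozen=True)
class SimGenome:
    name: str
    sequence: str
    genes: tuple[Gene, ...]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SyntheticCommunity:
    """Synthetic genomes plus one abundance vector, with provenance."""

    genomes: dict[str, SimGenome]
    abundance: AbundanceVector
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.genomes) != set(self.abundance.species):
            raise UserInputError("genome labels do not match abundance labels")


def default_species_names(n: int) -> list[str]:
    return [f"sp{i + 1}" for i in range(n)]


def _random_protein(length: int, rng: random.Random) -> str:
    return "M" + "".join(rng.choice(AA20) for _ in range(length - 1))


def _mutate_protein(protein: str, rate: float, rng: random.Random) -> str:
    out = [protein[0]]  # the start Met is fixed by the start codon
    for aa in protein[1:]:
        if rng.random() < rate:
            out.append(rng.choice(AA20.replace(aa, "")))
        else:
            out.append(aa)
    return "".join(out)


def _back_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein) + "TAA"


def make_genomes(
    n_species: int = 5,
    genome_len: int = 50_000,
    gene_len_range: tuple[int, int] = (306, 606),
    seed: int = 0,
    divergence: float = 0.7,
    efficiency_spread: float = 6.0,
) -> dict[str, SimGenome]:
    """Build mutually divergent genomes sharing a mutated base gene set.

    Each genome packs non-overlapping forward-strand ORFs (ATG ... TAA, at
    least 100 translated residues) separated by 20-100 nt of random
    intergenic sequence, filling the genome up to ``genome_len``. All
    species carry homologs of the same base genes, independently mutated at
    ``divergence`` substitutions per amino-acid site, with codons drawn
    fresh per species and gene order shuffled, so both proteins and
    nucleotide sequences differ between species. Deterministic given
    ``seed``.

    The default divergence (0.7 per site) keeps between-species best hits
    in the remote-homology regime, so a gene missing from one sample is
    not silently replaced by a strong cross-species hit.

    Each gene carries a sequencing efficiency in ``[1/efficiency_spread,
    efficiency_spread]``: per-gene k-tuple coverage in an assembly varies
    around the species' depth by gene-specific factors (mappability, GC,
    repeats), and that variation is what makes gene recovery degrade
    gradually — rather than all at once — as a species' abundance drops
    (see `sequenced_proteome`). Efficiencies follow a right-skewed
    density proportional to 1/c^2 (most genes recover somewhat below the
    nominal depth, a minority far above it, the heavy low tail mirroring
    hard-to-assemble genes) and are taken as that density's exact
    quantiles, assigned to genes in shuffled order, so every species'
    recovered-gene fraction follows the same smooth curve of abundance
    instead of a sample-size-limited random staircase.
    """
    lo, hi = gene_len_range
    if lo < 306:
        raise UserInputError("min gene length must be >= 306 nt (100 aa + start/stop)")
    if genome_len < 10 * hi:
        raise UserInputError(
            f"genome_len={genome_len} too small: need >= 10x max gene length ({10 * hi})"
        )
    if not 0.0 <= divergence <= 1.0:
        raise UserInputError(f"divergence must be in [0, 1], got {divergence}")
    rng = random.Random(seed)

    # base gene lengths chosen once so every species has homologs of each
    base_proteins = []
    budget = genome_len
    g = 0
    while True:
        gene_nt = rng.randrange(lo, hi + 1, 3)
        spacer = rng.randrange(20, 101)
        if gene_nt + spacer > budget:
            break
        budget -= gene_nt + spacer
        base_proteins.append(_random_protein((gene_nt - 3) // 3, rng))
        g += 1
    if not base_proteins:
        raise UserInputError("infeasible packing: no gene fits in genome_len")

    n_genes = len(base_proteins)
    # quantiles of density ∝ 1/c^2 on [1/spread, spread]:
    # CDF F(c) = (spread - 1/c) / (spread - 1/spread)
    lo_inv, hi_inv = efficiency_spread, 1.0 / efficiency_spread
    eff_grid = [
        1.0 / (lo_inv - (i + 0.5) / n_genes * (lo_inv - hi_inv))
        for i in range(n_genes)
    ]

    genomes = {}
    for s, name in enumerate(default_species_names(n_species)):
        order = list(range(n_genes))
        rng.shuffle(order)
        efficiencies = eff_grid[:]
        rng.shuffle(efficiencies)
        parts, genes, pos = [], [], 0
        for gi in order:
            prot = _mutate_protein(base_proteins[gi], divergence, rng)
            orf = _back_translate(prot, rng)
            spacer = "".join(rng.choice("ACGT") for _ in range(rng.randrange(20, 101)))
            parts.append(orf)
            eff = efficiencies[gi]
            genes.append(
                Gene(id=f"{name}_g{gi:03d}", start=pos, end=pos + len(orf),
                     protein=prot, efficiency=eff)
            )
            parts.append(spacer)
            pos += len(orf) + len(spacer)
        seq = "".join(parts)
        if len(seq) < genome_len:  # pad to nominal length
            seq += "".join(rng.choice("ACGT") for _ in range(genome_len - len(seq)))
        genomes[name] = SimGenome(name=name, sequence=seq, genes=tuple(genes))
    return genomes


def convergent_vectors(
    base=BASE_ABUNDANCE_VECTORS,
    steps: int = 10,
    rate: float = 0.05,
    species: list[str] | None = None,
    cumulative: bool = True,
) -> list[AbundanceVector]:
    """Abundance vectors drifting toward a uniform community.

    For each base vector and step k = 1..steps, components above the current
    vector mean are decreased and components below it increased, each by
    ``rate`` (multiplicatively, compounded over steps), then renormalized.
    Later steps are strictly closer (L1) to the uniform vector, so within a
    group the highest-step samples have most lost the group's original
    composition. Output: ``steps`` vectors per base, labelled ``G{g}-{k}``.

    ``cumulative=False`` gives the single-perturbation variant instead:
    vector k perturbs only component ``(k-1) mod n``, up for odd k and down
    for even k, by ``rate``.
    """
    species = species or default_species_names(len(base[0]))
    out = []
    for g, vec in enumerate(base, start=1):
        v = np.asarray(vec, dtype=float)
        if cumulative:
            cur = v.copy()
            for k in range(1, steps + 1):
                cur = np.where(cur > cur.mean(), cur * (1 - rate), cur * (1 + rate))
                cur = cur / cur.sum()
                out.append(
                    AbundanceVector(f"G{g}-{k}", tuple(species), tuple(cur.tolist()))
                )
        else:
            for k in range(1, steps + 1):
                cur = v.copy()
                idx = (k - 1) % len(v)
                cur[idx] *= (1 + rate) if k % 2 else (1 - rate)
                cur = cur / cur.sum()
                out.append(
                    AbundanceVector(f"G{g}-{k}", tuple(species), tuple(cur.tolist()))
                )
    return out


def gaussian_vectors(
    base=BASE_ABUNDANCE_VECTORS,
    reps: int = 10,
    seed: int = 0,
    species: list[str] | None = None,
) -> list[AbundanceVector]:
    """Abundance vectors randomized with scaled half-normal noise.

    Each component c is replaced by ``c + |N(0, c)| / 5`` (noise standard
    deviation equal to the component, scaled by one fifth), then the vector
    is renormalized; ``reps`` independent draws per base vector, labelled
    ``G{g}-{k}``. Deterministic given ``seed``.
    """
    species = species or default_species_names(len(base[0]))
    rng = np.random.default_rng(seed)
    out = []
    for g, vec in enumerate(base, start=1):
        v = np.asarray(vec, dtype=float)
        for k in range(1, reps + 1):
            noisy = v + np.abs(rng.normal(0.0, v)) / 5.0
            noisy = noisy / noisy.sum()
            out.append(
                AbundanceVector(f"G{g}-{k}", tuple(species), tuple(noisy.tolist()))
            )
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_reads(
    community: SyntheticCommunity,
    n_reads: int,
    read_len: int = 200,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Shotgun reads from a community (stand-in for a read simulator).

    Species are sampled multinomially with probability proportional to
    abundance x genome length (abundance is a genome-copy proportion, so
    longer genomes yield proportionally more reads); read start positions
    are uniform, strands random, and substitution errors are applied per
    base at ``error_rate``. Deterministic given ``seed``.
    """
    genomes = community.genomes
    if any(read_len > len(g) for g in genomes.values()):
        raise UserInputError("read_len exceeds the shortest genome length")
    if not 0.0 <= error_rate < 1.0:
        raise UserInputError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    species = list(community.abundance.species)
    weights = community.abundance.as_array() * np.array(
        [len(genomes[s]) for s in species], dtype=float
    )
    if weights.sum() <= 0:
        raise UserInputError("all abundances are zero")
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads = []
    i = 0
    for s, c in zip(species, counts):
        seq = genomes[s].sequence
        if c == 0:
            continue
        starts = rng.integers(0, len(seq) - read_len + 1, size=c)
        strands = rng.integers(0, 2, size=c)
        for st, rev in zip(starts, strands):
            frag = seq[st : st + read_len]
            if rev:
                frag = _revcomp(frag)
            if error_rate > 0:
                frag = _add_errors(frag, error_rate, rng)
            reads.append((f"{community.abundance.label}_r{i}", frag, None))
            i += 1
    return ReadSet(sample_id=community.abundance.label, reads=reads)


def _add_errors(seq: str, rate: float, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"), dtype="S1")
    for pos in hit:
        choices = bases[bases != arr[pos]]
        arr[pos] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def community_proteome(
    community: SyntheticCommunity, coverage_scale: float = 100.0
) -> Proteome:
    """Assembly-free proteome of a community.

    Translates every embedded ORF directly and sets each protein's coverage
    to ``abundance * coverage_scale`` for its species; all records are
    complete. Zero-abundance species contribute no proteins. Deterministic.
    """
    records = []
    for sp, prop in zip(community.abundance.species, community.abundance.proportions):
        if prop <= 0:
            continue
        for gene in community.genomes[sp].genes:
            records.append(
                ProteinRecord(
                    id=gene.id,
                    sequence=gene.protein,
                    coverage=prop * coverage_scale,
                    has_start=True,
                    has_stop=True,
                )
            )
    return Proteome(sample_id=community.abundance.label, records=records)


def sequenced_proteome(
    community: SyntheticCommunity,
    depth: float = 20.0,
    min_coverage: float = 2.0,
    stochastic: bool = False,
    seed: int = 0,
) -> Proteome:
    """Proteome as recovered after finite-depth sequencing and assembly.

    Models the composition-dependent part of read sampling + assembly +
    gene calling without running them: gene g of species s gets k-tuple
    coverage ``abundance_s * depth * efficiency_g`` (``depth`` is the
    coverage a species would get at abundance 1; the per-gene efficiency
    factor comes from `make_genomes`), and genes whose coverage falls below
    ``min_coverage`` fail assembly and are absent from the proteome.

    Because efficiencies are spread log-uniformly, the recovered fraction
    of a species' genes rises smoothly with its abundance, so community
    composition reaches the proteome distance through gene content and
    coverage weights — the same route read sampling + assembly provide in
    a real run. With ``stochastic=True`` the recorded coverage is
    additionally a Poisson draw around its mean (deterministic given
    ``seed``); the default is the noise-free expectation.
    """
    if depth <= 0:
        raise UserInputError(f"depth must be > 0, got {depth}")
    rng = np.random.default_rng(seed)
    records = []
    for sp, prop in zip(community.abundance.species, community.abundance.proportions):
        if prop <= 0:
            continue
        for gene in community.genomes[sp].genes:
            cov = prop * depth * gene.efficiency
            if stochastic:
                cov = float(rng.poisson(cov))
            if cov >= min_coverage:
                records.append(
                    ProteinRecord(
                        id=gene.id,
                        sequence=gene.protein,
                        coverage=float(cov),
                        has_start=True,
                        has_stop=True,
                    )
                )
    if not records:
        raise UserInputError(
            f"{community.abundance.label}: no gene reached coverage "
            f"{min_coverage} at depth {depth}"
        )
    return Proteome(sample_id=community.abundance.label, records=records)


def make_communities(
    vectors: list[AbundanceVector],
    genomes: dict[str, SimGenome],
    scheme: str = "convergent",
    seed: int = 0,
) -> list[SyntheticCommunity]:
    """Pair one genome set with many abundance vectors."""
    return [
        SyntheticCommunity(
            genomes=genomes,
            abundance=v,
            provenance={"scheme": scheme, "seed": seed},
        )
        for v in vectors
    ]
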