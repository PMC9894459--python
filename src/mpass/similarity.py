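"""Proteome-to-proteome distance from coverage-weighted average similarity.

The distance between two metagenome-derived proteomes is built in three
steps:

1. every retained protein of sample A is searched against all proteins of
   sample B (and vice versa) by local alignment, keeping the best-scoring
   hit per query;
2. each gene's best-hit bit score is normalized by its self-score, giving a
   per-gene similarity in [0, 1]; per-gene dissimilarities are averaged with
   weights proportional to the gene's k-tuple coverage, and the two
   directions are averaged, giving the normalized average dissimilarity T;
3. T is mapped onto the scale of percent Poisson-corrected 16S rRNA
   substitution rates by the calibrated exponential transform
   ``S = const1 * exp(const2 * T)`` with defaults const1 = 4.142 and
   const2 = 2.824.

Genes with no hit in the other sample contribute maximal dissimilarity, so
two metagenomes that share no genes still receive a (large, finite)
distance. The transform constants can be re-fitted from (T, S2') calibration
points with `estimate_constants`; S2' is the Poisson-corrected substitution
rate computed by `poisson_corrected_rate`.

Alignment scores are BLOSUM62 local-alignment bit scores with affine gap
penalties (open 11, extend 1) and Karlin–Altschul statistics, matching the
defaults of the protein searches this pipeline is calibrated against.
Because the score of an (a, b) sequence pair does not depend on which sample
the sequences came from, scores are cached on the sequence pair; repeated
sequences across samples (ubiquitous in simulation and common in real
cross-sample comparisons) are aligned once.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import curve_fit

from .errors import UserInputError
from .seqio import Proteome

logger = logging.getLogger(__name__)

#: Calibration of the T -> S transform against percent Poisson-corrected
#: 16S rRNA substitution rates (94-organism regression).
DEFAULT_CONST1 = 4.142
DEFAULT_CONST2 = 2.824

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class DistanceParams:
    """Constants of the exponential transform S = const1 * exp(const2 * T)."""

    const1: float = DEFAULT_CONST1
    const2: float = DEFAULT_CONST2

    def __post_init__(self):
        if not (math.isfinite(self.const1) and self.const1 > 0):
            raise UserInputError(f"const1 must be finite and > 0, got {self.const1}")
        if not (math.isfinite(self.const2) and self.const2 >= 0):
            raise UserInputError(f"const2 must be finite and >= 0, got {self.const2}")


@dataclass(frozen=True)
class Hit:
    """Best hit of one query protein against a target proteome.

    ``target_id`` is None when no alignment passed the reporting threshold;
    the hit then carries zero score and infinite e-value.
    """

    query_id: str
    self_score: float
    target_id: str | None = None
    best_score: float = 0.0
    evalue: float = math.inf

    @property
    def is_hit(self) -> bool:
        return self.target_id is not None

    @property
    def similarity(self) -> float:
        """Self-score-normalized similarity in [0, 1]; 0 for no-hit."""
        if not self.is_hit:
            return 0.0
        return min(1.0, max(0.0, self.best_score / self.self_score))


@dataclass
class HitTable:
    """Best hits of every retained query protein against one target sample."""

    query_sample: str
    target_sample: str
    hits: dict[str, Hit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)


class ScoringScheme:
    """Local-alignment scoring: substitution matrix, affine gaps, statistics.

    Parameters
    ----------
    matrix : str
        Name of a substitution matrix known to Biopython (default BLOSUM62).
    gap_open, gap_extend : int
        Affine gap penalties; a gap of length k costs ``gap_open + k *
        gap_extend``.
    evalue_max : float
        Reporting threshold: alignments with e-value above this are no-hits.
    ka_lambda, ka_k : float
        Karlin–Altschul parameters used to convert raw scores to bit scores
        and e-values.
    """

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        gap_open: int = 11,
        gap_extend: int = 1,
        evalue_max: float = 10.0,
        ka_lambda: float = _KA_LAMBDA,
        ka_k: float = _KA_K,
    ):
        self.matrix_name = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.evalue_max = evalue_max
        self.ka_lambda = ka_lambda
        self.ka_k = ka_k
        self._aligner = Align.PairwiseAligner()
        self._aligner.substitution_matrix = substitution_matrices.load(matrix)
        # PairwiseAligner charges open_gap_score for the first gapped
        # position, so open = -(gap_open + gap_extend) reproduces the
        # "11 + k" affine cost convention.
        self._aligner.open_gap_score = -(gap_open + gap_extend)
        self._aligner.extend_gap_score = -gap_extend
        self._aligner.mode = "local"
        self._alphabet = set(str(self._aligner.substitution_matrix.alphabet))
        self._cache: dict[tuple[str, str], float] = {}

    def raw_score(self, a: str, b: str) -> float:
        """Smith–Waterman raw score, cached on the unordered sequence pair."""
        key = (a, b) if a <= b else (b, a)
        score = self._cache.get(key)
        if score is None:
            score = float(self._aligner.score(key[0], key[1]))
            self._cache[key] = score
        return score

    def bit_score(self, raw: float) -> float:
        return (self.ka_lambda * raw - math.log(self.ka_k)) / math.log(2.0)

    def evalue(self, bits: float, query_len: int, search_space: int) -> float:
        """Extreme-value e-value for a bit score in a given search space."""
        return query_len * search_space * 2.0 ** (-bits)

    def validate(self, seq: str, label: str = "sequence") -> None:
        if not seq:
            raise UserInputError(f"{label}: empty sequence")
        bad = set(seq) - self._alphabet
        if bad:
            raise UserInputError(f"{label}: characters {sorted(bad)} not in scoring alphabet")


def align_score(
    a: str, b: str, scoring: ScoringScheme | None = None, search_space: int | None = None
) -> tuple[float, float]:
    """Align two protein sequences locally; return (bit score, e-value).

    ``search_space`` is the effective target size in residues (defaults to
    ``len(b)``, i.e. a single-sequence database); the e-value is
    ``len(a) * search_space * 2**-bits``.
    """
    scoring = scoring or ScoringScheme()
    scoring.validate(a, "query")
    scoring.validate(b, "target")
    bits = scoring.bit_score(scoring.raw_score(a, b))
    return bits, scoring.evalue(bits, len(a), search_space or len(b))


def best_hits(
    query: Proteome, target: Proteome, scoring: ScoringScheme | None = None
) -> HitTable:
    """Best-scoring target protein for every query protein.

    Every retained query protein appears exactly once in the result; queries
    whose best alignment has e-value above the reporting threshold are
    recorded as no-hits. Self-scores are computed with the same scoring
    scheme. Ties on score are broken toward the lexicographically smallest
    target id, for reproducibility.
    """
    scoring = scoring or ScoringScheme()
    if len(query) == 0 or len(target) == 0:
        raise UserInputError(
            f"best_hits needs non-empty proteomes "
            f"({query.sample_id}: {len(query)}, {target.sample_id}: {len(target)})"
        )
    for rec in itertools.chain(query, target):
        scoring.validate(rec.sequence, rec.id)

    search_space = sum(r.length for r in target)
    targets = sorted(target, key=lambda r: r.id)
    table = HitTable(query_sample=query.sample_id, target_sample=target.sample_id)
    for q in query:
        self_bits = scoring.bit_score(scoring.raw_score(q.sequence, q.sequence))
        best_raw, best_id = -math.inf, None
        for t in targets:
            raw = scoring.raw_score(q.sequence, t.sequence)
            if raw > best_raw:
                best_raw, best_id = raw, t.id
        bits = scoring.bit_score(best_raw)
        ev = scoring.evalue(bits, q.length, search_space)
        if ev > scoring.evalue_max:
            table.hits[q.id] = Hit(query_id=q.id, self_score=self_bits)
        else:
            table.hits[q.id] = Hit(
                query_id=q.id,
                self_score=self_bits,
                target_id=best_id,
                best_score=bits,
                evalue=ev,
            )
    return table


class ScoreIndex:
    """Raw-score matrix over the unique sequences of a set of proteomes.

    All-against-all comparison of many samples re-aligns the same sequence
    pairs repeatedly (identical sequences recur across samples). This index
    computes the raw Smith–Waterman score for each unique unordered sequence
    pair once and serves per-sample-pair submatrices as numpy arrays, so a
    30-sample comparison costs one unique-pair alignment pass plus cheap
    slicing. Results are identical to calling `best_hits` pair by pair.
    """

    def __init__(self, proteomes: list[Proteome], scoring: ScoringScheme):
        self.scoring = scoring
        seqs: dict[str, int] = {}
        for p in proteomes:
            for rec in p:
                scoring.validate(rec.sequence, rec.id)
                seqs.setdefault(rec.sequence, len(seqs))
        self._index = seqs
        uniq = list(seqs)
        n = len(uniq)
        logger.info("aligning %d unique sequences (%d pairs)", n, n * (n + 1) // 2)
        mat = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                mat[i, j] = mat[j, i] = scoring.raw_score(uniq[i], uniq[j])
        self._matrix = mat

    def indices(self, p: Proteome) -> np.ndarray:
        return np.fromiter((self._index[r.sequence] for r in p), dtype=int, count=len(p))

    def pair_tables(self, a: Proteome, b: Proteome) -> tuple[HitTable, HitTable]:
        """Hit tables for both directions of one sample pair."""
        return self._directed(a, b), self._directed(b, a)

    def _directed(self, query: Proteome, target: Proteome) -> HitTable:
        if len(query) == 0 or len(target) == 0:
            raise UserInputError(
                f"best hits need non-empty proteomes "
                f"({query.sample_id}: {len(query)}, {target.sample_id}: {len(target)})"
            )
        scoring = self.scoring
        # Sort targets by id so that argmax tie-breaking matches best_hits'
        # lexicographically-smallest-id convention.
        targets = sorted(target, key=lambda r: r.id)
        qi = self.indices(query)
        ti = np.fromiter((self._index[r.sequence] for r in targets), dtype=int,
                         count=len(targets))
        sub = self._matrix[np.ix_(qi, ti)]
        best_col = sub.argmax(axis=1)
        best_raw = sub[np.arange(len(qi)), best_col]
        self_raw = self._matrix[qi, qi]
        search_space = sum(r.length for r in target)
        table = HitTable(query_sample=query.sample_id, target_sample=target.sample_id)
        for k, q in enumerate(query):
            self_bits = scoring.bit_score(self_raw[k])
            bits = scoring.bit_score(best_raw[k])
            ev = scoring.evalue(bits, q.length, search_space)
            if ev > scoring.evalue_max:
                table.hits[q.id] = Hit(query_id=q.id, self_score=self_bits)
            else:
                table.hits[q.id] = Hit(
                    query_id=q.id,
                    self_score=self_bits,
                    target_id=targets[best_col[k]].id,
                    best_score=bits,
                    evalue=ev,
                )
        return table


def directed_avg_dissimilarity(table: HitTable, coverage: dict[str, float]) -> float:
    """Coverage-weighted mean per-gene dissimilarity for one direction."""
    total = 0.0
    acc = 0.0
    for qid, hit in table.hits.items():
        w = coverage.get(qid)
        if w is None:
            raise UserInputError(f"no coverage for query gene {qid!r}")
        total += w
        acc += w * (1.0 - hit.similarity)
    if total <= 0:
        raise UserInputError(
            f"total coverage of sample {table.query_sample!r} is zero; cannot weight genes"
        )
    return acc / total


def normalized_avg_dissimilarity(
    ab: HitTable, ba: HitTable, cov_a: dict[str, float], cov_b: dict[str, float]
) -> float:
    """Normalized average dissimilarity T between two proteomes.

    Per gene, dissimilarity is ``1 - best_score/self_score`` (1 for genes
    with no hit, so sample-specific genes push samples apart). Each
    direction averages its genes with weights proportional to k-tuple
    coverage; T is the arithmetic mean of the two directions and lies in
    [0, 1], with 0 for identical proteomes.
    """
    t = 0.5 * (
        directed_avg_dissimilarity(ab, cov_a) + directed_avg_dissimilarity(ba, cov_b)
    )
    return min(1.0, max(0.0, t))


def distance_from_T(T: float, params: DistanceParams | None = None) -> float:
    """Exponential transform of T onto the 16S substitution-rate scale.

    ``S = const1 * exp(const2 * T)``, in percent substitution-rate
    equivalents; strictly increasing in T, equal to const1 at T = 0.
    """
    params = params or DistanceParams()
    if not 0.0 <= T <= 1.0:
        raise UserInputError(f"T must be in [0, 1], got {T}")
    return params.const1 * math.exp(params.const2 * T)


def poisson_corrected_rate(matched: int, aln_len: int, gapped: int = 0) -> float:
    """Percent Poisson-corrected substitution rate from an alignment.

    The observed mismatch proportion ``S1' = 1 - matched/(aln_len - gapped)``
    is corrected for multiple substitutions at a site:
    ``S2' = -ln(1 - S1') * 100``.
    """
    if gapped < 0 or aln_len <= gapped:
        raise UserInputError(
            f"need aln_len > gapped >= 0, got aln_len={aln_len}, gapped={gapped}"
        )
    sites = aln_len - gapped
    if not 0 <= matched <= sites:
        raise UserInputError(f"matched must be in [0, {sites}], got {matched}")
    if matched == 0:
        raise UserInputError("no matched loci: Poisson correction is undefined")
    s1 = 1.0 - matched / sites
    return -math.log(1.0 - s1) * 100.0


def estimate_constants(
    points: "list[tuple[float, float]] | np.ndarray", refine: bool = True
) -> tuple[DistanceParams, dict]:
    """Fit S2' ~ const1 * exp(const2 * T) to calibration points.

    Points are (T, S2') pairs, S2' the percent Poisson-corrected 16S
    substitution rate. The fit is log-linear least squares on positive S2'
    (non-positive values are excluded with a warning), optionally refined by
    nonlinear least squares on the original scale. Returns the fitted
    parameters and diagnostics (n_used, log-scale r2, residual sd).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise UserInputError("need at least 3 (T, S2') points")
    pos = pts[:, 1] > 0
    if (~pos).any():
        logger.warning("excluding %d non-positive S2' points from the fit", int((~pos).sum()))
    pts = pts[pos]
    if pts.shape[0] < 3:
        raise UserInputError("fewer than 3 points with positive S2'; cannot fit")
    t, s = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise UserInputError("all T values identical; exponential fit is unidentifiable")

    c2, log_c1 = np.polyfit(t, np.log(s), 1)
    c1 = math.exp(log_c1)
    if refine:
        try:
            (c1, c2), _ = curve_fit(
                lambda x, a, b: a * np.exp(b * x), t, s, p0=(c1, c2), maxfev=10000
            )
        except RuntimeError:
            logger.warning("nonlinear refinement did not converge; keeping log-linear fit")
    resid = np.log(s) - (math.log(c1) + c2 * t)
    ss_tot = float(np.sum((np.log(s) - np.log(s).mean()) ** 2))
    diag = {
        "n_used": int(pts.shape[0]),
        "r2_log": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0,
        "resid_sd_log": float(np.std(resid)),
    }
    return DistanceParams(const1=float(c1), const2=float(c2)), diag


def build_distance_matrix(
    proteomes: list[Proteome],
    scoring: ScoringScheme | None = None,
    params: DistanceParams | None = None,
) -> tuple[skbio.DistanceMatrix, pd.DataFrame]:
    """All-against-all proteome distances S, plus a per-pair provenance log.

    Evaluates T for every unordered sample pair (T is symmetric by
    construction) and maps it through the exponential transform. The matrix
    diagonal is 0 — tree building requires zero self-distance; the transform's
    own S(T=0) = const1 offset is recorded in the log, not subtracted from
    off-diagonal entries. Returns a `skbio.DistanceMatrix` of S values and a
    DataFrame logging (sample_a, sample_b, T, similarity, S).
    """
    scoring = scoring or ScoringScheme()
    params = params or DistanceParams()
    labels = [p.sample_id for p in proteomes]
    if len(labels) != len(set(labels)):
        raise UserInputError(f"duplicate sample labels: {sorted(labels)}")
    if len(proteomes) < 3:
        raise UserInputError("need at least 3 proteomes for a tree-ready matrix")

    n = len(proteomes)
    index = ScoreIndex(proteomes, scoring)
    mat = np.zeros((n, n))
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        a, b = proteomes[i], proteomes[j]
        ab, ba = index.pair_tables(a, b)
        T = normalized_avg_dissimilarity(ab, ba, a.coverage_map(), b.coverage_map())
        S = distance_from_T(T, params)
        mat[i, j] = mat[j, i] = S
        rows.append(
            {"sample_a": a.sample_id, "sample_b": b.sample_id,
             "T": T, "similarity": 1.0 - T, "S": S}
        )
        logger.info("pair %s vs %s: T=%.4f S=%.3f", a.sample_id, b.sample_id, T, S)
    log = pd.DataFrame(rows, columns=["sample_a", "sample_b", "T", "similarity", "S"])
    return skbio.DistanceMatrix(mat, ids=labels), log


def write_phylip(dm: skbio.DistanceMatrix, path) -> None:
    """Write a distance matrix in lower-triangle PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for i, label in enumerate(dm.ids):
            row = " ".join(f"{dm.data[i, j]:.6f}" for j in range(i))
            fh.write(f"{label:<10s} {row}".rstrip() + "\n")


def read_phylip(path) -> skbio.DistanceMatrix:
    """Read a lower-triangle or square PHYLIP distance matrix."""
    with open(path) as fh:
        tokens_by_line = [line.split() for line in fh if line.strip()]
    if not tokens_by_line:
        raise UserInputError(f"{path}: empty distance matrix file")
    try:
        n = int(tokens_by_line[0][0])
    except ValueError as exc:
        raise UserInputError(f"{path}: first line must give the number of samples") from exc
    labels, mat = [], np.zeros((n, n))
    for i, tokens in enumerate(tokens_by_line[1 : n + 1]):
        labels.append(tokens[0])
        vals = [float(x) for x in tokens[1:]]
        if len(vals) == n:  # square
            mat[i, :] = vals
        elif len(vals) == i:  # lower triangle
            mat[i, :i] = vals
            mat[:i, i] = vals
        else:
            raise UserInputError(f"{path}: row {tokens[0]!r} has {len(vals)} values")
    return skbio.DistanceMatrix(mat, ids=labels)


def write_tsv(dm: skbio.DistanceMatrix, path) -> None:
    """Write a distance matrix as a square labelled TSV."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
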