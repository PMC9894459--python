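"""Per-gene conservation traces across samples (tree-concordance analysis).

For a focal sample, each high-coverage protein is searched against every
other sample's proteome and its per-gene distance S_g (the same exponential
transform as the proteome distance, applied to the single gene's normalized
dissimilarity instead of the proteome average) is recorded, giving one
distance profile per gene across samples. Genes whose profile correlates
with the patristic distance from the focal leaf on the metagenomic tree
(Pearson r above a cutoff, 0.7 by default) are "tree-concordant": their
individual conservation pattern recapitulates the whole-proteome topology.

The exported matrix (genes x samples of S_g, rows sorted by descending r)
is the input for external heatmap tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import UserInputError
from .phylo import patristic_distances
from .seqio import Proteome, ProteinRecord
from .similarity import (
    DistanceParams,
    ScoringScheme,
    best_hits,
    distance_from_T,
)

logger = logging.getLogger(__name__)

MODES = ("score", "evalue")
_EVALUE_FLOOR = 1e-200
_NEGLOG_CAP = 200.0


@dataclass
class GeneTraceMatrix:
    """Per-gene distance profiles with their tree correlations.

    ``matrix``: genes x samples DataFrame of S_g values, rows sorted by
    descending Pearson r; ``pearson_r``: per-gene r against the patristic
    distances; ``selected``: gene ids with r > the cutoff.
    """

    matrix: pd.DataFrame
    pearson_r: pd.Series
    selected: list[str]
    excluded: list[str]

    def to_tsv(self, path: str | Path) -> None:
        out = self.matrix.copy()
        out.insert(0, "pearson_r", self.pearson_r)
        out.to_csv(path, sep="\t", index_label="gene")


def select_top_coverage(p: Proteome, top_n: int = 1000) -> Proteome:
    """The ``top_n`` records by descending k-tuple coverage (ties by id)."""
    if len(p) < top_n:
        logger.warning(
            "sample %s has %d proteins (< top_n=%d); keeping all",
            p.sample_id, len(p), top_n,
        )
    ranked = sorted(p, key=lambda r: (-r.coverage, r.id))
    return Proteome(sample_id=p.sample_id, records=ranked[:top_n])


def _dissimilarity(hit, mode: str) -> float:
    if mode == "score":
        return 1.0 - hit.similarity
    # e-value mode (non-normative): dissimilarity from the ratio of capped
    # -log10 e-values of the best hit and the self hit
    if not hit.is_hit:
        return 1.0
    nl_best = min(_NEGLOG_CAP, -math.log10(max(hit.evalue, _EVALUE_FLOOR)))
    self_ev = hit.self_score and 2.0 ** (-hit.self_score)  # bits -> ~evalue scale
    nl_self = min(_NEGLOG_CAP, -math.log10(max(self_ev, _EVALUE_FLOOR)))
    if nl_self <= 0:
        return 1.0
    return min(1.0, max(0.0, 1.0 - nl_best / nl_self))


def per_gene_distance(
    gene: ProteinRecord,
    target: Proteome,
    params: DistanceParams | None = None,
    scoring: ScoringScheme | None = None,
    mode: str = "score",
) -> float:
    """Distance S_g of one gene to one sample.

    The gene's best hit in the target proteome gives a per-gene
    dissimilarity d_g — ``1 - best_score/self_score`` in the default
    ``score`` mode, an e-value-based monotone analogue in ``evalue`` mode —
    and ``S_g = const1 * exp(const2 * d_g)``. A gene with no hit gets the
    maximal distance ``S(1)``.
    """
    if mode not in MODES:
        raise UserInputError(f"unknown mode {mode!r}; expected one of {MODES}")
    params = params or DistanceParams()
    table = best_hits(
        Proteome(sample_id="__query__", records=[gene]), target, scoring
    )
    d = _dissimilarity(table.hits[gene.id], mode)
    return distance_from_T(d, params)


def trace_genes(
    focal: Proteome,
    others: list[Proteome],
    tree: TreeNode,
    top_n: int = 1000,
    r_cutoff: float = 0.7,
    params: DistanceParams | None = None,
    scoring: ScoringScheme | None = None,
    mode: str = "score",
) -> GeneTraceMatrix:
    """Trace each high-coverage focal gene across samples and rank by r.

    For each of the focal sample's ``top_n`` highest-coverage genes, the
    vector of per-gene distances S_g to every other sample is correlated
    (Pearson) with the patristic distance from the focal leaf to that
    sample's leaf on ``tree``. Genes with zero-variance profiles are
    excluded with a warning (r is undefined); genes with r > ``r_cutoff``
    form the tree-concordant selection.
    """
    if mode not in MODES:
        raise UserInputError(f"unknown mode {mode!r}; expected one of {MODES}")
    params = params or DistanceParams()
    scoring = scoring or ScoringScheme()
    sample_ids = [p.sample_id for p in others]
    patristic = patristic_distances(tree, focal.sample_id)
    missing = set(sample_ids) - set(patristic)
    if missing:
        raise UserInputError(f"samples not in tree: {sorted(missing)}")

    top = select_top_coverage(focal, top_n)
    profiles = {rec.id: [] for rec in top}
    for other in others:
        table = best_hits(top, other, scoring)
        for rec in top:
            d = _dissimilarity(table.hits[rec.id], mode)
            profiles[rec.id].append(distance_from_T(d, params))

    tree_dist = np.array([patristic[s] for s in sample_ids])
    rows, rvals, excluded = {}, {}, []
    for gid, profile in profiles.items():
        vec = np.asarray(profile)
        if np.ptp(vec) == 0 or np.ptp(tree_dist) == 0:
            excluded.append(gid)
            continue
        rvals[gid] = float(np.corrcoef(vec, tree_dist)[0, 1])
        rows[gid] = vec
    if excluded:
        logger.warning("%d genes excluded (zero-variance distance profile)", len(excluded))

    order = sorted(rvals, key=lambda g: (-rvals[g], g))
    matrix = pd.DataFrame(
        [rows[g] for g in order], index=order, columns=sample_ids, dtype=float
    )
    r_series = pd.Series({g: rvals[g] for g in order}, dtype=float).loc[order]
    selected = [g for g in order if rvals[g] > r_cutoff]
    return GeneTraceMatrix(
        matrix=matrix, pearson_r=r_series, selected=selected, excluded=excluded
    )
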