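"""Environmental-parameter dendrograms and their ranking against a tree.

For each measured environmental variable (pH, temperature, ion
concentrations, ...) the samples are clustered hierarchically on the
absolute difference of that single variable, and the resulting dendrogram
is compared to the metagenomic tree by Robinson–Foulds symmetric
difference. Ranking the variables by that difference points at the
parameters whose gradient best mirrors the community turnover.

Exact ties in merge heights are collapsed into polytomies rather than
resolved arbitrarily, so the symmetric difference is not inflated by
artifactual binary resolutions; since clustering depends only on pairwise
value differences, any positive-slope affine transform of a variable gives
the same dendrogram.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .errors import UserInputError
from .phylo import leaf_labels, rf_symmetric_difference

logger = logging.getLogger(__name__)

LINKAGES = ("average", "single", "complete")


def read_env_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a samples x parameters table (TSV/CSV, sample labels in column 1)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise UserInputError(f"{path}: duplicate sample labels {dups}")
    return df


def env_dendrogram(
    values, labels: list[str] | None = None, method: str = "average",
    on_constant: str = "star",
) -> TreeNode:
    """Single-parameter dendrogram of samples.

    Samples are clustered agglomeratively (default UPGMA/average linkage) on
    the distance ``|x_i - x_j|``. Missing values drop the sample with a
    warning; fewer than 4 usable samples is an error. When every value is
    identical the result is a star tree with a warning (``on_constant=
    "error"`` raises instead). Branch lengths are merge-height differences;
    equal-height nested merges collapse into polytomies.
    """
    if method not in LINKAGES:
        raise UserInputError(f"unknown linkage {method!r}; expected one of {LINKAGES}")
    if isinstance(values, pd.Series):
        labels = list(values.index)
        values = values.to_numpy(dtype=float)
    else:
        values = np.asarray(values, dtype=float)
        if labels is None:
            raise UserInputError("labels are required when values is not a Series")
    if len(labels) != len(values):
        raise UserInputError("labels and values differ in length")

    keep = ~np.isnan(values)
    if (~keep).any():
        dropped = [l for l, k in zip(labels, keep) if not k]
        logger.warning("dropping samples with missing values: %s", dropped)
    labels = [l for l, k in zip(labels, keep) if k]
    values = values[keep]
    if len(values) < 4:
        raise UserInputError(f"need at least 4 samples with values, have {len(values)}")
    if np.ptp(values) == 0:
        if on_constant == "error":
            raise UserInputError("all values identical; dendrogram is degenerate")
        logger.warning("all values identical; returning a star dendrogram")
        root = TreeNode()
        for l in labels:
            root.append(TreeNode(name=l, length=0.0))
        return root

    z = linkage(pdist(values[:, None], metric="cityblock"), method=method)
    return _linkage_to_tree(z, labels)


def _linkage_to_tree(z: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix to a TreeNode, collapsing tied heights."""
    n = len(labels)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=labels[i]), 0.0) for i in range(n)
    }
    for k, (i, j, height, _) in enumerate(z):
        left, lh = nodes.pop(int(i))
        right, rh = nodes.pop(int(j))
        parent = TreeNode()
        for child, ch in ((left, lh), (right, rh)):
            child.length = max(0.0, height - ch)
            parent.append(child)
        nodes[n + k] = (parent, float(height))
    root = nodes.popitem()[1][0]
    # collapse zero-length internal edges (exact merge-height ties) into polytomies
    for node in list(root.traverse(include_self=False)):
        if node.children and node.length == 0.0 and node.parent is not None:
            parent = node.parent
            parent.remove(node)
            for child in list(node.children):
                node.remove(child)
                parent.append(child)
    return root


def rank_env_parameters(
    tree: TreeNode, env: pd.DataFrame, method: str = "average"
) -> pd.DataFrame:
    """Rank environmental parameters by topological similarity to a tree.

    Builds one dendrogram per numeric column of ``env`` and computes its
    Robinson–Foulds symmetric difference to ``tree``. Output has one row per
    parameter, sorted by ascending symmetric difference (most tree-like
    first), ties alphabetical. Columns that cannot be clustered (all-equal
    or too few values) are reported with a NaN difference.
    """
    tips = leaf_labels(tree)
    missing = tips - set(env.index)
    if missing:
        raise UserInputError(f"samples in tree but not in table: {sorted(missing)}")
    env = env.loc[sorted(tips)]
    rows = []
    for col in env.columns:
        values = pd.to_numeric(env[col], errors="coerce")
        try:
            dendro = env_dendrogram(values, method=method)
            sd = rf_symmetric_difference(tree, dendro)
        except UserInputError as exc:
            logger.warning("parameter %r skipped: %s", col, exc)
            sd = np.nan
        rows.append({"parameter": col, "symmetric_difference": sd})
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["symmetric_difference", "parameter"], na_position="last"
    ).reset_index(drop=True)
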