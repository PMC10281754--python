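"""Pairwise CpG co-methylation structure and hierarchical clustering.

Methylation at CpGs under a shared genetic signal is co-regulated, so their
beta values correlate across donors — positively within a regulatory block,
and sometimes negatively between blocks under one signal with opposing
effects.  We compute pairwise-complete Pearson correlations, then order CpGs
by average-linkage agglomerative clustering on the signed distance d = 1 - r,
which keeps anti-correlated blocks apart (d near 2) rather than merging them
as |r| would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DomainError

MIN_PAIRS = 3  # pairs with fewer complete observations are flagged missing


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: np.ndarray        # symmetric; NaN where a pair had < MIN_PAIRS observations
    n_pairs: np.ndarray  # pairwise-complete sample counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def correlation_matrix(beta_matrix: pd.DataFrame,
                       min_pairs: int = MIN_PAIRS) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation of a donors x CpGs beta matrix.

    Pairs with fewer than ``min_pairs`` complete observations are reported as
    NaN (missing, not fabricated).
    """
    df = pd.DataFrame(beta_matrix)
    labels = [str(c) for c in df.columns]
    r = df.corr(method="pearson", min_periods=min_pairs).to_numpy()
    notna = df.notna().astype(int).to_numpy()
    n_pairs = notna.T @ notna
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(labels, r, n_pairs)


def _condensed_distance(corr: CorrelationMatrix) -> np.ndarray:
    r = np.asarray(corr.r, dtype=float)
    if np.isnan(r).any():
        raise DomainError("correlation matrix has missing pairs; "
                          "drop the affected CpGs before clustering")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return squareform(d, checks=False)


def hierarchical_order(corr: CorrelationMatrix) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomeration on d = 1 - r.

    Returns ``(leaf_labels_in_dendrogram_order, linkage_matrix)`` where the
    linkage matrix is in scipy's standard (n-1) x 4 merge format.
    """
    z = hierarchy.linkage(_condensed_distance(corr), method="average")
    leaves = hierarchy.leaves_list(z)
    return [corr.labels[i] for i in leaves], z


def cluster_blocks(corr: CorrelationMatrix, cut_height: float) -> dict[str, int]:
    """Flat clusters by cutting the merge tree at ``cut_height`` on d = 1 - r.

    Two CpGs share a cluster iff they merged at or below the cut.  Cluster ids
    are renumbered in order of first appearance along the label list.
    """
    if not 0.0 <= cut_height <= 2.0:
        raise DomainError(f"cut_height {cut_height} outside [0, 2]")
    z = hierarchy.linkage(_condensed_distance(corr), method="average")
    raw = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, cid in zip(corr.labels, raw):
        if cid not in remap:
            remap[cid] = len(remap) + 1
        out[label] = remap[cid]
    return out


def merge_tree_json(corr: CorrelationMatrix) -> list[dict]:
    """The merge tree as a JSON-ready list of merges (for the report bundle)."""
    _, z = hierarchical_order(corr)
    n = len(corr.labels)

    def name(i: int) -> str | int:
        return corr.labels[i] if i < n else int(i)

    return [
        {"merge": int(n + k), "left": name(int(a)), "right": name(int(b)),
         "height": float(h), "size": int(s)}
        for k, (a, b, h, s) in enumerate(z)
    ]
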