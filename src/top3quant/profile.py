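"""Expression profiles: row z-scores and complete-linkage Pearson clustering.

Each protein's Top3 abundances are standardized across all injections,
z = (x - mu) / sigma with mu and sigma taken over both conditions pooled,
and the resulting matrix is clustered agglomeratively on both axes using
complete linkage with Pearson distance d = 1 - r. The outputs are
heatmap-ready: a z-matrix with row/column leaf orders plus Newick-exportable
dendrograms; rendering itself is left to any plotting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quantify import ProteinQuantMatrix

#: minimum mutually non-missing positions for a pairwise Pearson distance
MIN_SHARED = 3


@dataclass
class Dendrogram:
    """A scipy-format linkage matrix together with its leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class ZScoreProfile:
    """Row-standardized matrix plus (optional) dendrograms and leaf orders."""

    z: pd.DataFrame
    degenerate_rows: list[str] = field(default_factory=list)
    sd_convention: str = "sample"  # n-1 denominator; see zscore_rows
    row_tree: Dendrogram | None = None
    col_tree: Dendrogram | None = None
    excluded_rows: list[str] = field(default_factory=list)

    @property
    def row_order(self) -> list[str]:
        return self.row_tree.leaf_order if self.row_tree else list(self.z.index)

    @property
    def col_order(self) -> list[str]:
        return self.col_tree.leaf_order if self.col_tree else list(self.z.columns)

    def ordered(self) -> pd.DataFrame:
        rows = [r for r in self.row_order if r in self.z.index]
        return self.z.loc[rows, self.col_order]


def zscore_rows(
    matrix: ProteinQuantMatrix | pd.DataFrame, ddof: int = 1
) -> ZScoreProfile:
    """Standardize each protein's abundances across all injections.

    Missing cells stay missing. Rows with zero standard deviation (constant
    abundance) are emitted as all-zero and listed in ``degenerate_rows``
    rather than raising. ``ddof=1`` gives the sample-SD convention
    (default); ``ddof=0`` toggles the population convention. The convention
    used is recorded on the profile.
    """
    df = matrix.abundance if isinstance(matrix, ProteinQuantMatrix) else matrix
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=ddof)
    has_data = df.notna().any(axis=1)
    degenerate = sd.index[((sd == 0) | sd.isna()) & has_data].tolist()
    z = df.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    # constant rows: all-zero where observed, flagged rather than an error
    for row in degenerate:
        z.loc[row] = np.where(df.loc[row].notna(), 0.0, np.nan)
    return ZScoreProfile(
        z=z,
        degenerate_rows=[str(r) for r in degenerate],
        sd_convention="sample" if ddof == 1 else "population",
    )


def pearson_distance(a, b) -> float:
    """Pearson distance d = 1 - r over mutually non-missing positions.

    Requires at least ``MIN_SHARED`` shared positions and nonzero variance
    in both vectors; the result lies in [0, 2].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < MIN_SHARED:
        raise ValueError(
            f"need >= {MIN_SHARED} mutually non-missing positions, got {int(ok.sum())}"
        )
    x, y = a[ok], b[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance over shared positions")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 2.0))


def _pairwise_pearson_distance(df: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Full pairwise-complete Pearson distance matrix over rows of ``df``.

    Rows that cannot be placed (zero variance, or fewer than MIN_SHARED
    shared positions with some other row) are excluded and reported.
    """
    corr = df.T.corr(min_periods=MIN_SHARED)  # pairwise-complete Pearson
    # greedily drop the items with the most undefined pairwise distances
    # (e.g. opposite-condition exclusives share no runs) until none remain
    excluded: list[str] = []
    while True:
        nan_counts = corr.isna().sum(axis=1)
        if nan_counts.sum() == 0:
            break
        worst = nan_counts.idxmax()
        excluded.append(str(worst))
        corr = corr.drop(index=worst, columns=worst)
    usable = corr.index.tolist()
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return d, [str(u) for u in usable], excluded


def cluster_complete(z: pd.DataFrame, axis: str = "rows") -> tuple[Dendrogram, list[str]]:
    """Complete-linkage agglomerative clustering on Pearson distance.

    The inter-cluster distance is the maximum pairwise Pearson distance, so
    merge heights are non-decreasing. Returns the dendrogram and the list
    of items excluded for degeneracy (zero variance or insufficient
    overlap). Ties are resolved deterministically (scipy's ordering, which
    merges the smallest cluster indices first).
    """
    if axis not in {"rows", "cols"}:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    df = z if axis == "rows" else z.T
    d, labels, excluded = _pairwise_pearson_distance(df)
    if len(labels) < 2:
        raise ValueError("fewer than 2 clusterable items")
    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(linkage=Z, labels=labels), excluded


def cut_clusters(dend: Dendrogram, k: int) -> pd.Series:
    """Flat cluster labels from cutting the dendrogram into ``k`` groups."""
    flat = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return pd.Series(flat, index=dend.labels, name="cluster")


def profile_matrix(
    matrix: ProteinQuantMatrix | pd.DataFrame, ddof: int = 1
) -> ZScoreProfile:
    """z-score the matrix and cluster both axes; one-stop heatmap prep."""
    prof = zscore_rows(matrix, ddof=ddof)
    clusterable = prof.z.drop(index=prof.degenerate_rows, errors="ignore")
    row_tree, excluded = cluster_complete(clusterable, axis="rows")
    col_tree, _ = cluster_complete(prof.z.drop(index=prof.degenerate_rows,
                                               errors="ignore"), axis="cols")
    prof.row_tree = row_tree
    prof.col_tree = col_tree
    prof.excluded_rows = excluded
    return prof
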