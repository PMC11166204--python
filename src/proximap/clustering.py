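"""Effector-matrix construction and hierarchical clustering.

Preys are compared by Canberra distance between their WDS profiles over the
baits; baits by 1 - Pearson correlation over their prey profiles.  Both
axes are agglomerated with the classical (unsquared-dissimilarity) Ward
variant, historically known as "ward.D": the Lance-Williams recurrence with
Ward coefficients is applied to the dissimilarities exactly as given, never
squared.  The number of clusters is chosen by maximum mean silhouette width
computed on the same distance matrix, ties resolved toward the smallest k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .io_formats import AnnotationLists

__all__ = [
    "BaitPreyMatrix",
    "Dendrogram",
    "ClusterResult",
    "build_effector_matrix",
    "prey_distances",
    "bait_distances",
    "ward_cluster",
    "mean_silhouette",
    "select_k",
]


@dataclass
class BaitPreyMatrix:
    """bait x prey matrix of WDS scores; absent pairs are 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("WDS matrix must be nonnegative")

    @property
    def baits(self) -> list[str]:
        return list(self.values.index)

    @property
    def preys(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Merge history in scipy linkage format plus leaf identifiers."""

    linkage: np.ndarray  # (n-1, 4): idx_a, idx_b, height, size
    leaves: list[str]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (0-based) for a k-cluster cut."""
        return cut_tree(self.linkage, n_clusters=k).ravel()


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # index: leaf ids
    silhouette_profile: dict[int, float]


def build_effector_matrix(
    wds: pd.DataFrame, annotations: AnnotationLists | None = None
) -> BaitPreyMatrix:
    """Pivot filtered WDS scores to bait x prey, dropping GAP/GEF preys.

    ``wds`` needs columns bait, prey, wds (e.g. the filtered score table).
    """
    df = wds
    if annotations is not None:
        regulators = annotations.gap_ids | annotations.gef_ids
        df = df[~df["prey"].isin(regulators)]
    if df.empty:
        raise ValidationError("no preys left after removing GAPs and GEFs")
    mat = df.pivot_table(index="bait", columns="prey", values="wds",
                         aggfunc="max", fill_value=0.0)
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    if mat.shape[1] == 0:
        raise ValidationError("effector matrix is empty")
    return BaitPreyMatrix(values=mat)


def prey_distances(m: BaitPreyMatrix) -> pd.DataFrame:
    """Canberra distances between prey WDS profiles (0/0 terms contribute 0)."""
    if len(m.preys) < 2:
        raise ValidationError("need >=2 preys for distances")
    d = squareform(pdist(m.values.values.T, metric="canberra"))
    return pd.DataFrame(d, index=m.preys, columns=m.preys)


def bait_distances(m: BaitPreyMatrix) -> pd.DataFrame:
    """1 - Pearson correlation between bait WDS profiles."""
    if len(m.baits) < 2:
        raise ValidationError("need >=2 baits for distances")
    vals = m.values.values
    sd = vals.std(axis=1)
    flat = [b for b, s in zip(m.baits, sd) if s == 0]
    if flat:
        raise ValidationError(f"zero-variance bait profile(s): {flat}")
    d = 1.0 - np.corrcoef(vals)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=m.baits, columns=m.baits)


def ward_cluster(d: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerate with the Lance-Williams Ward update on raw dissimilarities.

    This is the "ward.D" variant: d(k, i+j) = ((n_i + n_k) d(k,i)
    + (n_j + n_k) d(k,j) - n_k d(i,j)) / (n_i + n_j + n_k), applied to the
    input dissimilarities as given (not squared).
    """
    if isinstance(d, pd.DataFrame):
        leaves = [str(x) for x in d.index]
        mat = d.values.astype(float)
    else:
        mat = np.asarray(d, dtype=float)
        leaves = [str(i) for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if np.isnan(mat).any():
        raise ValidationError("NaN in distance matrix")
    if not np.allclose(mat, mat.T, atol=1e-8) or (np.diag(mat) != 0).any():
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValidationError("need at least two leaves")

    work = mat.copy()
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)  # scipy-style ids; merged clusters get n, n+1, ...
    active = np.ones(n, dtype=bool)
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        height = work[i, j]
        ni, nj = sizes[i], sizes[j]
        a, b = sorted((cluster_id[i], cluster_id[j]))
        linkage[step] = (a, b, height, ni + nj)
        # Lance-Williams Ward update into slot i
        others = active.copy()
        others[[i, j]] = False
        nk = sizes[others]
        work[i, others] = (
            (ni + nk) * work[i, others] + (nj + nk) * work[j, others] - nk * height
        ) / (ni + nj + nk)
        work[others, i] = work[i, others]
        sizes[i] = ni + nj
        active[j] = False
        cluster_id[i] = next_id
        next_id += 1
    return Dendrogram(linkage=linkage, leaves=leaves)


def mean_silhouette(d: np.ndarray | pd.DataFrame, labels: np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    A singleton cluster's silhouette is defined as 0.
    """
    mat = d.values if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs >=2 clusters")
    n = len(labels)
    widths = np.zeros(n)
    for idx in range(n):
        own = labels[idx]
        same = (labels == own) & (np.arange(n) != idx)
        if not same.any():
            widths[idx] = 0.0  # singleton
            continue
        a = mat[idx, same].mean()
        b = min(mat[idx, labels == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        widths[idx] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def select_k(
    d: pd.DataFrame,
    dend: Dendrogram,
    k_range=range(2, 21),
) -> ClusterResult:
    """Choose the cut with maximal mean silhouette width (ties: smallest k)."""
    n = len(dend.leaves)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValidationError(f"k_range {list(k_range)!r} incompatible with {n} leaves")
    mat = d.loc[dend.leaves, dend.leaves]
    profile: dict[int, float] = {}
    for k in ks:
        labels = dend.cut(k)
        profile[k] = mean_silhouette(mat, labels)
    best_k = max(ks, key=lambda k: (profile[k], -k))
    if profile[best_k] < 0.25:
        warnings.warn(
            f"weak cluster structure: best mean silhouette {profile[best_k]:.3f} at k={best_k}"
        )
    labels = pd.Series(dend.cut(best_k), index=dend.leaves, name="cluster")
    return ClusterResult(k=best_k, labels=labels, silhouette_profile=profile)
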