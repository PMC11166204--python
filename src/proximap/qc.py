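"""Replicate quality control.

Biological replicates of a BioID purification are compared by Spearman rank
correlation of prey spectral counts (gate at rho >= 0.9) and by a classical
multidimensional-scaling embedding of all replicates; a replicate that fails
the correlation gate or that does not sit nearest to one of its siblings in
the embedding is flagged for re-acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import InteractionTable

__all__ = [
    "ReplicateMatrix",
    "QCReport",
    "replicate_matrices",
    "replicate_correlation",
    "qc_gate",
    "mds_embed",
    "replicate_grouping_check",
]


@dataclass
class ReplicateMatrix:
    """Prey x replicate spectral-count matrix for one bait in one cell line."""

    bait: str
    cell_line: str
    counts: pd.DataFrame  # index: prey ids, columns: replicate labels

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValidationError(f"bait {self.bait}: needs at least one replicate")
        if self.counts.index.has_duplicates:
            raise ValidationError(f"bait {self.bait}: duplicate prey ids")
        if (self.counts.values < 0).any():
            raise ValidationError(f"bait {self.bait}: negative counts")

    @property
    def replicate_labels(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class QCReport:
    pairwise_rho: pd.DataFrame
    flagged: set[str] = field(default_factory=set)
    embedding: pd.DataFrame | None = None  # index replicate, columns x, y


def replicate_matrices(table: InteractionTable) -> list[ReplicateMatrix]:
    """Expand per-record replicate counts into per-bait prey x replicate matrices."""
    out: list[ReplicateMatrix] = []
    for (bait, line), sub in table.df.groupby(["bait", "cell_line"], sort=True):
        reps = sub["replicate_specs"].dropna()
        if reps.empty:
            continue
        width = max(len(t) for t in reps)
        rows = {
            prey: list(t) + [0] * (width - len(t))
            for prey, t in zip(sub.loc[reps.index, "prey"], reps)
        }
        counts = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=[f"rep{i + 1}" for i in range(width)])
        out.append(ReplicateMatrix(bait=str(bait), cell_line=str(line), counts=counts))
    return out


def _spearman_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman over the union of preys, ties mid-ranked, zeros kept."""
    values = counts.values.astype(float)
    for j, label in enumerate(counts.columns):
        if not values[:, j].any():
            raise ValidationError(f"replicate {label!r} has all-zero counts")
    n = values.shape[1]
    rho = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.spearmanr(values[:, i], values[:, j]).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def replicate_correlation(m: ReplicateMatrix) -> QCReport:
    """Pairwise Spearman correlations between a bait's replicates."""
    if m.counts.shape[1] < 2:
        raise ValidationError(f"bait {m.bait}: need >=2 replicates for correlation QC")
    nonzero_preys = int((m.counts.values.sum(axis=1) > 0).sum())
    if nonzero_preys < 3:
        raise ValidationError(f"bait {m.bait}: fewer than 3 detected preys")
    return QCReport(pairwise_rho=_spearman_matrix(m.counts))


def qc_gate(report: QCReport, threshold: float = 0.9) -> set[str]:
    """Flag replicates whose correlation with *every* sibling is below threshold.

    With two replicates and a single sub-threshold correlation both are
    flagged (neither has a passing partner); with more replicates only the
    outlier(s) are.
    """
    rho = report.pairwise_rho
    flagged: set[str] = set()
    labels = list(rho.index)
    for label in labels:
        others = [o for o in labels if o != label]
        if not others:
            continue
        if all(rho.loc[label, o] < threshold for o in others):
            flagged.add(label)
    report.flagged |= flagged
    return flagged


def mds_embed(matrices: list[ReplicateMatrix] | pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of replicates on dissimilarity 1 - Spearman rho.

    Accepts either a list of per-bait matrices (pooled on the union of preys,
    absent preys as zero) or a prey x replicate DataFrame.  Returns centred
    (x, y) coordinates per replicate.
    """
    if isinstance(matrices, pd.DataFrame):
        pooled = matrices
    else:
        cols = {}
        for m in matrices:
            for label in m.counts.columns:
                key = f"{m.bait}:{label}"
                while key in cols:  # tolerate repeated bait ids
                    key += "'"
                cols[key] = m.counts[label]
        pooled = pd.DataFrame(cols).fillna(0.0)
    if pooled.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 pooled replicates")
    rho = _spearman_matrix(pooled)
    diss = 1.0 - rho.values
    if np.allclose(diss, 0.0):
        warnings.warn("all replicate profiles identical; MDS embedding degenerate")
        coords = np.zeros((diss.shape[0], 2))
        return pd.DataFrame(coords, index=rho.index, columns=["x", "y"])
    # Torgerson double centring of squared dissimilarities.
    d2 = diss ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    coords -= coords.mean(axis=0)
    return pd.DataFrame(coords, index=rho.index, columns=["x", "y"])


def replicate_grouping_check(
    coords: pd.DataFrame, groups: dict[str, list[str]]
) -> set[str]:
    """Flag replicates whose nearest embedded neighbour is not a group sibling."""
    flagged: set[str] = set()
    xy = coords[["x", "y"]]
    for bait, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"group {bait!r} has a single replicate; grouping check skipped")
            continue
        for label in members:
            deltas = xy.sub(xy.loc[label], axis=1)
            dist = np.hypot(deltas["x"], deltas["y"]).drop(index=label)
            nearest = dist.idxmin()
            if nearest not in members:
                flagged.add(label)
    return flagged


def qc_screen(table: InteractionTable, threshold: float = 0.9) -> pd.DataFrame:
    """Run the full QC gate over a screen; one row per replicate.

    Columns: cell_line, bait, replicate, min_rho, flag.
    """
    rows = []
    for m in replicate_matrices(table):
        if m.counts.shape[1] < 2 or (m.counts.values.sum(axis=1) > 0).sum() < 3:
            warnings.warn(
                f"bait {m.bait} ({m.cell_line}): too few replicates or preys for QC; skipped"
            )
            continue
        report = replicate_correlation(m)
        flagged = qc_gate(report, threshold=threshold)
        rho = report.pairwise_rho
        for label in m.replicate_labels:
            others = [o for o in m.replicate_labels if o != label]
            min_rho = min(rho.loc[label, o] for o in others) if others else np.nan
            rows.append(
                {
                    "cell_line": m.cell_line,
                    "bait": m.bait,
                    "replicate": label,
                    "min_rho": min_rho,
                    "flag": label in flagged,
                }
            )
    return pd.DataFrame(rows, columns=["cell_line", "bait", "replicate", "min_rho", "flag"])
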