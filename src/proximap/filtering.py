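"""High-confidence filter stack and cutpoint calibration.

A record survives iff AvgP >= avg_p_min AND AvgSpec >= the cell line's
avg_spec_min AND CAAX ratio >= caax_ratio_min AND the prey is not on the
contaminant blocklist.  All comparisons are inclusive.  The spectral-count
and CAAX-ratio cutpoints are calibrated against gold-standard recall labels
by receiver-operating-characteristic (Youden J) and cumulative-distribution
(maximum ECDF gap) analyses, restricted to a small set of well-characterised
calibration baits; adopting a calibrated cutpoint remains a user decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import GoldStandard, InteractionTable

__all__ = [
    "DEFAULT_BLOCKLIST",
    "FilterConfig",
    "FilterResult",
    "CutpointReport",
    "CalibrationResult",
    "apply_filters",
    "label_recall",
    "roc_cutpoint",
    "cda_cutpoint",
    "calibrate",
]

#: Contaminants removed by name: keratins, the BirA* ligase itself,
#: endogenous biotin-dependent carboxylases and bacterial beta-galactosidase.
DEFAULT_BLOCKLIST = frozenset(
    {
        "KRT1", "KRT2", "KRT5", "KRT6A", "KRT6B", "KRT8", "KRT9", "KRT10",
        "KRT14", "KRT16", "KRT17", "KRT18", "KRT19",
        "BIRA",
        "PC", "PCCA", "PCCB", "MCCC1", "MCCC2", "ACACA", "ACACB",
        "LACZ",
    }
)

# Attrition is attributed to the first failing filter in this order.
_FILTER_ORDER = ("avg_p", "avg_spec", "caax_ratio", "blocklist")


@dataclass(frozen=True)
class FilterConfig:
    avg_p_min: float = 0.95
    avg_spec_min: dict[str, float] = field(
        default_factory=lambda: {"HEK293": 4.5, "HeLa": 6.0}
    )
    caax_ratio_min: float = 1.7
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST

    def __post_init__(self) -> None:
        if not (0 <= self.avg_p_min <= 1):
            raise ValidationError("avg_p_min must be in [0, 1]")
        if any(v < 0 for v in self.avg_spec_min.values()) or self.caax_ratio_min < 0:
            raise ValidationError("thresholds must be >= 0")

    def with_thresholds(self, avg_spec_min: float, caax_ratio_min: float) -> "FilterConfig":
        return replace(
            self,
            avg_spec_min={k: avg_spec_min for k in self.avg_spec_min} or {"*": avg_spec_min},
            caax_ratio_min=caax_ratio_min,
        )


@dataclass
class FilterResult:
    kept: pd.DataFrame
    attrition: dict[str, int]  # records_in, removed per filter, records_out

    def check_accounting(self) -> bool:
        removed = sum(self.attrition[f"removed_{k}"] for k in _FILTER_ORDER)
        return self.attrition["records_in"] - removed == self.attrition["records_out"]


@dataclass
class CutpointReport:
    score_name: str
    roc_points: pd.DataFrame | None = None  # threshold, sensitivity, specificity, youden_j
    auc: float | None = None
    roc_cutpoint: float | None = None
    cda_curve: pd.DataFrame | None = None  # score, ecdf_pos, ecdf_neg, gap
    cda_cutpoint: float | None = None


@dataclass
class CalibrationResult:
    reports: dict[str, CutpointReport]
    ranked: pd.DataFrame  # avg_spec_min, caax_ratio_min, precision, recall, rank


def _scored(table: InteractionTable, scores: pd.DataFrame | None) -> pd.DataFrame:
    """Non-control records with a caax_ratio column attached."""
    rec = table.noncontrol()[["bait", "prey", "cell_line", "avg_spec", "avg_p"]].copy()
    if scores is not None and "caax_ratio" in scores.columns:
        rec = rec.merge(
            scores[["bait", "prey", "cell_line", "caax_ratio"]],
            on=["bait", "prey", "cell_line"],
            how="left",
        )
        rec["caax_ratio"] = rec["caax_ratio"].fillna(np.inf)
    elif "caax" in table.controls:
        from .scoring import caax_ratio as _caax

        rec = rec.merge(_caax(table), on=["bait", "prey", "cell_line"], how="left")
        rec["caax_ratio"] = rec["caax_ratio"].fillna(np.inf)
    else:
        rec["caax_ratio"] = np.inf
    return rec


def apply_filters(
    table: InteractionTable,
    config: FilterConfig,
    scores: pd.DataFrame | None = None,
) -> FilterResult:
    """Apply the conjunctive filter stack; returns survivors plus attrition counts."""
    rec = _scored(table, scores)
    lines = set(rec["cell_line"].unique())
    known = set(config.avg_spec_min)
    if "*" not in known and not lines <= known:
        raise ValidationError(
            f"no avg_spec_min configured for cell line(s) {sorted(lines - known)}"
        )
    spec_min = rec["cell_line"].map(
        lambda l: config.avg_spec_min.get(l, config.avg_spec_min.get("*"))
    )
    pass_p = rec["avg_p"] >= config.avg_p_min
    pass_spec = rec["avg_spec"] >= spec_min
    pass_caax = rec["caax_ratio"] >= config.caax_ratio_min
    pass_block = ~rec["prey"].isin(config.blocklist)

    fails = {
        "avg_p": ~pass_p,
        "avg_spec": pass_p & ~pass_spec,
        "caax_ratio": pass_p & pass_spec & ~pass_caax,
        "blocklist": pass_p & pass_spec & pass_caax & ~pass_block,
    }
    kept = rec[pass_p & pass_spec & pass_caax & pass_block].reset_index(drop=True)
    attrition = {"records_in": len(rec)}
    for name in _FILTER_ORDER:
        attrition[f"removed_{name}"] = int(fails[name].sum())
    attrition["records_out"] = len(kept)
    return FilterResult(kept=kept, attrition=attrition)


def label_recall(records: pd.DataFrame, gold: GoldStandard) -> pd.DataFrame:
    """Attach binary recall labels from the gold standard.

    Only records whose bait is in ``gold.bait_subset`` are retained (the
    calibration baits); label 1 iff (bait, prey) is a gold edge.
    """
    if not gold.edges:
        raise ValidationError("gold standard has no edges")
    baits = gold.bait_subset or {b for b, _ in gold.edges}
    sub = records[records["bait"].isin(baits)].copy()
    pairs = set(gold.edges)
    sub["label"] = [
        1 if (b, p) in pairs else 0 for b, p in zip(sub["bait"], sub["prey"])
    ]
    if sub.empty or sub["label"].sum() == 0:
        raise ValidationError("no positive recall labels among calibration-bait records")
    return sub.reset_index(drop=True)


def _check_classes(labels: np.ndarray) -> None:
    if labels.sum() == 0:
        raise ValidationError("no positive labels")
    if labels.sum() == len(labels):
        raise ValidationError("no negative labels")


def roc_cutpoint(scores, labels, score_name: str = "score") -> CutpointReport:
    """ROC over all distinct observed thresholds (keep iff score >= t).

    The cutpoint maximises Youden J = sensitivity + specificity - 1, ties
    resolved toward the smallest threshold; AUC by the trapezoid rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    _check_classes(y)
    thresholds = np.unique(s)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    sens = np.array([(s[y == 1] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(s[y == 0] < t).sum() / n_neg for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (= smallest threshold) tie
    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec, "youden_j": j}
    )
    # trapezoid over the full step curve, endpoints (0,0) and (1,1) included
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])[::-1]
    tpr = np.concatenate([[1.0], sens, [0.0]])[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return CutpointReport(
        score_name=score_name,
        roc_points=points,
        auc=auc,
        roc_cutpoint=float(thresholds[best]),
    )


def cda_cutpoint(scores, labels, score_name: str = "score") -> CutpointReport:
    """Cumulative-distribution cutpoint: the score maximising F_neg - F_pos.

    This is the Kolmogorov-Smirnov location of the two empirical CDFs; ties
    resolve to the smallest score, and an all-zero gap (indistinguishable
    classes) is reported with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    grid = np.unique(s)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    f_pos = np.searchsorted(pos, grid, side="right") / len(pos)
    f_neg = np.searchsorted(neg, grid, side="right") / len(neg)
    gap = f_neg - f_pos
    best = int(np.argmax(gap))
    if gap[best] <= 0:
        warnings.warn("positive and negative score distributions are indistinguishable")
    curve = pd.DataFrame({"score": grid, "ecdf_pos": f_pos, "ecdf_neg": f_neg, "gap": gap})
    return CutpointReport(
        score_name=score_name,
        cda_curve=curve,
        cda_cutpoint=float(grid[best]),
    )


def calibrate(
    table: InteractionTable,
    gold: GoldStandard,
    grid_avg_spec,
    grid_caax_ratio,
    *,
    config: FilterConfig | None = None,
    scores: pd.DataFrame | None = None,
    precision_target: float = 0.95,
) -> CalibrationResult:
    """Estimate AvgSpec / CAAX-ratio cutpoints from gold-standard recall.

    The AvgP pre-filter is applied first (at ``config.avg_p_min``); recall
    labels come from the gold standard restricted to its calibration baits.
    Per-score ROC and CDA cutpoint reports are computed, and the supplied
    threshold grid is ranked by recall among configurations meeting the
    precision target (ties toward smaller thresholds).  The final choice of
    thresholds is left to the user.
    """
    grid_avg_spec = list(grid_avg_spec)
    grid_caax = list(grid_caax_ratio)
    if not grid_avg_spec or not grid_caax:
        raise ValidationError("empty calibration grid")
    config = config or FilterConfig()
    rec = _scored(table, scores)
    rec = rec[rec["avg_p"] >= config.avg_p_min]
    labelled = label_recall(rec, gold)
    y = labelled["label"].to_numpy()
    if y.all():
        raise ValidationError("all calibration records are labelled positive")

    reports = {
        "avg_spec": _merge_reports(
            roc_cutpoint(labelled["avg_spec"], y, "avg_spec"),
            cda_cutpoint(labelled["avg_spec"], y, "avg_spec"),
        ),
        "caax_ratio": _merge_reports(
            roc_cutpoint(_finite(labelled["caax_ratio"]), y, "caax_ratio"),
            cda_cutpoint(_finite(labelled["caax_ratio"]), y, "caax_ratio"),
        ),
    }

    rows = []
    spec_v = labelled["avg_spec"].to_numpy()
    caax_v = labelled["caax_ratio"].to_numpy()
    for a in grid_avg_spec:
        for c in grid_caax:
            kept = (spec_v >= a) & (caax_v >= c)
            tp = int((kept & (y == 1)).sum())
            precision = tp / kept.sum() if kept.any() else np.nan
            recall = tp / y.sum()
            rows.append(
                {"avg_spec_min": a, "caax_ratio_min": c,
                 "precision": precision, "recall": recall}
            )
    ranked = pd.DataFrame(rows)
    meets = ranked["precision"] >= precision_target
    ranked["meets_precision_target"] = meets
    ranked = ranked.sort_values(
        by=["meets_precision_target", "recall", "precision",
            "avg_spec_min", "caax_ratio_min"],
        ascending=[False, False, False, True, True],
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return CalibrationResult(reports=reports, ranked=ranked)


def _finite(values: pd.Series) -> np.ndarray:
    """Clip +inf CAAX ratios to just above the largest finite observation."""
    v = values.to_numpy(dtype=float)
    finite = v[np.isfinite(v)]
    cap = (finite.max() if finite.size else 1.0) * 2 + 1
    return np.where(np.isfinite(v), v, cap)


def _merge_reports(roc: CutpointReport, cda: CutpointReport) -> CutpointReport:
    roc.cda_curve = cda.cda_curve
    roc.cda_cutpoint = cda.cda_cutpoint
    return roc
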