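"""Per-interaction derived scores.

The central quantity is the CompPASS-family WD specificity score, computed
per cell line and per (bait, prey) pair as

    WD(b, p) = sqrt( Xbar(b, p) * ( (K / f(p)) * omega(p) ) ** n(b, p) )

where Xbar is the average spectral count, K the number of non-control baits
in the screen, f(p) the number of those baits that detect prey p,
n(b, p) the number of replicates of bait b detecting p (1 when replicate
counts are unavailable), and omega(p) = max(1, sd/mean of Xbar over the f(p)
detecting baits) an across-bait variability weight (omega = 1 when f = 1).
A prey seen in every purification at comparable abundance is penalised by
frequency; a prey seen reproducibly in one bait at high counts is rewarded.

The two cell lines' WD scores are pooled by summation into the WDS score,
with absence in one line contributing zero.  The module also computes the
CAAX membrane-control enrichment ratio, the log2 fold change against the
mean of the negative controls, and the complexity-based normalised spectral
count (CBNP), which rescales counts by the median purification complexity.

Control purifications never enter K, f or omega: they define background,
not specificity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import InteractionTable

__all__ = [
    "compute_wd",
    "sum_wds",
    "caax_ratio",
    "log2fc_controls",
    "cbnp",
    "score_table",
]


def _avg_spec_pivot(df: pd.DataFrame) -> pd.DataFrame:
    """bait x prey AvgSpec matrix (absent pairs 0)."""
    return df.pivot_table(index="bait", columns="prey", values="avg_spec",
                          aggfunc="sum", fill_value=0.0)


def compute_wd(table: InteractionTable, cell_line: str) -> pd.DataFrame:
    """WD score per (bait, prey) for one cell line.

    Returns a DataFrame with columns bait, prey, cell_line, wd covering every
    pair with a nonzero average spectral count (wd = 0 rows for detected-at-
    zero records are omitted since AvgSpec = 0 implies WD = 0).
    """
    sub = table.subset(cell_line)
    sub = sub[~sub["is_control"]]
    if sub.empty or sub["bait"].nunique() == 0:
        raise ValidationError(f"no non-control baits in cell line {cell_line!r}")
    x = _avg_spec_pivot(sub)  # baits x preys
    k = x.shape[0]
    detected = x.values > 0
    f = detected.sum(axis=0)  # per prey
    keep = f > 0
    x = x.loc[:, keep]
    detected = detected[:, keep]
    f = f[keep]

    vals = x.values
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = vals.sum(axis=0)
        means = sums / f
        # sample sd over the detecting baits only
        sq = (np.where(detected, vals - means, 0.0) ** 2).sum(axis=0)
        sd = np.sqrt(np.where(f > 1, sq / np.maximum(f - 1, 1), 0.0))
        omega = np.where(f > 1, np.maximum(1.0, sd / means), 1.0)

    # replicate detections n(b, p): from replicate_specs when present, else 1
    n_mat = np.ones_like(vals)
    has_reps = sub["replicate_specs"].notna()
    if has_reps.any():
        reps = sub[has_reps]
        bait_idx = x.index.get_indexer(reps["bait"])
        prey_idx = x.columns.get_indexer(reps["prey"])
        n_det = reps["replicate_specs"].map(lambda t: sum(1 for c in t if c > 0)).values
        ok = (bait_idx >= 0) & (prey_idx >= 0)
        n_mat[bait_idx[ok], prey_idx[ok]] = np.maximum(n_det[ok], 1)

    base = (k / f) * omega
    wd = np.sqrt(vals * base[np.newaxis, :] ** n_mat)
    wd[~detected] = 0.0

    out = pd.DataFrame(wd, index=x.index, columns=x.columns).stack()
    out = out[out > 0].rename("wd").reset_index()
    out.columns = ["bait", "prey", "wd"]
    out.insert(2, "cell_line", cell_line)
    return out


def sum_wds(wd_a: pd.DataFrame, wd_b: pd.DataFrame) -> pd.DataFrame:
    """Pool two cell lines' WD tables into the summed WDS score.

    A pair missing from one line contributes 0; pairs absent from both are
    not emitted.  The two inputs must come from distinct cell lines.
    """
    lines_a = set(wd_a["cell_line"].unique())
    lines_b = set(wd_b["cell_line"].unique())
    if lines_a & lines_b:
        raise ValidationError(f"sum_wds called with the same cell line twice: {lines_a & lines_b}")
    merged = pd.merge(
        wd_a[["bait", "prey", "wd"]],
        wd_b[["bait", "prey", "wd"]],
        on=["bait", "prey"],
        how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0.0)
    merged["wds"] = merged["wd_a"] + merged["wd_b"]
    return merged[["bait", "prey", "wds"]].sort_values(["bait", "prey"]).reset_index(drop=True)


def caax_ratio(table: InteractionTable) -> pd.DataFrame:
    """AvgSpec enrichment of each bait over the membrane-targeted CAAX control.

    ratio = Xbar(bait, prey) / Xbar(caax, prey); a prey absent from the CAAX
    control gives +inf (maximal enrichment, passes any finite cutoff).
    """
    caax_bait = table.controls.get("caax")
    if caax_bait is None:
        raise ValidationError("no CAAX control configured")
    frames = []
    for line in table.cell_lines:
        sub = table.subset(line)
        caax = sub[sub["bait"] == caax_bait]
        if caax.empty:
            raise ValidationError(f"CAAX control {caax_bait!r} absent from cell line {line!r}")
        caax_spec = caax.set_index("prey")["avg_spec"]
        rec = sub[~sub["is_control"]][["bait", "prey", "cell_line", "avg_spec"]].copy()
        denom = rec["prey"].map(caax_spec).fillna(0.0).values
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, rec["avg_spec"].values / denom, np.inf)
        # 0/0: undetected pair over undetected control counts as absent, not enriched
        ratio = np.where((rec["avg_spec"].values == 0) & (denom == 0), 0.0, ratio)
        rec["caax_ratio"] = ratio
        frames.append(rec[["bait", "prey", "cell_line", "caax_ratio"]])
    return pd.concat(frames, ignore_index=True)


def log2fc_controls(table: InteractionTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 fold change of each record against the mean of the negative controls.

    Negative controls are the non-CAAX control purifications (empty vector
    and soluble GFP).  A pseudocount keeps the ratio finite for zero counts.
    """
    neg_baits = [b for role, b in table.controls.items() if role != "caax"]
    if not neg_baits:
        raise ValidationError("no non-CAAX negative control configured")
    frames = []
    for line in table.cell_lines:
        sub = table.subset(line)
        ctrl = sub[sub["bait"].isin(neg_baits)]
        ctrl_mean = ctrl.pivot_table(index="prey", values="avg_spec", aggfunc="sum")
        ctrl_mean = ctrl_mean["avg_spec"] / len(neg_baits)  # absent control records count 0
        rec = sub[~sub["is_control"]][["bait", "prey", "cell_line", "avg_spec"]].copy()
        mean = rec["prey"].map(ctrl_mean).fillna(0.0).values
        rec["log2fc"] = np.log2((rec["avg_spec"].values + pseudocount) / (mean + pseudocount))
        frames.append(rec[["bait", "prey", "cell_line", "log2fc"]])
    return pd.concat(frames, ignore_index=True)


def cbnp(table: InteractionTable) -> pd.DataFrame:
    """Complexity-based normalised spectral counts.

    cbnp(b, p) = Xbar(b, p) * median_b' N(b') / N(b) with N(b) the number of
    distinct preys detected with bait b in that cell line, so counts from
    low-complexity purifications are scaled up and vice versa.
    """
    frames = []
    for line in table.cell_lines:
        sub = table.subset(line)
        rec = sub[~sub["is_control"]]
        n_by_bait = rec[rec["avg_spec"] > 0].groupby("bait")["prey"].nunique()
        empty = set(rec["bait"].unique()) - set(n_by_bait.index)
        for bait in sorted(empty):
            warnings.warn(f"bait {bait!r} identified no preys in {line!r}; skipped for CBNP")
        if n_by_bait.empty:
            continue
        median_n = float(n_by_bait.median())
        keep = rec[rec["bait"].isin(n_by_bait.index)][
            ["bait", "prey", "cell_line", "avg_spec"]
        ].copy()
        keep["cbnp"] = keep["avg_spec"].values * median_n / keep["bait"].map(n_by_bait).values
        frames.append(keep[["bait", "prey", "cell_line", "cbnp"]])
    if not frames:
        raise ValidationError("no bait identified any prey; CBNP undefined")
    return pd.concat(frames, ignore_index=True)


def score_table(table: InteractionTable) -> pd.DataFrame:
    """All derived scores in one long table.

    Columns: bait, prey, cell_line, avg_spec, avg_p, wd, wds, caax_ratio,
    log2fc, cbnp.  WDS is attached to every cell line's rows of a pair.  In a
    single-cell-line screen WDS equals WD.
    """
    lines = table.cell_lines
    wd_frames = [compute_wd(table, line) for line in lines]
    wd_all = pd.concat(wd_frames, ignore_index=True)
    if len(wd_frames) == 2:
        wds = sum_wds(wd_frames[0], wd_frames[1])
    elif len(wd_frames) == 1:
        wds = wd_all[["bait", "prey", "wd"]].rename(columns={"wd": "wds"})
    else:
        raise ValidationError(f"score_table supports 1 or 2 cell lines, got {len(lines)}")

    base = table.noncontrol()[["bait", "prey", "cell_line", "avg_spec", "avg_p"]].copy()
    out = base.merge(wd_all, on=["bait", "prey", "cell_line"], how="left")
    out["wd"] = out["wd"].fillna(0.0)
    out = out.merge(wds, on=["bait", "prey"], how="left")
    out["wds"] = out["wds"].fillna(0.0)
    if "caax" in table.controls:
        out = out.merge(caax_ratio(table), on=["bait", "prey", "cell_line"], how="left")
    else:
        out["caax_ratio"] = np.inf
    neg = [r for r in table.controls if r != "caax"]
    if neg:
        out = out.merge(log2fc_controls(table), on=["bait", "prey", "cell_line"], how="left")
    else:
        out["log2fc"] = np.nan
    out = out.merge(cbnp(table), on=["bait", "prey", "cell_line"], how="left")
    return out.reset_index(drop=True)
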