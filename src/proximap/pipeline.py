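"""End-to-end orchestration: QC -> scoring -> filtering -> clustering -> localization.

A declarative :class:`PipelineConfig` (loadable from YAML) names the input
tables per cell line, the control bait ids, the filter thresholds, clustering
options and annotation resources.  :func:`run_pipeline` materialises one
artifact directory with per-stage TSV outputs and a ``report.json`` carrying
per-stage record counts; it is deterministic given inputs and seed.  With a
single cell line the WDS score degenerates to the WD score and cross-line
overlap summaries are suppressed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, localization, qc, scoring
from .errors import ProximapError, ValidationError
from .filtering import FilterConfig, apply_filters
from .io_formats import (
    AnnotationLists,
    InteractionTable,
    read_annotation_list,
    read_interaction_table,
    read_marker_sets,
    write_dotplot_table,
    write_network,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_overlap"]


@dataclass
class PipelineConfig:
    inputs: dict[str, str]  # cell line -> SAINT-style TSV path
    controls: dict[str, str]  # role -> bait id
    output_dir: str
    dialect: str = "saint_tsv"
    filter: FilterConfig = field(default_factory=FilterConfig)
    qc_threshold: float = 0.9
    exclude_replicates: list[str] = field(default_factory=list)
    k_range: tuple[int, int] = (2, 20)
    cluster_axes: tuple[str, ...] = ("prey", "bait")
    atlas_path: str | None = None
    gap_path: str | None = None
    gef_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = raw.pop("filter", None)
        cfg = cls(**raw)
        if filt:
            blocklist = filt.pop("blocklist", None)
            fc = FilterConfig(
                avg_p_min=filt.get("avg_p_min", 0.95),
                avg_spec_min=filt.get("avg_spec_min", {"HEK293": 4.5, "HeLa": 6.0}),
                caax_ratio_min=filt.get("caax_ratio_min", 1.7),
                blocklist=frozenset(blocklist) if blocklist is not None
                else FilterConfig().blocklist,
            )
            cfg.filter = fc
        return cfg

    def validate_paths(self) -> None:
        for line, path in self.inputs.items():
            if not Path(path).exists():
                raise ValidationError(f"input for {line!r} not found: {path}")
        for p in (self.atlas_path, self.gap_path, self.gef_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"resource not found: {p}")


def _load_tables(cfg: PipelineConfig) -> InteractionTable:
    frames = []
    for line, path in sorted(cfg.inputs.items()):
        t = read_interaction_table(path, dialect=cfg.dialect,
                                   controls=cfg.controls, cell_line=line)
        df = t.df.copy()
        df["cell_line"] = df["cell_line"].where(df["cell_line"].notna(), line)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return InteractionTable(df=merged, controls=dict(cfg.controls))


def summarize_overlap(filtered: pd.DataFrame) -> dict:
    """Per-line and shared interaction counts (bait-prey pairs and unique preys)."""
    lines = sorted(filtered["cell_line"].unique())
    if len(lines) != 2:
        raise ValidationError("overlap summary needs exactly two cell lines")
    sets = {
        line: set(map(tuple, filtered[filtered["cell_line"] == line][["bait", "prey"]].values))
        for line in lines
    }
    shared = sets[lines[0]] & sets[lines[1]]
    preys = {line: {p for _, p in pairs} for line, pairs in sets.items()}
    return {
        "pairs": {lines[0]: len(sets[lines[0]]), lines[1]: len(sets[lines[1]]),
                  "shared": len(shared)},
        "unique_preys": {lines[0]: len(preys[lines[0]]), lines[1]: len(preys[lines[1]]),
                         "shared": len(preys[lines[0]] & preys[lines[1]])},
    }


def run_pipeline(cfg: PipelineConfig, table: InteractionTable | None = None) -> dict:
    """Run every stage and write the artifact directory; returns the report.

    On a stage failure the exception is re-raised with the stage name and a
    MANIFEST file marks the output as incomplete.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages": []}
    report: dict = {"seed": cfg.seed, "stages": {}}

    def _stage(name: str):
        manifest["stages"].append(name)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return name

    try:
        _stage("load")
        if table is None:
            cfg.validate_paths()
            table = _load_tables(cfg)
        lines = table.cell_lines
        report["stages"]["load"] = {
            "records_in": int(len(table.df)),
            "cell_lines": lines,
            "n_baits": int(table.noncontrol()["bait"].nunique()),
        }

        _stage("qc")
        (out / "qc").mkdir(exist_ok=True)
        qc_table = qc.qc_screen(table, threshold=cfg.qc_threshold)
        qc_table.to_csv(out / "qc" / "replicate_qc.tsv", sep="\t", index=False)
        report["stages"]["qc"] = {
            "replicates": int(len(qc_table)),
            "flagged": sorted(
                f"{b}:{r}" for b, r in qc_table[qc_table["flag"]][["bait", "replicate"]].values
            ),
        }

        _stage("scores")
        (out / "scores").mkdir(exist_ok=True)
        scores = scoring.score_table(table)
        scores.to_csv(out / "scores" / "scores.tsv", sep="\t", index=False)
        report["stages"]["scores"] = {"records": int(len(scores))}

        _stage("filtered")
        (out / "filtered").mkdir(exist_ok=True)
        result = apply_filters(table, cfg.filter, scores=scores)
        filtered = result.kept.merge(
            scores[["bait", "prey", "cell_line", "wd", "wds", "log2fc", "cbnp"]],
            on=["bait", "prey", "cell_line"], how="left",
        )
        filtered.to_csv(out / "filtered" / "interactions.tsv", sep="\t", index=False)
        write_network(filtered, out / "filtered" / "network.tsv", format="edge_tsv")
        write_dotplot_table(filtered, out / "filtered" / "dotplot.tsv")
        report["stages"]["filtered"] = dict(result.attrition)
        if not result.check_accounting():
            raise ValidationError("filter attrition counts do not sum to records_out")
        if len(lines) == 2:
            report["stages"]["overlap"] = summarize_overlap(filtered)

        _stage("clusters")
        (out / "clusters").mkdir(exist_ok=True)
        annotations = AnnotationLists(
            gap_ids=read_annotation_list(cfg.gap_path) if cfg.gap_path else set(),
            gef_ids=read_annotation_list(cfg.gef_path) if cfg.gef_path else set(),
        )
        report["stages"]["clusters"] = {}
        if len(filtered) == 0:
            warnings.warn("no filtered interactions; clustering skipped")
        else:
            matrix = clustering.build_effector_matrix(filtered, annotations)
            k_lo, k_hi = cfg.k_range
            for axis in cfg.cluster_axes:
                if axis == "prey":
                    d = clustering.prey_distances(matrix)
                else:
                    d = clustering.bait_distances(matrix)
                if len(d) < 3:
                    warnings.warn(f"too few {axis}s to cluster; skipped")
                    continue
                dend = clustering.ward_cluster(d)
                res = clustering.select_k(d, dend, range(k_lo, k_hi + 1))
                res.labels.rename("cluster").to_frame().assign(axis=axis).to_csv(
                    out / "clusters" / f"{axis}_clusters.tsv", sep="\t")
                pd.DataFrame(
                    dend.linkage, columns=["child_a", "child_b", "height", "size"]
                ).to_csv(out / "clusters" / f"{axis}_merges.tsv", sep="\t", index=False)
                pd.Series(res.silhouette_profile, name="mean_silhouette").rename_axis(
                    "k").to_csv(out / "clusters" / f"{axis}_silhouette.tsv", sep="\t")
                report["stages"]["clusters"][axis] = {
                    "k": res.k,
                    "mean_silhouette": res.silhouette_profile[res.k],
                }

        _stage("localization")
        (out / "localization").mkdir(exist_ok=True)
        if cfg.atlas_path and len(filtered):
            atlas = read_marker_sets(cfg.atlas_path)
            calls = localization.localize_baits(filtered, atlas)
            calls.to_csv(out / "localization" / "calls.tsv", sep="\t", index=False)
            top = calls[calls["rank"] == 1][["bait", "compartment"]]
            report["stages"]["localization"] = {
                "baits": int(top["bait"].nunique()),
                "top_compartment": dict(zip(top["bait"], top["compartment"])),
            }
        else:
            report["stages"]["localization"] = {"skipped": True}

        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["complete"] = True
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return report
    except ProximapError as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise type(exc)(f"pipeline failed at stage {stage!r}: {exc}") from exc
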