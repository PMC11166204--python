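"""Readers and writers for the tabular formats the pipeline touches.

Supported inputs are SAINT-style bait-prey result tables (TSV), BioGRID-style
tab-delimited edge lists used as a recall gold standard, and GMT marker-set
files describing subcellular compartments.  Outputs are plain edge TSV / SIF
network files and a long-format dot-plot table.

Prey identity throughout is the gene symbol; accession columns, when present,
are carried as opaque metadata and never interpreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "InteractionTable",
    "GoldStandard",
    "CompartmentAtlas",
    "AnnotationLists",
    "CONTROL_ROLES",
    "read_interaction_table",
    "write_interaction_table",
    "read_gold_standard",
    "read_marker_sets",
    "read_annotation_list",
    "write_network",
    "write_dotplot_table",
]

#: Recognised control-purification roles: the empty BirA*-Flag vector, the
#: soluble BirA*-Flag-eGFP fusion and the membrane-targeted CAAX construct.
CONTROL_ROLES = ("empty_vector", "gfp", "caax")

# Canonical internal column order for interaction tables.
_COLUMNS = ["bait", "prey", "cell_line", "avg_spec", "avg_p", "replicate_specs", "is_control"]

# Column aliases accepted for the saint_tsv dialect (SAINTexpress "list" output).
_SAINT_ALIASES = {
    "bait": ("Bait",),
    "prey": ("PreyGene", "Prey"),
    "avg_spec": ("AvgSpec",),
    "avg_p": ("AvgP",),
    "spec": ("Spec",),
    "cell_line": ("CellLine", "Cell_line"),
}
_GENERIC_ALIASES = {
    "bait": ("bait",),
    "prey": ("prey",),
    "avg_spec": ("avg_spec",),
    "avg_p": ("avg_p",),
    "spec": ("spec", "replicate_specs"),
    "cell_line": ("cell_line",),
}


@dataclass
class InteractionTable:
    """One row per bait x prey x cell-line with counts and SAINT probability.

    ``df`` columns: bait, prey, cell_line, avg_spec, avg_p,
    replicate_specs (tuple of ints or None), is_control (bool).
    ``controls`` maps a control role (see :data:`CONTROL_ROLES`) to a bait id.
    """

    df: pd.DataFrame
    controls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"interaction table missing columns: {missing}")
        if len(df) == 0:
            return
        if (df["bait"].astype(str).str.len() == 0).any():
            raise ValidationError("empty bait_id")
        bad_p = df[(df["avg_p"] < 0) | (df["avg_p"] > 1)]
        if len(bad_p):
            raise ValidationError(
                f"avg_p outside [0, 1] at row(s) {list(bad_p.index[:5])}"
            )
        if (df["avg_spec"] < 0).any():
            raise ValidationError("negative avg_spec")
        dup = df.duplicated(subset=["bait", "prey", "cell_line"])
        if dup.any():
            raise ValidationError(
                f"duplicate (bait, prey, cell_line) at row(s) {list(df.index[dup][:5])}"
            )
        has_reps = df["replicate_specs"].notna()
        if has_reps.any():
            sub = df[has_reps]
            means = sub["replicate_specs"].map(lambda t: float(np.mean(t)))
            off = (means - sub["avg_spec"]).abs() > 1e-9
            if off.any():
                raise ValidationError(
                    "avg_spec disagrees with mean(replicate_specs) at row(s) "
                    f"{list(sub.index[off][:5])}"
                )
        roles = list(self.controls)
        if len(set(self.controls.values())) != len(roles):
            # distinct roles must name distinct baits
            raise ValidationError("control_bait_ids must be distinct across roles")

    @property
    def control_baits(self) -> set[str]:
        return set(self.controls.values())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.df["cell_line"].unique())

    def subset(self, cell_line: str) -> pd.DataFrame:
        return self.df[self.df["cell_line"] == cell_line]

    def noncontrol(self) -> pd.DataFrame:
        return self.df[~self.df["is_control"]]


@dataclass
class GoldStandard:
    """Physical-interaction edges used as positive recall labels."""

    edges: set[tuple[str, str]]
    source_tag: str = ""
    bait_subset: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.bait_subset:
            in_edges = {b for b, _ in self.edges}
            if not self.bait_subset <= in_edges:
                raise ValidationError(
                    "bait_subset contains baits absent from the edge list: "
                    f"{sorted(self.bait_subset - in_edges)}"
                )


@dataclass
class CompartmentAtlas:
    """Subcellular compartment name -> marker prey symbols."""

    compartments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.compartments.items():
            if not members:
                raise ValidationError(f"compartment {name!r} has no markers")

    def __len__(self) -> int:
        return len(self.compartments)


@dataclass
class AnnotationLists:
    """Regulator / contaminant annotation sets used downstream."""

    gap_ids: set[str] = field(default_factory=set)
    gef_ids: set[str] = field(default_factory=set)
    contaminant_ids: set[str] = field(default_factory=set)


def _resolve_columns(header: Iterable[str], aliases: Mapping[str, tuple[str, ...]],
                     required: Iterable[str]) -> dict[str, str]:
    header = list(header)
    resolved: dict[str, str] = {}
    for key, names in aliases.items():
        for name in names:
            if name in header:
                resolved[key] = name
                break
    for key in required:
        if key not in resolved:
            raise FormatError(
                f"missing mandatory column for {key!r} (expected one of {aliases[key]})"
            )
    return resolved


def _parse_replicates(value, delimiter: str, row: int) -> tuple[int, ...] | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    parts = text.split(delimiter)
    try:
        counts = tuple(int(float(p)) for p in parts)
    except ValueError as exc:
        raise FormatError(f"unparseable replicate spectral counts {text!r} at row {row}") from exc
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative replicate count at row {row}")
    return counts


def read_interaction_table(
    path: str | Path,
    dialect: str = "saint_tsv",
    *,
    controls: Mapping[str, str] | None = None,
    cell_line: str | None = None,
    replicate_delimiter: str = "|",
) -> InteractionTable:
    """Read a SAINT-style bait-prey result table.

    Parameters
    ----------
    dialect
        ``saint_tsv`` (SAINTexpress column names: Bait, Prey/PreyGene, Spec,
        AvgSpec, AvgP, optional CellLine) or ``generic_tsv`` (lower-case
        column names).
    controls
        Map of control role -> bait id; matching rows are flagged
        ``is_control``.  Control purifications are identified by configured
        bait ids, never by name matching.
    cell_line
        Cell line to assign when the file has no cell-line column.
    replicate_delimiter
        Separator inside the per-replicate spectral-count column.
    """
    path = Path(path)
    if dialect not in ("saint_tsv", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    aliases = _SAINT_ALIASES if dialect == "saint_tsv" else _GENERIC_ALIASES
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(raw.columns, aliases, required=("bait", "prey", "avg_spec", "avg_p"))

    n = len(raw)
    if "cell_line" in cols:
        lines = raw[cols["cell_line"]].astype(str)
    else:
        lines = pd.Series([cell_line if cell_line is not None else "HEK293"] * n, dtype=object)

    def _num(col: str, name: str) -> pd.Series:
        series = raw[col]
        try:
            return pd.to_numeric(series)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r} ({name})") from exc

    avg_spec = _num(cols["avg_spec"], "avg_spec").astype(float) if n else pd.Series(dtype=float)
    avg_p = _num(cols["avg_p"], "avg_p").astype(float) if n else pd.Series(dtype=float)
    if n:
        bad = avg_p[(avg_p < 0) | (avg_p > 1)]
        if len(bad):
            raise ValidationError(f"avg_p outside [0, 1] at row {int(bad.index[0]) + 2} of {path.name}")

    if "spec" in cols and n:
        reps = [
            _parse_replicates(v, replicate_delimiter, i + 2)
            for i, v in enumerate(raw[cols["spec"]])
        ]
    else:
        reps = [None] * n

    control_map = dict(controls or {})
    control_baits = set(control_map.values())
    df = pd.DataFrame(
        {
            "bait": raw[cols["bait"]].astype(str) if n else pd.Series(dtype=str),
            "prey": raw[cols["prey"]].astype(str) if n else pd.Series(dtype=str),
            "cell_line": lines,
            "avg_spec": avg_spec,
            "avg_p": avg_p,
            "replicate_specs": pd.Series(reps, dtype=object),
            "is_control": (raw[cols["bait"]].astype(str).isin(control_baits)
                           if n else pd.Series(dtype=bool)),
        }
    )
    if not n:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in _COLUMNS})
        df = df.astype({"avg_spec": float, "avg_p": float, "is_control": bool})
    return InteractionTable(df=df, controls=control_map)


def write_interaction_table(
    table: InteractionTable,
    path: str | Path,
    dialect: str = "saint_tsv",
    *,
    replicate_delimiter: str = "|",
) -> None:
    """Serialize a table so that :func:`read_interaction_table` round-trips it."""
    df = table.df
    reps = df["replicate_specs"].map(
        lambda t: "" if t is None else replicate_delimiter.join(str(int(c)) for c in t)
    )
    if dialect == "saint_tsv":
        out = pd.DataFrame(
            {
                "Bait": df["bait"],
                "PreyGene": df["prey"],
                "CellLine": df["cell_line"],
                "Spec": reps,
                "AvgSpec": df["avg_spec"],
                "AvgP": df["avg_p"],
            }
        )
    elif dialect == "generic_tsv":
        out = pd.DataFrame(
            {
                "bait": df["bait"],
                "prey": df["prey"],
                "cell_line": df["cell_line"],
                "spec": reps,
                "avg_spec": df["avg_spec"],
                "avg_p": df["avg_p"],
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False)


_BIOGRID_SYMBOL_COLS = (
    ("Official Symbol Interactor A", "Official Symbol Interactor B"),
    ("OFFICIAL_SYMBOL_A", "OFFICIAL_SYMBOL_B"),
)


def read_gold_standard(
    path: str | Path,
    bait_subset: Iterable[str] | None = None,
    *,
    source_tag: str = "",
) -> GoldStandard:
    """Read a BioGRID-style tab-delimited edge list.

    If BioGRID official-symbol columns are present they are used; otherwise
    the first two columns are taken as interactor identifiers.  Symmetric
    duplicates (A,B)/(B,A) are collapsed.  When ``bait_subset`` is given,
    edges are restricted to those touching a subset bait and oriented so the
    bait comes first.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError("gold-standard file needs at least two identifier columns")
    col_a = col_b = None
    for a, b in _BIOGRID_SYMBOL_COLS:
        if a in raw.columns and b in raw.columns:
            col_a, col_b = a, b
            break
    if col_a is None:
        col_a, col_b = raw.columns[0], raw.columns[1]

    subset = set(bait_subset) if bait_subset is not None else None
    edges: set[tuple[str, str]] = set()
    seen_pairs: set[frozenset[str]] = set()
    for a, b in zip(raw[col_a].astype(str), raw[col_b].astype(str)):
        pair = frozenset((a, b))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        if subset is None:
            edges.add((a, b))
        else:
            if a in subset:
                edges.add((a, b))
            elif b in subset:
                edges.add((b, a))
    if subset is not None and not edges:
        raise ValidationError(
            "no gold-standard edges left after restricting to the calibration "
            f"baits {sorted(subset)}; calibration is typically run on a small "
            "set of well-characterised baits (e.g. ARF1, ARF6, SAR1A, SAR1B)"
        )
    present = {b for b, _ in edges}
    return GoldStandard(
        edges=edges,
        source_tag=source_tag,
        bait_subset=(subset & present) if subset is not None else set(),
    )


def read_marker_sets(path: str | Path) -> CompartmentAtlas:
    """Read a GMT file: per line, compartment name, description, members..."""
    compartments: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in compartments:
                raise FormatError(f"duplicate compartment {name!r} at GMT line {lineno}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"GMT line {lineno} has no members")
            compartments[name] = members
    return CompartmentAtlas(compartments=compartments)


def read_annotation_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_network(df: pd.DataFrame, path: str | Path, format: str = "edge_tsv") -> None:
    """Write surviving bait-prey pairs as an edge TSV or a SIF file.

    An empty table yields a header-only file (edge_tsv) or an empty file (sif)
    plus a warning, so downstream tooling sees a well-formed artifact.
    """
    pairs = df[["bait", "prey"]].drop_duplicates()
    if len(pairs) == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    if format == "edge_tsv":
        pairs.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for bait, prey in pairs.itertuples(index=False):
                fh.write(f"{bait}\tproximity\t{prey}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def write_dotplot_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format table behind dot-plot views.

    ``relative_abundance`` is each prey's AvgSpec divided by its maximum
    AvgSpec over baits (within a cell line when present); pairs with no
    record under a bait are simply omitted.
    """
    cols = ["bait", "prey", "avg_spec", "avg_p"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"dotplot table needs columns {missing}")
    out = df.copy()
    group = ["prey", "cell_line"] if "cell_line" in out.columns else ["prey"]
    denom = out.groupby(group)["avg_spec"].transform("max")
    with np.errstate(invalid="ignore"):
        out["relative_abundance"] = np.where(denom > 0, out["avg_spec"] / denom, 0.0)
    keep = ["bait", "prey"] + (["cell_line"] if "cell_line" in out.columns else [])
    out = out[keep + ["avg_spec", "relative_abundance", "avg_p"]]
    out = out.rename(columns={"avg_spec": "AvgSpec", "avg_p": "AvgP"})
    out.to_csv(path, sep="\t", index=False)
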