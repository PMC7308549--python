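"""Per-case cell tables: I/O, validation, and global (non-spatial) indicators.

The pipeline consumes tabular exports of a cell-segmentation/classification
step of whole-slide image analysis: one row per detected cell with its
coordinates (μm), tissue compartment (tumor epithelium, stroma, or
background), and per-marker positivity flags. HER2 is recorded on the
clinical 0/1+/2+/3+ scale rather than as a binary flag; a cell counts as
HER2-positive when scored 2+ or 3+.

Compartment areas (mm²) arrive in a sidecar record and are the denominators
of the immune-cell density indicators. Cells missing a marker flag are
excluded from that marker's denominator — different markers are typically
stained on different serial sections, so absence means "not evaluated",
never "negative". Background cells are kept in files but excluded from all
indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, SchemaError, UndefinedIndicatorError

COMPARTMENTS = ("tumor", "stroma", "background")
HER2_CLASSES = ("0", "1+", "2+", "3+")
HER2_POSITIVE = ("2+", "3+")

#: Canonical marker flag columns (0/1/NaN). HER2 lives in ``her2_class``.
MARKER_COLUMNS = ("er", "pr", "ki67", "cd8", "satb1", "hif1a")
COORD_COLUMNS = ("x_um", "y_um")
REQUIRED_COLUMNS = COORD_COLUMNS + ("compartment",)


@dataclass(frozen=True)
class CompartmentGeometry:
    """Compartment areas in mm²; ``None`` when unknown."""

    tumor_area_mm2: float | None = None
    stroma_area_mm2: float | None = None

    def area(self, compartment: str) -> float:
        value = {"tumor": self.tumor_area_mm2, "stroma": self.stroma_area_mm2}.get(
            compartment
        )
        if value is None:
            raise ConfigError(
                f"no area available for compartment {compartment!r}; supply a "
                "geometry sidecar (case_id, tumor_area_mm2, stroma_area_mm2)"
            )
        if value <= 0:
            raise ConfigError(f"{compartment} area must be > 0, got {value}")
        return float(value)


@dataclass
class CellMap:
    """One case's cell point pattern plus compartment geometry.

    ``cells`` holds canonical columns ``x_um``, ``y_um``, ``compartment``,
    any subset of :data:`MARKER_COLUMNS` (float 0/1 with NaN = not
    evaluated) and optionally ``her2_class``. ``bounds`` is the
    ``(xmin, ymin, xmax, ymax)`` envelope in μm.
    """

    case_id: str
    cells: pd.DataFrame
    geometry: CompartmentGeometry = field(default_factory=CompartmentGeometry)
    bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise SchemaError("case identifier must be non-empty")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"cell table missing required column(s): {missing}")
        bad = ~self.cells["compartment"].isin(COMPARTMENTS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            value = self.cells["compartment"].iloc[row]
            raise SchemaError(
                f"unknown compartment label {value!r} at row {row}; "
                f"expected one of {COMPARTMENTS}"
            )
        xy = self.cells[list(COORD_COLUMNS)].to_numpy(dtype=float)
        if xy.size and (~np.isfinite(xy) | (xy < 0)).any():
            raise ParseError("cell coordinates must be finite and >= 0")
        if self.bounds is None:
            if len(self.cells):
                self.bounds = (
                    float(xy[:, 0].min()),
                    float(xy[:, 1].min()),
                    float(xy[:, 0].max()),
                    float(xy[:, 1].max()),
                )
            else:
                self.bounds = (0.0, 0.0, 0.0, 0.0)
        else:
            xmin, ymin, xmax, ymax = self.bounds
            if len(self.cells) and (
                (xy[:, 0] < xmin).any()
                or (xy[:, 0] > xmax).any()
                or (xy[:, 1] < ymin).any()
                or (xy[:, 1] > ymax).any()
            ):
                raise SchemaError("cell coordinates fall outside the stated bounds")

    @property
    def markers(self) -> list[str]:
        """Marker flag columns present in this table."""
        cols = [m for m in MARKER_COLUMNS if m in self.cells.columns]
        if "her2_class" in self.cells.columns:
            cols.append("her2")
        return cols

    def compartment_cells(self, compartment: str) -> pd.DataFrame:
        if compartment not in COMPARTMENTS:
            raise ConfigError(f"unknown compartment {compartment!r}")
        return self.cells[self.cells["compartment"] == compartment]

    def with_cells(self, cells: pd.DataFrame) -> "CellMap":
        return replace(self, cells=cells, bounds=None)


def marker_masks(
    cells: pd.DataFrame, marker: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return boolean (evaluated, positive) masks for ``marker``.

    For ``"her2"`` the evaluated cells are those with a non-null
    ``her2_class`` and positives are 2+/3+; for flag markers the evaluated
    cells are those with a non-NaN flag.
    """
    if marker == "her2":
        if "her2_class" not in cells.columns:
            raise ConfigError("marker 'her2' requires a her2_class column")
        cls = cells["her2_class"].astype("string")
        evaluated = cls.notna().to_numpy()
        known = cls.isin(HER2_CLASSES) | ~cls.notna()
        if not known.all():
            bad = cls[~known].iloc[0]
            raise SchemaError(f"unknown her2_class value {bad!r}")
        positive = cls.isin(HER2_POSITIVE).to_numpy()
        return evaluated, positive
    if marker not in cells.columns:
        raise ConfigError(f"marker {marker!r} not present in cell table")
    flags = pd.to_numeric(cells[marker], errors="coerce")
    evaluated = flags.notna().to_numpy()
    positive = (flags == 1).to_numpy()
    return evaluated, positive


def global_percent(cellmap: CellMap, marker: str, compartment: str = "tumor") -> float:
    """Percentage of marker-positive cells among evaluated cells (0–100)."""
    sub = cellmap.compartment_cells(compartment)
    evaluated, positive = marker_masks(sub, marker)
    n = int(evaluated.sum())
    if n == 0:
        raise UndefinedIndicatorError(
            "no_evaluable_cells",
            f"no {marker}-evaluated cells in the {compartment} compartment",
        )
    return 100.0 * int((positive & evaluated).sum()) / n


def cell_density(
    cellmap: CellMap, markers: str | Sequence[str], compartment: str
) -> float:
    """Density (cells/mm²) of cells positive for every marker in ``markers``."""
    if isinstance(markers, str):
        markers = [markers]
    area = cellmap.geometry.area(compartment)
    sub = cellmap.compartment_cells(compartment)
    match = np.ones(len(sub), dtype=bool)
    for marker in markers:
        evaluated, positive = marker_masks(sub, marker)
        match &= evaluated & positive
    return float(match.sum()) / area


# ---------------------------------------------------------------------------
# I/O

def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    case_id: str | None = None,
    geometry: CompartmentGeometry | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> CellMap:
    """Read a delimited cell table into a :class:`CellMap`.

    ``schema`` maps canonical column names to the file's column names
    (identity where omitted), decoupling the pipeline from vendor dialects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in list(REQUIRED_COLUMNS)
              + list(MARKER_COLUMNS) + ["her2_class", "case_id"]}
    raw = raw.rename(columns={k: v for k, v in rename.items() if k in raw.columns})
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(
                f"required column {schema.get(col, col)!r} (for {col!r}) "
                f"not found in {path.name}"
            )
    out = pd.DataFrame(index=raw.index)
    for col in COORD_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ParseError(
                f"non-numeric coordinate in column {col!r} at row {row}: "
                f"{raw[col].iloc[row]!r}",
                row=row,
            )
        out[col] = vals.astype(float)
    out["compartment"] = raw["compartment"].str.strip().str.lower()
    for m in MARKER_COLUMNS:
        if m in raw.columns:
            out[m] = pd.to_numeric(raw[m], errors="coerce")
    if "her2_class" in raw.columns:
        out["her2_class"] = raw["her2_class"].str.strip()
        out.loc[out["her2_class"].isin(("", "nan", "NA")), "her2_class"] = pd.NA
    if case_id is None:
        if "case_id" in raw.columns and raw["case_id"].notna().any():
            case_id = str(raw["case_id"].dropna().iloc[0])
        else:
            case_id = path.stem
    return CellMap(
        case_id=case_id,
        cells=out.reset_index(drop=True),
        geometry=geometry or CompartmentGeometry(),
        bounds=bounds,
    )


def write_cell_table(cellmap: CellMap, path: str | Path) -> Path:
    """Write the cell table as delimited text, coordinates at full precision."""
    path = Path(path)
    cols = [c for c in ("x_um", "y_um", "compartment") if c in cellmap.cells.columns]
    cols += [m for m in MARKER_COLUMNS if m in cellmap.cells.columns]
    if "her2_class" in cellmap.cells.columns:
        cols.append("her2_class")
    df = cellmap.cells[cols].copy()
    df.insert(0, "case_id", cellmap.case_id)
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")
    return path


def read_geometry_table(path: str | Path) -> dict[str, CompartmentGeometry]:
    """Read the geometry sidecar (case_id, tumor_area_mm2, stroma_area_mm2)."""
    df = pd.read_csv(Path(path))
    for col in ("case_id", "tumor_area_mm2", "stroma_area_mm2"):
        if col not in df.columns:
            raise SchemaError(f"geometry sidecar missing column {col!r}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["case_id"])] = CompartmentGeometry(
            tumor_area_mm2=None if pd.isna(row["tumor_area_mm2"]) else float(row["tumor_area_mm2"]),
            stroma_area_mm2=None if pd.isna(row["stroma_area_mm2"]) else float(row["stroma_area_mm2"]),
        )
    return out


def write_geometry_table(
    geometries: Mapping[str, CompartmentGeometry], path: str | Path
) -> Path:
    rows = [
        {
            "case_id": cid,
            "tumor_area_mm2": g.tumor_area_mm2,
            "stroma_area_mm2": g.stroma_area_mm2,
        }
        for cid, g in geometries.items()
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)
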