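"""Data model and I/O for per-cell immunofluorescence tables.

A *section* is a single tissue section imaged as a grid of field-of-view
(FOV) tiles.  Each cell carries local (within-tile) pixel coordinates, a
tissue class (``tumor`` or ``stroma``) and one mean intensity per
(marker, compartment) pair.  This module validates those tables, reads and
writes them as plain CSV, applies the per-FOV quality filter and selects
tumor cells for downstream analysis.

Coordinates are 0-based pixel units with y increasing downward (image
convention).  Intensities are arbitrary-unit non-negative reals; no
normalization happens at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPanel",
    "CellRecord",
    "FOVRecord",
    "SectionTable",
    "FOVExclusion",
    "SchemaError",
    "ValidationError",
    "read_cell_table",
    "write_cell_table",
    "filter_fovs",
    "select_tumor_cells",
]

NUCLEAR = "nuclear"
CYTOPLASM = "cytoplasm"
COMPARTMENTS = (NUCLEAR, CYTOPLASM)
DIRECTIONS = ("low", "high")
TISSUE_CLASSES = ("tumor", "stroma")

#: canonical non-intensity columns of a cell table CSV
CELL_COLUMNS = ("cell_id", "fov_id", "x_local", "y_local", "tissue_class")
#: canonical columns of a FOV metadata CSV
FOV_COLUMNS = (
    "fov_id",
    "grid_row",
    "grid_col",
    "tile_width",
    "tile_height",
    "tumor_fraction",
    "artifact_fraction",
)


class SchemaError(ValueError):
    """A required column is missing or mis-mapped in an input file."""


class ValidationError(ValueError):
    """A table violates an invariant (non-finite intensity, bad class, ...)."""


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker panel with compartment and tail-direction per marker.

    The default panel encodes the three-marker phenotype used throughout:
    AKT (cytoplasm, low tail), H3K9me2 (nuclear, low tail),
    HES1 (cytoplasm, high tail).
    """

    marker_names: tuple[str, ...] = ("AKT", "H3K9me2", "HES1")
    compartment_of: Mapping[str, str] = field(
        default_factory=lambda: {
            "AKT": CYTOPLASM,
            "H3K9me2": NUCLEAR,
            "HES1": CYTOPLASM,
        }
    )
    direction_of: Mapping[str, str] = field(
        default_factory=lambda: {"AKT": "low", "H3K9me2": "low", "HES1": "high"}
    )

    def __post_init__(self) -> None:
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("duplicate marker names in panel")
        for m in self.marker_names:
            comp = self.compartment_of.get(m)
            if comp not in COMPARTMENTS:
                raise ValidationError(
                    f"marker {m!r}: compartment must be one of {COMPARTMENTS}, got {comp!r}"
                )
            direc = self.direction_of.get(m)
            if direc not in DIRECTIONS:
                raise ValidationError(
                    f"marker {m!r}: direction must be one of {DIRECTIONS}, got {direc!r}"
                )

    def intensity_column(self, marker: str) -> str:
        """CSV column name holding mean intensity for *marker*'s compartment."""
        return f"{marker}_{self.compartment_of[marker]}_mean"

    @property
    def intensity_columns(self) -> tuple[str, ...]:
        return tuple(self.intensity_column(m) for m in self.marker_names)

    def flag_column(self, marker: str) -> str:
        """Column name for the per-marker qualification flag (e.g. ``AKT_low``)."""
        return f"{marker}_{self.direction_of[marker]}"


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell (row-level convenience; tables are DataFrames)."""

    cell_id: int
    fov_id: str
    x_local: float
    y_local: float
    tissue_class: str
    intensity: Mapping[tuple[str, str], float]  # (marker, compartment) -> mean


@dataclass(frozen=True)
class FOVRecord:
    """One imaging tile with grid position and QC fractions."""

    fov_id: str
    grid_row: int
    grid_col: int
    tile_width: float
    tile_height: float
    tumor_fraction: float
    artifact_fraction: float


@dataclass
class SectionTable:
    """All cells and FOV metadata for one tissue section.

    ``cells`` columns: :data:`CELL_COLUMNS` plus one intensity column per
    panel marker.  ``fovs`` columns: :data:`FOV_COLUMNS`.
    """

    section_id: str
    cells: pd.DataFrame
    fovs: pd.DataFrame
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    patient_id: str | None = None
    sample_type: str | None = None
    batch_id: str | None = None

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        self.fovs = self.fovs.reset_index(drop=True)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise SchemaError(f"cell table missing column {col!r}")
        for col in self.panel.intensity_columns:
            if col not in self.cells.columns:
                raise SchemaError(f"cell table missing intensity column {col!r}")
        for col in FOV_COLUMNS:
            if col not in self.fovs.columns:
                raise SchemaError(f"FOV table missing column {col!r}")

        cells, fovs = self.cells, self.fovs
        if cells["cell_id"].duplicated().any():
            dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell_id {dup}")
        if fovs["fov_id"].duplicated().any():
            raise ValidationError("duplicate fov_id in FOV table")
        if fovs.duplicated(subset=["grid_row", "grid_col"]).any():
            raise ValidationError("duplicate (grid_row, grid_col) in FOV table")

        unknown = set(cells["fov_id"]) - set(fovs["fov_id"])
        if unknown:
            raise ValidationError(f"cells reference unknown FOVs: {sorted(unknown)!r}")

        bad_class = ~cells["tissue_class"].isin(TISSUE_CLASSES)
        if bad_class.any():
            raise ValidationError(
                f"unknown tissue_class {cells.loc[bad_class, 'tissue_class'].iloc[0]!r}"
            )

        for col in self.panel.intensity_columns:
            vals = cells[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                bad = cells.loc[~np.isfinite(vals), "cell_id"].iloc[0]
                raise ValidationError(f"non-finite {col} for cell_id {bad}")
            if (vals < 0).any():
                bad = cells.loc[vals < 0, "cell_id"].iloc[0]
                raise ValidationError(f"negative {col} for cell_id {bad}")

        for frac in ("tumor_fraction", "artifact_fraction"):
            vals = fovs[frac].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
                raise ValidationError(f"{frac} must lie in [0, 1]")

        # local coordinates must fall inside the declared tile extent
        merged = cells.merge(fovs[["fov_id", "tile_width", "tile_height"]], on="fov_id")
        out_x = (merged["x_local"] < 0) | (merged["x_local"] > merged["tile_width"])
        out_y = (merged["y_local"] < 0) | (merged["y_local"] > merged["tile_height"])
        if (out_x | out_y).any():
            bad = merged.loc[out_x | out_y, "cell_id"].iloc[0]
            raise ValidationError(f"cell_id {bad} lies outside its tile extent")

    def with_cells(self, cells: pd.DataFrame) -> "SectionTable":
        """Copy of this section with a different cell table (FOVs preserved)."""
        return replace(self, cells=cells.reset_index(drop=True))


@dataclass(frozen=True)
class FOVExclusion:
    """One excluded FOV with the reasons that triggered its removal."""

    fov_id: str
    reasons: tuple[str, ...]
    n_cells_removed: int


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names (schema maps canonical -> file)."""
    if not schema:
        return df
    rename = {src: canon for canon, src in schema.items() if src in df.columns}
    missing = [src for src in schema.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"schema maps to absent columns: {missing!r}")
    return df.rename(columns=rename)


def read_cell_table(
    cells_path: str | Path,
    fovs_path: str | Path,
    panel: MarkerPanel | None = None,
    schema: Mapping[str, str] | None = None,
    fov_schema: Mapping[str, str] | None = None,
    section_id: str | None = None,
    **meta,
) -> SectionTable:
    """Read a per-cell CSV and its sidecar FOV-metadata CSV into a section.

    Parameters
    ----------
    cells_path, fovs_path
        Paths to the cell table and FOV metadata CSVs.
    panel
        Marker panel; defaults to the AKT/H3K9me2/HES1 panel.
    schema, fov_schema
        Optional mappings from canonical column names to the file's column
        headers (export headers vary by segmentation-software version).
    section_id
        Overrides the ``section_id`` column if given; otherwise the column
        must be present and constant.
    meta
        Forwarded to :class:`SectionTable` (``patient_id`` etc.).
    """
    panel = panel or MarkerPanel()
    cells = _apply_schema(pd.read_csv(cells_path), schema)
    fovs = _apply_schema(pd.read_csv(fovs_path), fov_schema)

    if section_id is None:
        if "section_id" not in cells.columns:
            raise SchemaError("cell table missing column 'section_id'")
        ids = cells["section_id"].unique()
        if len(ids) > 1:
            raise ValidationError(f"multiple section_ids in one file: {ids!r}")
        section_id = str(ids[0]) if len(ids) else "section"
    cells = cells.drop(columns=["section_id"], errors="ignore")

    needed = list(CELL_COLUMNS) + list(panel.intensity_columns)
    missing = [c for c in needed if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing column {missing[0]!r}")
    return SectionTable(
        section_id=section_id, cells=cells[needed], fovs=fovs, panel=panel, **meta
    )


def write_cell_table(
    section: SectionTable, cells_path: str | Path, fovs_path: str | Path
) -> None:
    """Write a section back to the cell-table + FOV CSV pair."""
    out = section.cells.copy()
    out.insert(0, "section_id", section.section_id)
    out.to_csv(cells_path, index=False)
    section.fovs[list(FOV_COLUMNS)].to_csv(fovs_path, index=False)


def filter_fovs(
    section: SectionTable,
    min_tumor: float = 0.01,
    max_artifact: float = 0.70,
) -> tuple[SectionTable, list[FOVExclusion]]:
    """Drop FOVs failing the tile-level QC rule, together with their cells.

    A FOV is excluded iff ``tumor_fraction < min_tumor`` (strictly) or
    ``artifact_fraction > max_artifact`` (strictly); boundary values are
    kept.  Returns the filtered section and a report of exclusions.
    """
    if not (0 <= min_tumor <= 1 and 0 <= max_artifact <= 1):
        raise ValidationError("QC thresholds must lie in [0, 1]")
    fovs = section.fovs
    low_tumor = fovs["tumor_fraction"] < min_tumor
    high_artifact = fovs["artifact_fraction"] > max_artifact
    drop = low_tumor | high_artifact

    cells_per_fov = section.cells["fov_id"].value_counts()
    report = []
    for _, row in fovs.loc[drop].iterrows():
        reasons = []
        if row["tumor_fraction"] < min_tumor:
            reasons.append(f"tumor_fraction {row['tumor_fraction']:g} < {min_tumor:g}")
        if row["artifact_fraction"] > max_artifact:
            reasons.append(
                f"artifact_fraction {row['artifact_fraction']:g} > {max_artifact:g}"
            )
        report.append(
            FOVExclusion(
                fov_id=row["fov_id"],
                reasons=tuple(reasons),
                n_cells_removed=int(cells_per_fov.get(row["fov_id"], 0)),
            )
        )

    kept_ids = set(fovs.loc[~drop, "fov_id"])
    filtered = replace(
        section,
        cells=section.cells[section.cells["fov_id"].isin(kept_ids)].reset_index(drop=True),
        fovs=fovs.loc[~drop].reset_index(drop=True),
    )
    return filtered, report


def select_tumor_cells(section: SectionTable) -> SectionTable:
    """Retain tumor-class cells only; FOV metadata is preserved unchanged."""
    return section.with_cells(section.cells[section.cells["tissue_class"] == "tumor"])


def records_to_frame(records: Iterable[CellRecord], panel: MarkerPanel) -> pd.DataFrame:
    """Build a cell DataFrame from :class:`CellRecord` objects (test helper)."""
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "fov_id": r.fov_id,
            "x_local": r.x_local,
            "y_local": r.y_local,
            "tissue_class": r.tissue_class,
        }
        for m in panel.marker_names:
            row[panel.intensity_column(m)] = r.intensity[(m, panel.compartment_of[m])]
        rows.append(row)
    return pd.DataFrame(rows)
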