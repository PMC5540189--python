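"""Digital tumor maps: tile stitching, section stacks, rendering.

Each FOV tile has its own local pixel coordinate system; a whole-section
map is obtained by translating every cell by its tile's origin, derived
from the tile's grid position.  Maps render to scatter images (QCC red,
other tumor cells blue, excluded tile footprints gray) and export/import
losslessly as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_table import SectionTable, ValidationError
from .qcc_calling import QCCLabels

__all__ = [
    "TileLayout",
    "DigitalTumorMap",
    "SectionStack",
    "MapStyle",
    "stitch",
    "stack_sections",
    "render_map",
    "read_map",
]

#: default tile size (pixels) of a x20 multispectral field
DEFAULT_TILE = (1392, 1040)

MAP_COLUMNS = ("section_id", "cell_id", "x_global", "y_global", "qcc_label", "tissue_class")


@dataclass(frozen=True)
class TileLayout:
    """Per-FOV global origins derived from grid position and tile size."""

    origins: pd.DataFrame  # columns: fov_id, x0, y0, tile_width, tile_height

    @classmethod
    def from_fovs(cls, fovs: pd.DataFrame, overlap: float = 0.0) -> "TileLayout":
        """Origin of tile (r, c) is (c*(w-overlap), r*(h-overlap))."""
        df = fovs[["fov_id", "grid_row", "grid_col", "tile_width", "tile_height"]].copy()
        df["x0"] = df["grid_col"] * (df["tile_width"] - overlap)
        df["y0"] = df["grid_row"] * (df["tile_height"] - overlap)
        out = df[["fov_id", "x0", "y0", "tile_width", "tile_height"]]
        if out.duplicated(subset=["x0", "y0"]).any():
            raise ValidationError("tile origins are not unique")
        return cls(origins=out.reset_index(drop=True))

    def origin_of(self, fov_id) -> tuple[float, float]:
        row = self.origins[self.origins["fov_id"] == fov_id]
        if row.empty:
            raise ValidationError(f"no layout origin for tile {fov_id!r}")
        return float(row["x0"].iloc[0]), float(row["y0"].iloc[0])


@dataclass
class DigitalTumorMap:
    """Whole-section cell scatter in one Cartesian coordinate system.

    ``cells`` columns: cell_id, fov_id, x_global, y_global, tissue_class,
    qcc_label (bool).  ``excluded_regions`` lists (x0, y0, w, h) footprints
    of QC-excluded tiles for rendering.
    """

    section_id: str
    cells: pd.DataFrame
    stack_order: int = 0
    excluded_regions: list[tuple[float, float, float, float]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_qcc(self) -> int:
        return int(self.cells["qcc_label"].sum())

    def tumor_xy(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(xy array, qcc mask, cell_ids) over tumor cells only."""
        tum = self.cells[self.cells["tissue_class"] == "tumor"]
        xy = tum[["x_global", "y_global"]].to_numpy(dtype=float)
        return xy, tum["qcc_label"].to_numpy(dtype=bool), tum["cell_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out.insert(0, "section_id", self.section_id)
        out[list(MAP_COLUMNS)].to_csv(path, index=False)


def stitch(
    section: SectionTable,
    layout: TileLayout | None = None,
    labels: QCCLabels | None = None,
    excluded_fovs: pd.DataFrame | None = None,
) -> DigitalTumorMap:
    """Translate each cell by its tile origin into global coordinates.

    ``labels`` attaches QCC calls (cells absent from the label table get
    ``qcc_label=False``).  ``excluded_fovs`` (FOV-metadata rows of
    QC-dropped tiles) contribute gray footprints for rendering.
    """
    if layout is None:
        layout = TileLayout.from_fovs(section.fovs)
    cells = section.cells
    missing = set(cells["fov_id"]) - set(layout.origins["fov_id"])
    if missing:
        raise ValidationError(f"no layout origin for tile {sorted(missing)[0]!r}")
    merged = cells.merge(layout.origins[["fov_id", "x0", "y0"]], on="fov_id", how="left")
    out = pd.DataFrame(
        {
            "cell_id": merged["cell_id"],
            "fov_id": merged["fov_id"],
            "x_global": merged["x_local"] + merged["x0"],
            "y_global": merged["y_local"] + merged["y0"],
            "tissue_class": merged["tissue_class"],
        }
    )
    if labels is not None:
        lab = labels.table[["cell_id", "qcc"]].rename(columns={"qcc": "qcc_label"})
        out = out.merge(lab, on="cell_id", how="left")
        out["qcc_label"] = out["qcc_label"].eq(True)  # NaN (unlabeled) -> False
    else:
        out["qcc_label"] = False
    if len(out) != len(cells):
        raise ValidationError("stitch changed the cell count")

    regions = []
    if excluded_fovs is not None and len(excluded_fovs):
        ex_layout = TileLayout.from_fovs(
            pd.concat([section.fovs, excluded_fovs], ignore_index=True)
        )
        for _, row in excluded_fovs.iterrows():
            x0, y0 = ex_layout.origin_of(row["fov_id"])
            regions.append((x0, y0, float(row["tile_width"]), float(row["tile_height"])))
    return DigitalTumorMap(section_id=section.section_id, cells=out, excluded_regions=regions)


def unstitch(map_: DigitalTumorMap, layout: TileLayout) -> pd.DataFrame:
    """Recover local coordinates by subtracting tile origins (round-trip check)."""
    merged = map_.cells.merge(layout.origins[["fov_id", "x0", "y0"]], on="fov_id")
    return pd.DataFrame(
        {
            "cell_id": merged["cell_id"],
            "fov_id": merged["fov_id"],
            "x_local": merged["x_global"] - merged["x0"],
            "y_local": merged["y_global"] - merged["y0"],
        }
    )


@dataclass
class SectionStack:
    """Ordered sequence of maps; z-position is the rank in the given order."""

    maps: list[DigitalTumorMap]

    def __len__(self) -> int:
        return len(self.maps)


def stack_sections(maps: Sequence[DigitalTumorMap], order: Sequence[int]) -> SectionStack:
    """Arrange maps as a 3D stack; ``order[i]`` ranks map ``i`` along z."""
    if len(maps) != len(order):
        raise ValidationError("order list must match number of maps")
    if len(set(order)) != len(order):
        raise ValidationError("duplicate order values")
    ranked = sorted(zip(order, maps), key=lambda p: p[0])
    stacked = []
    for z, (_, m) in enumerate(ranked):
        m2 = DigitalTumorMap(
            section_id=m.section_id,
            cells=m.cells,
            stack_order=z,
            excluded_regions=list(m.excluded_regions),
        )
        stacked.append(m2)
    return SectionStack(maps=stacked)


@dataclass(frozen=True)
class MapStyle:
    qcc_color: str = "#ff0000"
    other_color: str = "#0000ff"
    excluded_color: str = "#bfbfbf"
    marker_size: float = 4.0
    figsize: tuple[float, float] = (8.0, 8.0)
    dpi: int = 100


def render_map(map_: DigitalTumorMap, path: str | Path, style: MapStyle | None = None) -> None:
    """Render a map to an image file (format by extension; SVG is deterministic).

    QCCs are drawn red, other cells blue, excluded tile footprints gray.
    Rendering twice with identical inputs yields byte-identical SVG.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if map_.n_cells == 0:
        raise ValidationError("cannot render an empty map")
    style = style or MapStyle()
    with matplotlib.rc_context({"svg.hashsalt": "qccmap"}):
        fig, ax = plt.subplots(figsize=style.figsize, dpi=style.dpi)
        for x0, y0, w, h in map_.excluded_regions:
            ax.add_patch(
                Rectangle((x0, y0), w, h, facecolor=style.excluded_color, edgecolor="none")
            )
        other = map_.cells[~map_.cells["qcc_label"]]
        qcc = map_.cells[map_.cells["qcc_label"]]
        ax.scatter(
            other["x_global"], other["y_global"], s=style.marker_size,
            c=style.other_color, linewidths=0, gid="other-cells",
        )
        if len(qcc):
            ax.scatter(
                qcc["x_global"], qcc["y_global"], s=style.marker_size,
                c=style.qcc_color, linewidths=0, gid="qcc-cells",
            )
        ax.set_aspect("equal")
        ax.invert_yaxis()  # image convention: y grows downward
        ax.set_title(map_.section_id)
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)


def read_map(path: str | Path) -> DigitalTumorMap:
    """Re-import a map CSV written by :meth:`DigitalTumorMap.to_csv`."""
    df = pd.read_csv(path)
    ids = df["section_id"].unique()
    if len(ids) != 1:
        raise ValidationError("map CSV must hold exactly one section")
    cells = df.drop(columns=["section_id"]).copy()
    cells["qcc_label"] = cells["qcc_label"].astype(bool)
    if "fov_id" not in cells.columns:
        cells["fov_id"] = "NA"
    return DigitalTumorMap(section_id=str(ids[0]), cells=cells)
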