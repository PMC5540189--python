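"""Synthetic sections and cohorts with the structure the pipeline assumes.

Generates per-cell tables with (a) spatially random (CSR) or clustered
(Thomas parent-offspring) QCC placement, (b) class-conditional log-normal
marker intensities (QCC: AKT low, H3K9me2 low, HES1 high), (c) per-section
multiplicative batch scaling, and (d) a FOV tile grid with tumor/artifact
QC fractions — everything needed to exercise ingestion, calling, mapping
and the cluster-index test without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cell_table import MarkerPanel, SectionTable, ValidationError, write_cell_table

__all__ = [
    "IntensityModel",
    "SynthConfig",
    "GroundTruth",
    "simulate_positions",
    "simulate_intensities",
    "simulate_section",
    "simulate_cohort",
]


@dataclass(frozen=True)
class IntensityModel:
    """Per-marker, per-class log-normal location/scale (natural-log units)."""

    loc_other: Mapping[str, float] = field(
        default_factory=lambda: {"AKT": 4.0, "H3K9me2": 4.0, "HES1": 3.0}
    )
    loc_qcc: Mapping[str, float] = field(
        default_factory=lambda: {"AKT": 2.0, "H3K9me2": 2.0, "HES1": 5.0}
    )
    scale: Mapping[str, float] = field(
        default_factory=lambda: {"AKT": 0.5, "H3K9me2": 0.5, "HES1": 0.5}
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full generative description of one synthetic section."""

    n_cells: int = 1000  # tumor cells
    fov_grid: tuple[int, int] = (2, 2)  # (rows, cols)
    tile_width: float = 1392.0
    tile_height: float = 1040.0
    stroma_fraction: float = 0.0  # extra stroma cells as fraction of n_cells
    qcc_fraction: float = 0.05
    spatial_model: str = "csr"  # {"csr", "thomas"}
    n_parents: int = 5
    cluster_sigma: float = 50.0  # Gaussian offspring dispersion (px)
    parent_seed: int | None = None  # share parents across "contiguous" sections
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    batch_scale: Mapping[str, float] = field(
        default_factory=lambda: {"AKT": 1.0, "H3K9me2": 1.0, "HES1": 1.0}
    )
    tumor_fraction: float = 0.5  # reported per-FOV QC value
    artifact_fraction: float = 0.0
    section_id: str = "synthetic"
    sample_type: str = "control"
    batch_id: str = "batch0"
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("qcc_fraction", self.qcc_fraction),
            ("tumor_fraction", self.tumor_fraction),
            ("artifact_fraction", self.artifact_fraction),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.stroma_fraction < 0:
            raise ValidationError("stroma_fraction must be >= 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.spatial_model not in ("csr", "thomas"):
            raise ValidationError(f"unknown spatial_model {self.spatial_model!r}")
        if self.spatial_model == "thomas":
            if self.cluster_sigma <= 0:
                raise ValidationError("cluster_sigma must be > 0")
            if self.n_parents < 1:
                raise ValidationError("n_parents must be >= 1")

    @property
    def field_size(self) -> tuple[float, float]:
        rows, cols = self.fov_grid
        return (cols * self.tile_width, rows * self.tile_height)


@dataclass
class GroundTruth:
    """Per-cell true class and (for Thomas offspring) cluster membership."""

    is_qcc: np.ndarray  # bool, tumor cells only
    cluster_id: np.ndarray  # int, -1 for non-offspring
    parents_xy: np.ndarray | None = None


def simulate_positions(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Tumor-cell global coordinates plus ground-truth classes.

    ``csr``: uniform positions, classes by independent Bernoulli draws.
    ``thomas``: non-QCC cells uniform; QCC cells Gaussian-dispersed
    offspring around uniform parents, clipped to the field.
    """
    rng = rng or np.random.default_rng(config.seed)
    w, h = config.field_size
    n = config.n_cells
    if n == 0:
        return np.empty((0, 2)), GroundTruth(
            is_qcc=np.empty(0, bool), cluster_id=np.empty(0, np.int64)
        )
    is_qcc = rng.random(n) < config.qcc_fraction
    cluster_id = np.full(n, -1, dtype=np.int64)
    xy = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    parents = None
    if config.spatial_model == "thomas" and is_qcc.any():
        idx = np.flatnonzero(is_qcc)
        # contiguous physical sections share cluster parents: draw them from
        # a dedicated stream when parent_seed is set
        prng = rng if config.parent_seed is None else np.random.default_rng(config.parent_seed)
        parents = np.column_stack(
            [prng.uniform(0, w, config.n_parents), prng.uniform(0, h, config.n_parents)]
        )
        assignment = rng.integers(0, config.n_parents, idx.size)
        offsets = rng.normal(0.0, config.cluster_sigma, size=(idx.size, 2))
        xy[idx] = parents[assignment] + offsets
        xy[idx, 0] = np.clip(xy[idx, 0], 0, np.nextafter(w, 0))
        xy[idx, 1] = np.clip(xy[idx, 1], 0, np.nextafter(h, 0))
        cluster_id[idx] = assignment
    return xy, GroundTruth(is_qcc=is_qcc, cluster_id=cluster_id, parents_xy=parents)


def simulate_intensities(
    classes: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Class-conditional log-normal intensities, batch-scaled, strictly positive."""
    rng = rng or np.random.default_rng(config.seed + 1)
    model = config.intensity_model
    panel = config.panel
    out = {}
    classes = np.asarray(classes, dtype=bool)
    n = classes.size
    for marker in panel.marker_names:
        loc = np.where(classes, model.loc_qcc[marker], model.loc_other[marker])
        draws = np.exp(rng.normal(loc, model.scale[marker], size=n))
        out[panel.intensity_column(marker)] = draws * config.batch_scale.get(marker, 1.0)
    return pd.DataFrame(out)


def _fov_frame(config: SynthConfig) -> pd.DataFrame:
    rows, cols = config.fov_grid
    recs = []
    for r in range(rows):
        for c in range(cols):
            recs.append(
                {
                    "fov_id": f"F{r}{c}",
                    "grid_row": r,
                    "grid_col": c,
                    "tile_width": config.tile_width,
                    "tile_height": config.tile_height,
                    "tumor_fraction": config.tumor_fraction,
                    "artifact_fraction": config.artifact_fraction,
                }
            )
    return pd.DataFrame(recs)


def simulate_section(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[SectionTable, GroundTruth]:
    """One full synthetic section consumable by the ingestion layer."""
    rng = rng or np.random.default_rng(config.seed)
    xy, truth = simulate_positions(config, rng)
    w, h = config.field_size

    n_stroma = int(round(config.stroma_fraction * config.n_cells))
    stroma_xy = np.column_stack(
        [rng.uniform(0, w, n_stroma), rng.uniform(0, h, n_stroma)]
    )
    all_xy = np.vstack([xy, stroma_xy])
    tissue = np.array(["tumor"] * len(xy) + ["stroma"] * n_stroma)
    classes = np.concatenate([truth.is_qcc, np.zeros(n_stroma, bool)])

    intens = simulate_intensities(classes, config, rng)
    col = np.minimum((all_xy[:, 0] // config.tile_width).astype(int), config.fov_grid[1] - 1)
    row = np.minimum((all_xy[:, 1] // config.tile_height).astype(int), config.fov_grid[0] - 1)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(all_xy)),
            "fov_id": [f"F{r}{c}" for r, c in zip(row, col)],
            "x_local": all_xy[:, 0] - col * config.tile_width,
            "y_local": all_xy[:, 1] - row * config.tile_height,
            "tissue_class": tissue,
        }
    )
    cells = pd.concat([cells, intens], axis=1)
    section = SectionTable(
        section_id=config.section_id,
        cells=cells,
        fovs=_fov_frame(config),
        panel=config.panel,
        sample_type=config.sample_type,
        batch_id=config.batch_id,
    )
    return section, truth


def simulate_cohort(
    configs: Sequence[SynthConfig],
    seeds: Sequence[int] | None = None,
    outdir: str | Path | None = None,
) -> list[tuple[SectionTable, GroundTruth]]:
    """Simulate several sections; optionally write CSVs plus a seed manifest.

    Output layout per section: ``<section_id>.cells.csv``,
    ``<section_id>.fovs.csv``, ``<section_id>.truth.csv`` and a single
    ``manifest.yaml`` recording every seed for exact reproduction.
    """
    if not configs:
        raise ValidationError("simulate_cohort needs at least one config")
    if seeds is not None:
        if len(seeds) != len(configs):
            raise ValidationError("seeds must match configs in length")
        configs = [replace(c, seed=s) for c, s in zip(configs, seeds)]
    results = []
    manifest = []
    for cfg in configs:
        section, truth = simulate_section(cfg)
        results.append((section, truth))
        manifest.append(
            {
                "section_id": cfg.section_id,
                "seed": int(cfg.seed),
                "spatial_model": cfg.spatial_model,
                "n_cells": int(cfg.n_cells),
                "qcc_fraction": float(cfg.qcc_fraction),
                "sample_type": cfg.sample_type,
            }
        )
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            write_cell_table(
                section,
                outdir / f"{cfg.section_id}.cells.csv",
                outdir / f"{cfg.section_id}.fovs.csv",
            )
            pd.DataFrame(
                {
                    "cell_id": np.arange(len(truth.is_qcc)),
                    "is_qcc": truth.is_qcc.astype(int),
                    "cluster_id": truth.cluster_id,
                }
            ).to_csv(outdir / f"{cfg.section_id}.truth.csv", index=False)
    if outdir is not None:
        with open(Path(outdir) / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"sections": manifest}, fh, sort_keys=False)
    return results
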