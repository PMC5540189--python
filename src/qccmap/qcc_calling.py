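"""Rank-percentile gating of the three-marker panel.

A cell is called QCC when it qualifies on every marker of the panel
simultaneously: low tail for AKT (cytoplasm) and H3K9me2 (nucleus), high
tail for HES1 (cytoplasm).  The relative mode flags exactly ``ceil(t*N)``
cells per marker, ranked within the section, which makes the call
invariant under any strictly increasing per-marker intensity transform —
in particular under per-batch multiplicative scaling.  Absolute cutoffs
are supported for comparison but are not reproducible across sections.

Tie handling: ranks are assigned by sorting on (intensity, cell_id), so
calls are deterministic even with tied intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cell_table import MarkerPanel, SectionTable, ValidationError

__all__ = [
    "ThresholdConfig",
    "QCCLabels",
    "qualify_marker",
    "call_qcc",
    "threshold_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Gating rule: relative fraction ``t`` or absolute per-marker cutoffs."""

    mode: str = "relative"  # {"relative", "absolute"}
    t: float = 0.25
    absolute_cutoffs: Mapping[str, float] | None = None
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    tumor_only: bool = True  # restrict the reference population to tumor cells

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "relative" and not (0.0 <= self.t <= 1.0):
            raise ValidationError(f"relative fraction t={self.t} outside [0, 1]")
        if self.mode == "absolute":
            cuts = self.absolute_cutoffs or {}
            missing = [m for m in self.panel.marker_names if m not in cuts]
            if missing:
                raise ValidationError(f"absolute mode missing cutoffs for {missing!r}")


@dataclass
class QCCLabels:
    """Per-cell call plus per-marker qualification flags and realized cutoffs.

    ``table`` columns: ``cell_id``, one boolean flag per marker (named e.g.
    ``AKT_low``), and boolean ``qcc``.  ``thresholds`` maps marker to the
    realized intensity cutoff (boundary flagged value in relative mode, the
    configured cutoff in absolute mode; NaN when nothing is flagged).
    """

    table: pd.DataFrame
    thresholds: dict[str, float]
    config: ThresholdConfig

    @property
    def qcc_mask(self) -> np.ndarray:
        return self.table["qcc"].to_numpy(dtype=bool)

    @property
    def n_qcc(self) -> int:
        return int(self.table["qcc"].sum())

    @property
    def n_cells(self) -> int:
        return len(self.table)


def qualify_marker(
    values: Sequence[float],
    t: float,
    direction: str,
    cell_ids: Sequence | None = None,
) -> np.ndarray:
    """Flag the extreme-``t`` tail of *values* by rank.

    Exactly ``ceil(t*N)`` cells are flagged: the lowest ranks for
    ``direction="low"``, the highest for ``direction="high"``.  Ties are
    broken by (intensity, cell_id) so the flagged set is deterministic and
    nested across increasing ``t``.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n == 0:
        raise ValidationError("qualify_marker requires at least one value")
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"fraction t={t} outside [0, 1]")
    if direction not in ("low", "high"):
        raise ValidationError(f"direction must be 'low' or 'high', got {direction!r}")
    ids = np.arange(n) if cell_ids is None else np.asarray(cell_ids)
    m = math.ceil(t * n)
    order = np.lexsort((ids, vals))  # ascending by (value, cell_id)
    flags = np.zeros(n, dtype=bool)
    if m > 0:
        chosen = order[:m] if direction == "low" else order[n - m :]
        flags[chosen] = True
    return flags


def call_qcc(section: SectionTable, config: ThresholdConfig | None = None) -> QCCLabels:
    """Call QCCs on a section with the configured gating rule.

    The reference population is the section's tumor cells by default
    (``config.tumor_only``); stroma cells neither qualify nor contribute to
    the percentile ranks.
    """
    config = config or ThresholdConfig()
    panel = config.panel
    cells = section.cells
    if config.tumor_only:
        cells = cells[cells["tissue_class"] == "tumor"]
    if len(cells) == 0:
        raise ValidationError("no cells in reference population for QCC calling")

    for marker in panel.marker_names:
        col = panel.intensity_column(marker)
        if col not in cells.columns:
            raise ValidationError(f"section lacks intensity column {col!r}")

    out = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    thresholds: dict[str, float] = {}
    qcc = np.ones(len(cells), dtype=bool)
    for marker in panel.marker_names:
        vals = cells[panel.intensity_column(marker)].to_numpy(dtype=float)
        direction = panel.direction_of[marker]
        if config.mode == "relative":
            flags = qualify_marker(vals, config.t, direction, cells["cell_id"].to_numpy())
            if flags.any():
                # boundary of the flagged set: max flagged value for a low
                # tail, min flagged value for a high tail
                thr = float(vals[flags].max() if direction == "low" else vals[flags].min())
            else:
                thr = float("nan")
        else:
            thr = float(config.absolute_cutoffs[marker])
            flags = vals <= thr if direction == "low" else vals >= thr
        thresholds[marker] = thr
        out[panel.flag_column(marker)] = flags
        qcc &= flags
    out["qcc"] = qcc
    return QCCLabels(table=out, thresholds=thresholds, config=config)


@dataclass
class SweepResult:
    """Threshold-sweep output: per-t section summary and per-FOV densities."""

    summary: pd.DataFrame  # columns: t, n_qcc, n_cells, qcc_p
    density: pd.DataFrame  # columns: t, fov_id, n_tumor_cells, qcc_d


def threshold_sweep(
    section: SectionTable,
    fractions: Sequence[float] = (0.25, 0.33, 0.50),
    panel: MarkerPanel | None = None,
) -> SweepResult:
    """Apply the relative rule at each fraction; QCC-P is non-decreasing in t."""
    if list(fractions) != sorted(fractions):
        raise ValidationError("fractions must be sorted ascending")
    panel = panel or MarkerPanel()
    summary_rows, density_rows = [], []
    for t in fractions:
        labels = call_qcc(section, ThresholdConfig(mode="relative", t=t, panel=panel))
        n = labels.n_cells
        summary_rows.append(
            {"t": t, "n_qcc": labels.n_qcc, "n_cells": n, "qcc_p": labels.n_qcc / n}
        )
        tumor = section.cells[section.cells["tissue_class"] == "tumor"]
        merged = tumor.merge(labels.table[["cell_id", "qcc"]], on="cell_id")
        for fov_id, grp in merged.groupby("fov_id", sort=True):
            density_rows.append(
                {
                    "t": t,
                    "fov_id": fov_id,
                    "n_tumor_cells": len(grp),
                    "qcc_d": grp["qcc"].mean(),
                }
            )
    return SweepResult(
        summary=pd.DataFrame(summary_rows), density=pd.DataFrame(density_rows)
    )
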