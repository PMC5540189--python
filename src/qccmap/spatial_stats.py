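"""QCC cluster index (QCC-CI) with window-censored k-nearest-neighbor rule.

For each focal QCC, candidate neighbors are the other tumor cells inside
a +/-``window`` box on each axis (Chebyshev pre-filter); focals with fewer
than ``k`` candidates are discarded; otherwise the per-focal score is the
fraction of QCCs among the ``k`` Euclidean-nearest candidates.  The
section-level index is the mean over retained focals.  Significance comes
from a label-permutation null: ``B`` random draws of ``n_qcc`` tumor cells
as pseudo-QCCs over the same geometry, with the identical discard rule,
and an add-one empirical p-value, one-sided toward clustering.

Geometry does not change across permutations, so the k-nearest in-window
neighbor lists are computed once (:func:`build_neighbor_index`) and reused
for every replicate.  A full-distance-matrix brute-force path and an
exhaustive enumeration of all labelings are provided as oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cell_table import ValidationError
from .tumor_map import DigitalTumorMap

__all__ = [
    "ClusterIndexConfig",
    "ClusterIndexResult",
    "NeighborIndex",
    "NoQCCError",
    "build_neighbor_index",
    "neighbor_fraction",
    "qcc_ci",
    "qcc_ci_bruteforce",
    "permutation_null",
    "empirical_p",
    "exact_null",
    "cluster_index_test",
]


class NoQCCError(ValueError):
    """The map contains no QCC — distinct from 'all focals discarded'."""


@dataclass(frozen=True)
class ClusterIndexConfig:
    """Parameters of the cluster index and its permutation null."""

    k: int = 100
    window: float = 500.0
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.window <= 0:
            raise ValidationError("window must be > 0")
        if self.B < 1:
            raise ValidationError("B must be >= 1")


@dataclass
class NeighborIndex:
    """Precomputed k-nearest in-window neighbors for every tumor cell.

    ``neighbors[i]`` holds the row indices of cell i's k nearest in-window
    tumor cells (meaningless where ``valid[i]`` is False, i.e. the cell had
    fewer than k in-window candidates and is discarded as a focal).
    """

    neighbors: np.ndarray  # (N, k) int
    valid: np.ndarray  # (N,) bool
    cell_ids: np.ndarray  # (N,)
    config: ClusterIndexConfig


def _as_tumor_arrays(
    map_or_xy, labels=None, cell_ids=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize inputs to (xy, qcc mask, cell_ids) over tumor cells."""
    if isinstance(map_or_xy, DigitalTumorMap):
        xy, qcc, ids = map_or_xy.tumor_xy()
        if labels is not None:
            qcc = np.asarray(labels, dtype=bool)
        return xy, qcc, ids
    xy = np.asarray(map_or_xy, dtype=float)
    qcc = np.asarray(labels, dtype=bool) if labels is not None else np.zeros(len(xy), bool)
    ids = np.arange(len(xy)) if cell_ids is None else np.asarray(cell_ids)
    return xy, qcc, ids


def build_neighbor_index(
    xy: np.ndarray, cell_ids: np.ndarray, config: ClusterIndexConfig
) -> NeighborIndex:
    """k-nearest in-window neighbors per cell, ties broken by cell_id.

    Candidates are selected with a Chebyshev (box) radius query, then
    ranked by Euclidean distance with (distance, cell_id) lexicographic
    tie-breaking; the focal cell itself never counts.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    k = config.k
    neighbors = np.full((n, k), -1, dtype=np.int64)
    valid = np.zeros(n, dtype=bool)
    if n:
        tree = cKDTree(xy)
        # rank of each cell_id, used for deterministic tie-breaks
        id_rank = np.empty(n, dtype=np.int64)
        id_rank[np.lexsort((np.arange(n), cell_ids))] = np.arange(n)
        candidates = tree.query_ball_point(xy, r=config.window, p=np.inf)
        for i, cand in enumerate(candidates):
            cand = np.asarray([c for c in cand if c != i], dtype=np.int64)
            if cand.size < k:
                continue
            d = np.linalg.norm(xy[cand] - xy[i], axis=1)
            order = np.lexsort((id_rank[cand], d))[:k]
            neighbors[i] = cand[order]
            valid[i] = True
    return NeighborIndex(
        neighbors=neighbors, valid=valid, cell_ids=np.asarray(cell_ids), config=config
    )


def neighbor_fraction(
    map_or_xy,
    focal_cell_id,
    labels=None,
    config: ClusterIndexConfig | None = None,
    cell_ids=None,
) -> float | None:
    """Per-focal score: QCC fraction among the k nearest in-window tumor cells.

    Returns ``None`` when the focal cell is discarded (fewer than k
    in-window candidates).
    """
    config = config or ClusterIndexConfig()
    xy, qcc, ids = _as_tumor_arrays(map_or_xy, labels, cell_ids)
    where = np.flatnonzero(ids == focal_cell_id)
    if where.size != 1:
        raise ValidationError(f"focal cell {focal_cell_id!r} not found uniquely")
    i = int(where[0])
    if not qcc[i]:
        raise ValidationError("focal cell must be labeled QCC")
    delta = np.abs(xy - xy[i])
    inside = (delta[:, 0] <= config.window) & (delta[:, 1] <= config.window)
    inside[i] = False
    cand = np.flatnonzero(inside)
    if cand.size < config.k:
        return None
    d = np.linalg.norm(xy[cand] - xy[i], axis=1)
    order = np.lexsort((ids[cand], d))[: config.k]
    return float(qcc[cand[order]].mean())


def _scores_from_index(index: NeighborIndex, qcc: np.ndarray) -> tuple[np.ndarray, int, int]:
    """(per-focal fractions over retained focals, n_retained, n_discarded)."""
    focal = np.flatnonzero(qcc)
    retained = focal[index.valid[focal]]
    n_disc = focal.size - retained.size
    if retained.size == 0:
        return np.empty(0), 0, n_disc
    fracs = qcc[index.neighbors[retained]].mean(axis=1)
    return fracs, retained.size, n_disc


@dataclass
class ClusterIndexResult:
    """Observed index, per-focal bookkeeping, permutation null and p-value."""

    qcc_ci: float  # NaN when undefined (all focals discarded)
    defined: bool
    fractions: np.ndarray  # retained per-focal fractions
    n_focal_retained: int
    n_focal_discarded: int
    permutation_scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_undefined_permutations: int = 0
    p_value: float = float("nan")
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "qcc_ci": None if not self.defined else self.qcc_ci,
            "defined": self.defined,
            "fractions": [float(f) for f in self.fractions],
            "n_focal_retained": self.n_focal_retained,
            "n_focal_discarded": self.n_focal_discarded,
            "permutation_scores": [float(s) for s in self.permutation_scores],
            "n_undefined_permutations": self.n_undefined_permutations,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "seed": self.seed,
        }


def qcc_ci(
    map_or_xy,
    labels=None,
    config: ClusterIndexConfig | None = None,
    cell_ids=None,
    index: NeighborIndex | None = None,
) -> ClusterIndexResult:
    """Observed cluster index: mean per-focal fraction over retained QCCs."""
    config = config or ClusterIndexConfig()
    xy, qcc, ids = _as_tumor_arrays(map_or_xy, labels, cell_ids)
    if not qcc.any():
        raise NoQCCError("map contains no QCC")
    if index is None:
        index = build_neighbor_index(xy, ids, config)
    fracs, n_ret, n_disc = _scores_from_index(index, qcc)
    if n_ret == 0:
        return ClusterIndexResult(
            qcc_ci=float("nan"), defined=False, fractions=fracs,
            n_focal_retained=0, n_focal_discarded=n_disc,
        )
    return ClusterIndexResult(
        qcc_ci=float(fracs.mean()), defined=True, fractions=fracs,
        n_focal_retained=n_ret, n_focal_discarded=n_disc,
    )


def qcc_ci_bruteforce(
    map_or_xy, labels=None, config: ClusterIndexConfig | None = None, cell_ids=None
) -> ClusterIndexResult:
    """Independent O(N^2) implementation via the full pairwise distance matrix."""
    config = config or ClusterIndexConfig()
    xy, qcc, ids = _as_tumor_arrays(map_or_xy, labels, cell_ids)
    if not qcc.any():
        raise NoQCCError("map contains no QCC")
    n = len(xy)
    fracs = []
    n_disc = 0
    for i in range(n):
        if not qcc[i]:
            continue
        dx = np.abs(xy[:, 0] - xy[i, 0])
        dy = np.abs(xy[:, 1] - xy[i, 1])
        inside = (dx <= config.window) & (dy <= config.window)
        inside[i] = False
        cand = np.flatnonzero(inside)
        if cand.size < config.k:
            n_disc += 1
            continue
        d = np.sqrt((xy[cand, 0] - xy[i, 0]) ** 2 + (xy[cand, 1] - xy[i, 1]) ** 2)
        order = np.lexsort((ids[cand], d))[: config.k]
        fracs.append(qcc[cand[order]].mean())
    fr = np.asarray(fracs, dtype=float)
    if fr.size == 0:
        return ClusterIndexResult(
            qcc_ci=float("nan"), defined=False, fractions=fr,
            n_focal_retained=0, n_focal_discarded=n_disc,
        )
    return ClusterIndexResult(
        qcc_ci=float(fr.mean()), defined=True, fractions=fr,
        n_focal_retained=fr.size, n_focal_discarded=n_disc,
    )


def permutation_null(
    map_or_xy,
    n_qcc: int,
    config: ClusterIndexConfig | None = None,
    cell_ids=None,
    index: NeighborIndex | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Permutation-null scores: B uniform draws of n_qcc pseudo-QCC tumor cells.

    Returns ``(scores, n_undefined)`` where ``scores`` holds the defined
    replicate indices (NaN-free) and ``n_undefined`` counts replicates in
    which every pseudo-focal was discarded.  Deterministic given
    ``config.seed`` (or an explicit ``rng``).
    """
    config = config or ClusterIndexConfig()
    xy, _, ids = _as_tumor_arrays(map_or_xy, None, cell_ids)
    n = len(xy)
    if n_qcc < 1:
        raise ValidationError("n_qcc must be >= 1")
    if n_qcc > n:
        raise ValidationError(f"n_qcc={n_qcc} exceeds tumor cell count {n}")
    if index is None:
        index = build_neighbor_index(xy, ids, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = []
    n_undef = 0
    labels = np.zeros(n, dtype=bool)
    for _ in range(config.B):
        chosen = rng.choice(n, size=n_qcc, replace=False)
        labels[:] = False
        labels[chosen] = True
        fracs, n_ret, _ = _scores_from_index(index, labels)
        if n_ret == 0:
            n_undef += 1
        else:
            scores.append(fracs.mean())
    return np.asarray(scores, dtype=float), n_undef


def empirical_p(observed: float, scores: Sequence[float]) -> float:
    """Add-one one-sided empirical p: (1 + #{score >= observed}) / (B + 1).

    Always strictly positive; one-sided toward clustering (high index).
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise ValidationError("no defined permutation scores; p undefined")
    return float((1 + np.sum(scores >= observed)) / (scores.size + 1))


def exact_null(
    map_or_xy, n_qcc: int, config: ClusterIndexConfig | None = None,
    cell_ids=None, max_labelings: int = 100_000,
) -> tuple[np.ndarray, int]:
    """Exhaustive null: cluster index for every C(N, n_qcc) labeling.

    Test oracle for the Monte-Carlo engine; errors out when the
    combinatorial bound exceeds ``max_labelings``.  Returns
    ``(defined score multiset, n_undefined labelings)``.
    """
    config = config or ClusterIndexConfig()
    xy, _, ids = _as_tumor_arrays(map_or_xy, None, cell_ids)
    n = len(xy)
    total = math.comb(n, n_qcc)
    if total > max_labelings:
        raise ValidationError(
            f"C({n}, {n_qcc}) = {total} labelings exceed {max_labelings}; use Monte-Carlo"
        )
    index = build_neighbor_index(xy, ids, config)
    scores = []
    n_undef = 0
    labels = np.zeros(n, dtype=bool)
    for combo in itertools.combinations(range(n), n_qcc):
        labels[:] = False
        labels[list(combo)] = True
        fracs, n_ret, _ = _scores_from_index(index, labels)
        if n_ret == 0:
            n_undef += 1
        else:
            scores.append(fracs.mean())
    return np.asarray(scores, dtype=float), n_undef


def cluster_index_test(
    map_or_xy, labels=None, config: ClusterIndexConfig | None = None, cell_ids=None
) -> ClusterIndexResult:
    """Full pipeline: observed index, permutation null, empirical p-value."""
    config = config or ClusterIndexConfig()
    xy, qcc, ids = _as_tumor_arrays(map_or_xy, labels, cell_ids)
    if not qcc.any():
        raise NoQCCError("map contains no QCC")
    index = build_neighbor_index(xy, ids, config)
    obs = qcc_ci(xy, qcc, config, cell_ids=ids, index=index)
    scores, n_undef = permutation_null(xy, int(qcc.sum()), config, cell_ids=ids, index=index)
    obs.permutation_scores = scores
    obs.n_undefined_permutations = n_undef
    obs.seed = config.seed
    if obs.defined and scores.size:
        obs.p_value = empirical_p(obs.qcc_ci, scores)
    return obs
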