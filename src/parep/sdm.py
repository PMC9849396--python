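"""Post-processing of species distribution model outputs into binary ranges.

Model *fitting* is out of scope; this module takes per-technique
suitability surfaces (values in [0, 1], NaN = nodata) and turns them into
the final presence/absence maps a gap analysis consumes:

1. evaluate each single-technique model (TSS, rank-based AUC);
2. drop members with TSS ≤ 0.8 or AUC ≤ 0.8 (strict inequalities kept);
3. ensemble the survivors as a TSS-weighted convex combination;
4. quality-control the ensemble (kept iff TSS ≥ 0.7 and AUC ≥ 0.8);
5. binarise at the 10-percentile training-presence threshold;
6. clip presence to within a distance of known occurrences;
7. for futures: average GCM projections, then restrict to cells a species
   could plausibly reach (dispersal distance from the current range).

Steps 5–7 form an anti-extensive chain: none of them ever adds a presence
cell to its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .grid import GridSpec, require_same_grid

SCENARIOS = ("current", "rcp45", "rcp85")

#: member-filter thresholds (strict) and ensemble QC thresholds (non-strict)
MEMBER_MIN_TSS = 0.8
MEMBER_MIN_AUC = 0.8
ENSEMBLE_MIN_TSS = 0.7
ENSEMBLE_MIN_AUC = 0.8


class UnmodellableSpeciesError(ValueError):
    """No single-technique model survived the performance filter."""


@dataclass
class SuitabilityMap:
    species_id: str
    technique_tag: str
    values: np.ndarray  # floats in [0, 1]; NaN = nodata
    grid: GridSpec
    tss: float = float("nan")
    auc: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("suitability raster does not match its grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


@dataclass
class BinaryRangeMap:
    """A species' presence/absence raster for one scenario."""

    species_id: str
    scenario: str
    presence: np.ndarray  # bool
    grid: GridSpec
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.grid.shape:
            raise ValueError("presence raster does not match its grid")

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())

    @property
    def range_km2(self) -> float:
        return self.n_cells * self.grid.cell_area_km2

    @property
    def is_empty(self) -> bool:
        return not self.presence.any()


def _values_at(raster: np.ndarray, points: np.ndarray, grid: GridSpec) -> np.ndarray:
    rc = grid.points_to_cells(points)
    return raster[rc[:, 0], rc[:, 1]]


def evaluate_tss(
    predicted: np.ndarray,
    presences: np.ndarray,
    absences: np.ndarray,
    grid: GridSpec,
) -> float:
    """True skill statistic: sensitivity + specificity − 1, in [−1, 1]."""
    presences = np.atleast_2d(presences)
    absences = np.atleast_2d(absences)
    if len(presences) == 0 or len(absences) == 0:
        raise ValueError("TSS needs at least one presence and one absence point")
    pred = np.asarray(predicted, dtype=bool)
    sens = float(np.mean(_values_at(pred, presences, grid)))
    spec = float(np.mean(~_values_at(pred, absences, grid)))
    return sens + spec - 1.0


def evaluate_auc(
    suitability: np.ndarray,
    presences: np.ndarray,
    absences: np.ndarray,
    grid: GridSpec,
) -> float:
    """Rank-based AUC (ties count one half).

    Equals the probability that a randomly drawn presence score exceeds a
    randomly drawn absence score, i.e. the Mann–Whitney U statistic
    normalised by the number of presence/absence pairs.
    """
    presences = np.atleast_2d(presences)
    absences = np.atleast_2d(absences)
    if len(presences) == 0 or len(absences) == 0:
        raise ValueError("AUC needs at least one presence and one absence point")
    sp = _values_at(np.asarray(suitability, float), presences, grid)
    sa = _values_at(np.asarray(suitability, float), absences, grid)
    if np.isnan(sp).any() or np.isnan(sa).any():
        raise ValueError("evaluation point falls on a nodata cell")
    ranks = rankdata(np.concatenate([sp, sa]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sa)))


def filter_members(
    members: list[SuitabilityMap],
    min_tss: float = MEMBER_MIN_TSS,
    min_auc: float = MEMBER_MIN_AUC,
) -> list[SuitabilityMap]:
    """Keep members whose TSS and AUC both *strictly* exceed the cutoffs."""
    return [m for m in members if m.tss > min_tss and m.auc > min_auc]


def member_qc_table(
    members: list[SuitabilityMap],
    min_tss: float = MEMBER_MIN_TSS,
    min_auc: float = MEMBER_MIN_AUC,
):
    """Per-member QC report (species_id, technique, tss, auc, kept), ready
    to write as CSV alongside the ensembles."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species_id": m.species_id,
                "technique": m.technique_tag,
                "tss": m.tss,
                "auc": m.auc,
                "kept": bool(m.tss > min_tss and m.auc > min_auc),
            }
            for m in members
        ],
        columns=["species_id", "technique", "tss", "auc", "kept"],
    )


def ensemble(members: list[SuitabilityMap]) -> SuitabilityMap:
    """TSS-weighted cell-wise convex combination of member suitabilities.

    Weights are proportional to each member's raw TSS, so the output is
    bounded cell-wise by the member min and max.
    """
    if not members:
        raise UnmodellableSpeciesError(
            "no members survived the performance filter; species cannot be modelled"
        )
    grid = members[0].grid
    for m in members[1:]:
        require_same_grid(grid, m.grid)
        if m.species_id != members[0].species_id:
            raise ValueError("ensemble members must belong to one species")
    w = np.array([m.tss for m in members], dtype=float)
    if np.any(w <= 0):
        raise ValueError("TSS weights must be positive (filter members first)")
    w = w / w.sum()
    stack = np.stack([m.values for m in members])
    values = np.tensordot(w, stack, axes=1)
    return SuitabilityMap(
        species_id=members[0].species_id,
        technique_tag="ensemble",
        values=values,
        grid=grid,
    )


def qc_ensemble(
    tss: float,
    auc: float,
    min_tss: float = ENSEMBLE_MIN_TSS,
    min_auc: float = ENSEMBLE_MIN_AUC,
) -> bool:
    """True iff the ensemble passes QC (TSS ≥ 0.7 and AUC ≥ 0.8).

    The discard rule is strict (< 0.7 / < 0.8), so boundary values pass.
    """
    return tss >= min_tss and auc >= min_auc


def threshold_10pct(
    suitability: SuitabilityMap,
    presences: np.ndarray,
    scenario: str = "current",
    percentile: float = 10.0,
) -> BinaryRangeMap:
    """Binarise at the 10th percentile of suitability at training presences.

    The percentile uses linear interpolation between order statistics, so
    at least 90% of the training presences fall inside the predicted
    range. Cells with suitability ≥ threshold (and not nodata) are
    presence.
    """
    vals = _values_at(suitability.values, np.atleast_2d(presences), suitability.grid)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all training presences fall on nodata cells")
    t = float(np.percentile(vals, percentile))
    with np.errstate(invalid="ignore"):
        presence = suitability.values >= t
    presence &= np.isfinite(suitability.values)
    return BinaryRangeMap(
        species_id=suitability.species_id,
        scenario=scenario,
        presence=presence,
        grid=suitability.grid,
    )


def _distance_to_points(grid: GridSpec, points: np.ndarray) -> np.ndarray:
    """Raster of cell-center Euclidean distances to the nearest point."""
    cx, cy = grid.cell_centers()
    tree = cKDTree(np.atleast_2d(points))
    d, _ = tree.query(np.column_stack([cx, cy]))
    return d.reshape(grid.shape)


def clip_to_occurrences(
    range_map: BinaryRangeMap,
    occurrences: np.ndarray,
    max_dist: float,
) -> BinaryRangeMap:
    """Drop presence cells farther than ``max_dist`` km from any occurrence."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    occurrences = np.atleast_2d(occurrences)
    if occurrences.size == 0:
        raise ValueError("at least one occurrence point is required")
    keep = _distance_to_points(range_map.grid, occurrences) <= max_dist
    return BinaryRangeMap(
        species_id=range_map.species_id,
        scenario=range_map.scenario,
        presence=range_map.presence & keep,
        grid=range_map.grid,
        flags=set(range_map.flags),
    )


def average_gcms(projections: list[SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise arithmetic mean of per-GCM suitability projections."""
    if not projections:
        raise ValueError("at least one projection is required")
    grid = projections[0].grid
    for p in projections[1:]:
        require_same_grid(grid, p.grid)
    values = np.mean(np.stack([p.values for p in projections]), axis=0)
    return SuitabilityMap(
        species_id=projections[0].species_id,
        technique_tag="gcm_mean",
        values=values,
        grid=grid,
    )


def range_edge(presence: np.ndarray) -> np.ndarray:
    """Presence cells with at least one absent 4-neighbour (grid border
    counts as absent)."""
    p = np.asarray(presence, dtype=bool)
    interior = np.zeros_like(p)
    interior[1:-1, 1:-1] = (
        p[1:-1, 1:-1] & p[:-2, 1:-1] & p[2:, 1:-1] & p[1:-1, :-2] & p[1:-1, 2:]
    )
    return p & ~interior


def apply_dispersal(
    future: BinaryRangeMap,
    current: BinaryRangeMap,
    max_dist: float,
) -> BinaryRangeMap:
    """Restrict a future range to cells reachable from the current range.

    A future presence cell is kept iff its center lies within ``max_dist``
    km of the current range (distance zero inside it, otherwise Euclidean
    distance to the nearest current presence-cell center, which is
    attained on the range edge). ``max_dist = inf`` is the identity;
    ``max_dist = 0`` keeps only cells overlapping the current range.
    """
    if future.species_id != current.species_id:
        raise ValueError("future and current maps must belong to one species")
    require_same_grid(future.grid, current.grid)
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if np.isinf(max_dist) or current.is_empty:
        keep = (
            np.ones(future.grid.shape, bool)
            if np.isinf(max_dist)
            else np.zeros(future.grid.shape, bool)
        )
    else:
        grid = future.grid
        edge = range_edge(current.presence)
        rr, cc = np.nonzero(edge)
        pts = np.column_stack(
            [
                grid.origin_x + (cc + 0.5) * grid.cell_side,
                grid.origin_y + (rr + 0.5) * grid.cell_side,
            ]
        )
        keep = current.presence | (_distance_to_points(grid, pts) <= max_dist)
    out = BinaryRangeMap(
        species_id=future.species_id,
        scenario=future.scenario,
        presence=future.presence & keep,
        grid=future.grid,
        flags=set(future.flags),
    )
    if current.is_empty and not np.isinf(max_dist):
        out.flags.add("no_current_range")
    return out
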