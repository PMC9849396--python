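"""Spatial null model for protected-area placement and the randomization test.

Each decadal cohort's PA polygons are rigidly moved — rotated, optionally
mirrored, and translated — to random feasible positions inside the study
area, preserving number, size and shape. Placements must not overlap each
other nor the real PAs of earlier decades, and must stay inside the study
polygon (touching the border is allowed), so total protected area is
conserved. Representation of the real network is then compared with the
distribution over randomized networks using the standard permutation
p-value p = (1 + #{null ≥ observed}) / (N + 1), one-sided for gains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec
from .representation import (
    NetworkSnapshot,
    DecadalCohort,
    ProtectedArea,
    coverage_matrix,
    percent_met_by_stratum,
    rasterize_network,
    _strata,
)

_AREA_TOL = 1e-9  # relative tolerance on rigid-motion area preservation
_OVERLAP_TOL = 1e-9  # absolute area below which an intersection counts as contact


class PlacementInfeasibleError(RuntimeError):
    pass


class ReplicateFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Mirror (about the centroid's vertical axis), then rotate about the
    centroid, then translate."""

    rotation_deg: float
    mirrored: bool
    translation: tuple[float, float]

    def apply(self, geom: BaseGeometry) -> BaseGeometry:
        c = geom.centroid
        out = geom
        if self.mirrored:
            out = affinity.scale(out, xfact=-1.0, yfact=1.0, origin=c)
        out = affinity.rotate(out, self.rotation_deg, origin=c)
        return affinity.translate(out, *self.translation)


@dataclass
class NullReplicate:
    cohort_label: str
    replicate_index: int
    seed: int
    placed: list[tuple[str, RigidTransform, BaseGeometry]]
    group_representation: dict[str, float] = field(default_factory=dict)

    @property
    def geometries(self) -> list[BaseGeometry]:
        return [g for (_, _, g) in self.placed]


@dataclass
class RandTestResult:
    cohort_label: str
    stratum: str
    scenario: str
    observed: float
    null_values: np.ndarray
    p_value: float
    significant: bool
    alpha: float


def _is_rectangle(poly: BaseGeometry) -> bool:
    if not isinstance(poly, Polygon):
        return False
    minx, miny, maxx, maxy = poly.bounds
    return abs(poly.area - (maxx - minx) * (maxy - miny)) <= 1e-9 * max(
        poly.area, 1.0
    )


class _PlacementSampler:
    """Precomputed state for repeatedly placing one polygon in one study
    area; the hot loop works on raw coordinate arrays and only materialises
    a shapely geometry for candidates whose bounds fit."""

    def __init__(self, polygon: BaseGeometry, study: BaseGeometry):
        if polygon.area > study.area:
            raise PlacementInfeasibleError("polygon larger than the study area")
        self.polygon = polygon
        self.study = study
        self.sbounds = study.bounds
        self.rect_study = _is_rectangle(study)
        if not self.rect_study:
            shapely.prepare(study)
        c = polygon.centroid
        self.cx0, self.cy0 = c.x, c.y
        self.coords = shapely.get_coordinates(polygon)

    def sample(
        self, rng: np.random.Generator, max_attempts: int = 1000
    ) -> tuple[RigidTransform, BaseGeometry]:
        sminx, sminy, smaxx, smaxy = self.sbounds
        coords = self.coords
        for _ in range(max_attempts):
            rot = float(rng.uniform(0.0, 360.0))
            mirrored = bool(rng.random() < 0.5)
            th = math.radians(rot)
            mx = -1.0 if mirrored else 1.0
            # linear part of (rotate ∘ mirror) about the centroid
            a, b = math.cos(th) * mx, -math.sin(th)
            d, e = math.sin(th) * mx, math.cos(th)
            xoff = self.cx0 - a * self.cx0 - b * self.cy0
            yoff = self.cy0 - d * self.cx0 - e * self.cy0
            x = coords[:, 0] * a + coords[:, 1] * b + xoff
            y = coords[:, 0] * d + coords[:, 1] * e + yoff
            minx, maxx = x.min(), x.max()
            miny, maxy = y.min(), y.max()
            if maxx - minx > smaxx - sminx or maxy - miny > smaxy - sminy:
                continue
            tx = float(rng.uniform(sminx - minx, smaxx - maxx))
            ty = float(rng.uniform(sminy - miny, smaxy - maxy))
            cand = shapely.transform(
                self.polygon,
                lambda p: np.column_stack(
                    [
                        p[:, 0] * a + p[:, 1] * b + xoff + tx,
                        p[:, 0] * d + p[:, 1] * e + yoff + ty,
                    ]
                ),
            )
            if self.rect_study or shapely.covers(self.study, cand):
                return RigidTransform(rot, mirrored, (tx, ty)), cand
        raise PlacementInfeasibleError(
            f"no feasible placement found in {max_attempts} attempts"
        )


def sample_transform(
    polygon: BaseGeometry,
    study: BaseGeometry,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[RigidTransform, BaseGeometry]:
    """Draw a uniform random rigid motion that keeps the polygon inside the
    study area.

    Rotation is uniform on [0°, 360°), mirroring (about the vertical axis
    through the centroid) is a fair coin, and the translation is
    rejection-sampled so the placement is uniform over all feasible
    positions of the (rotated, mirrored) polygon's bounding box inside the
    study bounding box, accepted when the polygon lies inside the study
    polygon (boundary contact allowed). Multi-part geometries move as one
    rigid unit; rigid motion preserves area exactly up to floating point.
    """
    return _PlacementSampler(polygon, study).sample(rng, max_attempts)


def _disjoint_from(
    cand: BaseGeometry, others: list[BaseGeometry], bounds: list[tuple]
) -> bool:
    cb = cand.bounds
    for geom, b in zip(others, bounds):
        if cb[0] < b[2] and cb[2] > b[0] and cb[1] < b[3] and cb[3] > b[1]:
            if cand.intersection(geom).area > _OVERLAP_TOL:
                return False
    return True


def build_null_network(
    cohort: DecadalCohort,
    fixed: list[ProtectedArea],
    study: BaseGeometry,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    max_restarts: int = 50,
) -> list[tuple[str, RigidTransform, BaseGeometry]]:
    """Place every cohort PA at a random feasible location.

    PAs are placed largest-first (large polygons dominate feasibility);
    each gets up to ``max_attempts`` rejection samples against containment
    and non-overlap with already-placed null PAs and the *real* earlier
    ``fixed`` PAs. If any PA cannot be placed the whole replicate restarts
    (up to ``max_restarts``) to avoid order-induced bias from partially
    stuck configurations.
    """
    if not cohort.members:
        raise ValueError(f"cohort {cohort.label} has no members")
    order = sorted(cohort.members, key=lambda p: -p.geometry.area)
    fixed_geoms = [p.geometry for p in fixed]
    fixed_bounds = [g.bounds for g in fixed_geoms]
    free = study.area - sum(g.area for g in fixed_geoms)
    if cohort.total_area_km2 > free + 1e-9:
        raise PlacementInfeasibleError(
            f"cohort {cohort.label} area {cohort.total_area_km2:.1f} km2 exceeds "
            f"unprotected study area {free:.1f} km2"
        )
    samplers = {pa.pa_id: _PlacementSampler(pa.geometry, study) for pa in order}
    for _ in range(max_restarts):
        placed: list[tuple[str, RigidTransform, BaseGeometry]] = []
        geoms: list[BaseGeometry] = list(fixed_geoms)
        bounds: list[tuple] = list(fixed_bounds)
        ok = True
        for pa in order:
            success = False
            sampler = samplers[pa.pa_id]
            for _ in range(max_attempts):
                t, cand = sampler.sample(rng, max_attempts=1000)
                if _disjoint_from(cand, geoms, bounds):
                    placed.append((pa.pa_id, t, cand))
                    geoms.append(cand)
                    bounds.append(cand.bounds)
                    success = True
                    break
            if not success:
                ok = False
                smallest = order[-1]
                break
        if ok:
            return placed
    raise ReplicateFailureError(
        f"cohort {cohort.label}: could not place PA {smallest.pa_id} "
        f"after {max_restarts} replicate restarts"
    )


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Fixed, recorded splitting rule for per-replicate seeds."""
    return (master_seed * 1_000_003 + replicate_index) % (2**31 - 1)


def _representation_of_mask(
    mask: np.ndarray,
    presence: np.ndarray,
    targets: np.ndarray,
    strata: dict[str, np.ndarray],
) -> dict[str, float]:
    frac, counts = coverage_matrix(presence, mask.reshape(1, -1))
    met = np.where(counts == 0, False, frac[:, 0] >= targets)
    return percent_met_by_stratum(met, strata)


def randomize_decade(
    cohort: DecadalCohort,
    fixed: list[ProtectedArea],
    study: BaseGeometry,
    grid: GridSpec,
    species_table: pd.DataFrame,
    range_maps: dict,
    targets: dict[str, float],
    n_replicates: int = 100,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[list[NullReplicate], dict[str, float]]:
    """Generate N randomized networks for one cohort and score each.

    Returns the replicates (each carrying its per-stratum percent-met on
    the union of the fixed real network and the null cohort) and the
    observed per-stratum percent-met of the real network (fixed + real
    cohort). Replicate seeds derive from the master seed by a fixed rule
    recorded on each replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sids = [
        s for s in species_table["species_id"] if s in range_maps
    ]
    table = species_table[species_table["species_id"].isin(sids)].reset_index(
        drop=True
    )
    presence = np.stack([range_maps[s].presence.ravel() for s in sids])
    tgt = np.array([targets[s] for s in sids])
    strata = _strata(table)

    fixed_mask = rasterize_network(fixed, grid).ravel()
    real_mask = fixed_mask | rasterize_network(cohort.members, grid).ravel()
    observed = _representation_of_mask(real_mask, presence, tgt, strata)

    replicates = []
    for i in range(1, n_replicates + 1):
        rseed = replicate_seed(seed, i)
        rng = np.random.default_rng(rseed)
        try:
            placed = build_null_network(
                cohort, fixed, study, rng, max_attempts=max_attempts
            )
        except (PlacementInfeasibleError, ReplicateFailureError) as err:
            raise ReplicateFailureError(
                f"replicate {i} of cohort {cohort.label}: {err}"
            ) from err
        null_members = [
            ProtectedArea(pid, geom, cohort.start_year)
            for (pid, _, geom) in placed
        ]
        null_mask = fixed_mask | rasterize_network(null_members, grid).ravel()
        rep = NullReplicate(
            cohort_label=cohort.label,
            replicate_index=i,
            seed=rseed,
            placed=placed,
            group_representation=_representation_of_mask(
                null_mask, presence, tgt, strata
            ),
        )
        replicates.append(rep)
    return replicates, observed


def rand_test(
    observed: float,
    null_values,
    alpha: float = 0.05,
    cohort_label: str = "",
    stratum: str = "",
    scenario: str = "current",
) -> RandTestResult:
    """One-sided permutation test for representation gains.

    p = (1 + #{null ≥ observed}) / (N + 1); significant iff p ≤ alpha.
    With N = 100 the smallest attainable p is 1/101 ≈ 0.0099.
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = int(np.sum(null_values >= observed))
    p = (1 + k) / (null_values.size + 1)
    return RandTestResult(
        cohort_label=cohort_label,
        stratum=stratum,
        scenario=scenario,
        observed=float(observed),
        null_values=null_values,
        p_value=float(p),
        significant=bool(p <= alpha),
        alpha=alpha,
    )


def save_replicates_geojson(
    replicates: list[NullReplicate], path
) -> None:
    """Write null placements as GeoJSON features carrying pa_id, replicate
    index, seed and transform parameters for exact replay."""
    from . import io as pio

    geoms = []
    props = []
    for rep in replicates:
        for pid, t, geom in rep.placed:
            geoms.append(geom)
            props.append(
                {
                    "pa_id": pid,
                    "cohort": rep.cohort_label,
                    "replicate": rep.replicate_index,
                    "seed": rep.seed,
                    "rotation_deg": t.rotation_deg,
                    "mirrored": t.mirrored,
                    "tx": t.translation[0],
                    "ty": t.translation[1],
                }
            )
    pio.write_geojson(path, geoms, props)


def decade_randomization_tests(
    cohorts: list[DecadalCohort],
    study: BaseGeometry,
    grid: GridSpec,
    species_table: pd.DataFrame,
    range_maps: dict,
    targets: dict[str, float],
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    scenario: str = "current",
    max_attempts: int = 1000,
    replicates_dir=None,
) -> pd.DataFrame:
    """Run the randomization test for every decadal cohort and stratum.

    Earlier-decade PAs always enter at their real locations; only the
    focal cohort is randomized. Cohort replicate seeds are offset by the
    cohort's position so decades are independent. With ``replicates_dir``
    set, every cohort's null placements are written there as
    ``null_replicates_<cohort>.geojson``.
    """
    rows = []
    ordered = sorted(cohorts, key=lambda c: c.end_year)
    for ci, cohort in enumerate(ordered):
        if not cohort.members:
            continue
        fixed = [pa for c in ordered[:ci] for pa in c.members]
        reps, observed = randomize_decade(
            cohort,
            fixed,
            study,
            grid,
            species_table,
            range_maps,
            targets,
            n_replicates=n_replicates,
            seed=replicate_seed(seed, 7919 * (ci + 1)),
            max_attempts=max_attempts,
        )
        if replicates_dir is not None:
            from pathlib import Path

            d = Path(replicates_dir)
            d.mkdir(parents=True, exist_ok=True)
            save_replicates_geojson(
                reps, d / f"null_replicates_{cohort.label}.geojson"
            )
        for stratum in observed:
            nulls = [r.group_representation[stratum] for r in reps]
            res = rand_test(
                observed[stratum],
                nulls,
                alpha=alpha,
                cohort_label=cohort.label,
                stratum=stratum,
                scenario=scenario,
            )
            rows.append(
                {
                    "cohort": cohort.label,
                    "stratum": stratum,
                    "scenario": scenario,
                    "observed": res.observed,
                    "null_mean": float(np.mean(res.null_values)),
                    "null_q95": float(np.quantile(res.null_values, 0.95)),
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "n_replicates": n_replicates,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def climate_randomization(
    last_cohort: DecadalCohort,
    fixed: list[ProtectedArea],
    study: BaseGeometry,
    grid: GridSpec,
    species_table: pd.DataFrame,
    future_maps: dict[str, dict],
    targets: dict[str, float],
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_attempts: int = 1000,
) -> pd.DataFrame:
    """Randomization test of the last decadal expansion against future ranges.

    ``future_maps`` maps scenario -> {species_id -> BinaryRangeMap}
    (post-dispersal). Only the last cohort is randomized; all earlier PAs
    stay fixed at their real locations. Species whose future range
    vanished stay in denominators with ``met = False``.
    """
    rows = []
    for si, (scenario, maps) in enumerate(sorted(future_maps.items())):
        missing = [
            s for s in species_table["species_id"] if s not in maps
        ]
        if missing:
            raise ValueError(
                f"missing {scenario} range maps for species: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        reps, observed = randomize_decade(
            last_cohort,
            fixed,
            study,
            grid,
            species_table,
            maps,
            targets,
            n_replicates=n_replicates,
            seed=replicate_seed(seed, 104729 * (si + 1)),
            max_attempts=max_attempts,
        )
        for stratum in observed:
            nulls = [r.group_representation[stratum] for r in reps]
            res = rand_test(
                observed[stratum],
                nulls,
                alpha=alpha,
                cohort_label=last_cohort.label,
                stratum=stratum,
                scenario=scenario,
            )
            rows.append(
                {
                    "cohort": last_cohort.label,
                    "stratum": stratum,
                    "scenario": scenario,
                    "observed": res.observed,
                    "null_mean": float(np.mean(res.null_values)),
                    "null_q95": float(np.quantile(res.null_values, 0.95)),
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "n_replicates": n_replicates,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
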