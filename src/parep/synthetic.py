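"""Seed-reproducible synthetic worlds for exercising the gap-analysis pipeline.

A synthetic world emulates the statistical structure the analysis assumes
about a tropical montane region without pretending to be real biogeography:

* a planar study area with an elevation gradient (a "lowland" side and a
  "montane" side) plus smooth noise;
* five taxonomic groups whose range-size distributions differ — birds and
  mammals get large, overlapping, low-elevation ranges; amphibians,
  reptiles and many threatened species get small scattered montane ranges;
* a protected-area declaration history organised in decadal cohorts whose
  placement drifts from high to low elevation over the decades;
* future-scenario ranges obtained by shifting each range upslope and
  eroding it to a configurable fraction of its current area (some ranges
  may disappear entirely).

Everything is a pure function of ``(config, seed)``: per-stage random
generators are spawned from the master seed with fixed spawn keys, so any
stage can be regenerated in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely import affinity
from scipy.ndimage import gaussian_filter

from .grid import GridSpec
from .representation import ProtectedArea
from .sdm import BinaryRangeMap

log = logging.getLogger(__name__)

GROUPS = ("bird", "mammal", "amphibian", "reptile", "plant")
SCENARIOS = ("current", "rcp45", "rcp85")


class InvalidConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GroupConfig:
    """Per-group species generation parameters.

    ``median_range_km2`` and ``log_sd`` parameterise a log-normal range-size
    distribution; ``elev_pref``/``elev_sd`` (m) give the Gaussian elevation
    density from which range seed cells are drawn.
    """

    n_species: int
    median_range_km2: float
    log_sd: float
    elev_pref: float
    elev_sd: float
    n_occurrences: int = 25
    dispersal_km: float = 20.0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise InvalidConfigError("n_species must be >= 0")
        if self.median_range_km2 <= 0 or self.log_sd < 0:
            raise InvalidConfigError("range-size distribution must be positive")


@dataclass
class ThreatConfig:
    """Probability of the threatened flag as a decreasing function of range size.

    ``p = p_max / (1 + (R / midpoint_km2) ** steepness)`` — a logistic in log
    range size, so small-ranged species are the most likely to be flagged.
    """

    p_max: float = 0.5
    midpoint_km2: float = 1000.0
    steepness: float = 1.5

    def probability(self, range_km2: np.ndarray) -> np.ndarray:
        r = np.asarray(range_km2, dtype=float)
        return self.p_max / (1.0 + (r / self.midpoint_km2) ** self.steepness)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise InvalidConfigError("p_max must lie in [0, 1]")


@dataclass
class DecadeSpec:
    """One decadal declaration cohort of the synthetic PA history."""

    label: str
    start_year: int
    end_year: int
    n_pas: int
    total_area_km2: float
    elev_mean: float
    elev_sd: float = 300.0

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise InvalidConfigError(f"decade {self.label}: start after end")
        if self.n_pas < 0 or self.total_area_km2 < 0:
            raise InvalidConfigError(f"decade {self.label}: negative count/area")


@dataclass
class ScenarioShift:
    """Directional range displacement (km, upslope) and areal shrink factor."""

    displacement_km: float
    shrink_factor: float

    def __post_init__(self) -> None:
        if not 0.0 < self.shrink_factor <= 1.0:
            raise InvalidConfigError("shrink_factor must lie in (0, 1]")


@dataclass
class SyntheticWorldConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(60, 60))
    #: fraction of the grid bounding box covered by the rectangular study
    #: area (must be >= 0.5 to keep margins thin); 1.0 = whole grid
    study_area_fraction: float = 1.0
    #: unit-vector direction in which elevation increases
    gradient_direction: tuple[float, float] = (1.0, 0.0)
    #: total relief (m) across the study area along the gradient
    relief_m: float = 3000.0
    base_elevation_m: float = 200.0
    noise_sd_m: float = 150.0
    noise_corr_cells: float = 3.0
    groups: dict[str, GroupConfig] = field(default_factory=lambda: default_groups())
    threat: ThreatConfig = field(default_factory=ThreatConfig)
    #: None = the default eight-decade history with decade totals scaled to
    #: the study-area size (the default totals are written for ~18,000 km²)
    pa_history: list[DecadeSpec] | None = None
    future_shift: dict[str, ScenarioShift] = field(
        default_factory=lambda: {
            "rcp45": ScenarioShift(displacement_km=6.0, shrink_factor=0.7),
            "rcp85": ScenarioShift(displacement_km=12.0, shrink_factor=0.5),
        }
    )
    max_place_attempts: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 < self.study_area_fraction <= 1.0:
            raise InvalidConfigError("study_area_fraction must lie in (0, 1]")
        if self.study_area_fraction < 0.5:
            raise InvalidConfigError(
                "study area must cover at least half the grid bounding box"
            )
        norm = math.hypot(*self.gradient_direction)
        if norm == 0:
            raise InvalidConfigError("gradient_direction must be a nonzero vector")
        self.gradient_direction = (
            self.gradient_direction[0] / norm,
            self.gradient_direction[1] / norm,
        )
        for name in self.groups:
            if name not in GROUPS:
                raise InvalidConfigError(f"unknown group {name!r}")
        if self.pa_history is None:
            area = self.grid.width * self.grid.height * self.study_area_fraction
            scale = area / 18_000.0
            self.pa_history = [
                DecadeSpec(d.label, d.start_year, d.end_year, d.n_pas,
                           d.total_area_km2 * scale, d.elev_mean, d.elev_sd)
                for d in default_pa_history()
            ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "n_rows": self.grid.n_rows,
            "n_cols": self.grid.n_cols,
            "cell_side": self.grid.cell_side,
            "origin_x": self.grid.origin_x,
            "origin_y": self.grid.origin_y,
        }
        return d


def default_groups() -> dict[str, GroupConfig]:
    """Default taxonomic structure: large overlapping lowland ranges for
    birds/mammals, small scattered montane ranges for herpetofauna, plants
    in between. Counts keep the group ordering of a vertebrate+plant fauna
    (plants most numerous, mammals fewest) at a size a laptop can iterate."""
    return {
        "bird": GroupConfig(40, median_range_km2=6000.0, log_sd=0.8,
                            elev_pref=400.0, elev_sd=700.0),
        "mammal": GroupConfig(15, median_range_km2=5000.0, log_sd=0.8,
                              elev_pref=400.0, elev_sd=700.0),
        "amphibian": GroupConfig(25, median_range_km2=300.0, log_sd=1.0,
                                 elev_pref=2200.0, elev_sd=500.0,
                                 dispersal_km=5.0),
        "reptile": GroupConfig(20, median_range_km2=500.0, log_sd=1.0,
                               elev_pref=2000.0, elev_sd=500.0,
                               dispersal_km=5.0),
        "plant": GroupConfig(50, median_range_km2=1500.0, log_sd=1.2,
                             elev_pref=1200.0, elev_sd=900.0,
                             dispersal_km=5.0),
    }


def default_pa_history() -> list[DecadeSpec]:
    """Eight decadal cohorts (1937–2015) with a mid-history expansion peak
    and mean placement elevation drifting from high to low, mirroring a
    network that began on páramo watersheds and later moved toward
    species-rich foothills."""
    decades = [
        ("1937-1945", 1937, 1945, 1, 150.0, 2800.0, 300.0),
        ("1946-1955", 1946, 1955, 2, 250.0, 2600.0, 300.0),
        ("1956-1965", 1956, 1965, 2, 350.0, 2400.0, 300.0),
        ("1966-1975", 1966, 1975, 3, 500.0, 2100.0, 350.0),
        ("1976-1985", 1976, 1985, 4, 900.0, 1700.0, 400.0),
        ("1986-1995", 1986, 1995, 5, 1300.0, 1200.0, 450.0),
        ("1996-2005", 1996, 2005, 4, 850.0, 900.0, 450.0),
        ("2006-2015", 2006, 2015, 3, 550.0, 600.0, 450.0),
    ]
    return [
        DecadeSpec(label, y0, y1, n, area, elev, sd)
        for (label, y0, y1, n, area, elev, sd) in decades
    ]


# ---------------------------------------------------------------------------
# species records


@dataclass
class SpeciesRecord:
    species_id: str
    group: str
    threatened: bool
    range_km2: float
    occurrences: np.ndarray  # (n, 2) planar points inside the current range

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.range_km2 <= 0:
            raise ValueError("range_km2 must be positive")


@dataclass
class SyntheticWorld:
    """Bundle of everything one seed generates."""

    config: SyntheticWorldConfig
    study_area: Polygon
    elevation: np.ndarray
    study_mask: np.ndarray  # bool raster: cell center inside study area
    species: list[SpeciesRecord]
    ranges: dict[str, dict[str, BinaryRangeMap]]  # scenario -> species_id -> map
    protected_areas: list[ProtectedArea]

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


# ---------------------------------------------------------------------------
# generation stages


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def make_study_area(config: SyntheticWorldConfig) -> tuple[Polygon, np.ndarray]:
    """Build the study polygon and elevation raster.

    The study area is a rectangle centred in the grid covering
    ``study_area_fraction`` of the grid bounding box. Elevation increases
    linearly along ``gradient_direction`` with total relief ``relief_m``,
    plus Gaussian-smoothed noise (zero-noise configs give an exactly
    monotone surface along the gradient).
    """
    grid = config.grid
    minx, miny, maxx, maxy = grid.bounds
    f = math.sqrt(config.study_area_fraction)
    w, h = grid.width * f, grid.height * f
    cx0, cy0 = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    study = box(cx0 - w / 2, cy0 - h / 2, cx0 + w / 2, cy0 + h / 2)
    if study.area <= 0 or not study.is_valid:
        raise InvalidConfigError("degenerate study-area polygon")

    cx, cy = grid.cell_centers()
    dx, dy = config.gradient_direction
    proj = (cx - minx) * dx + (cy - miny) * dy
    span = max(abs(grid.width * dx) + abs(grid.height * dy), 1e-12)
    elev = config.base_elevation_m + config.relief_m * (proj - proj.min()) / span

    if config.noise_sd_m > 0:
        rng = _stage_rng(config.seed, 0)
        white = rng.standard_normal(grid.shape)
        smooth = gaussian_filter(white, sigma=config.noise_corr_cells, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            elev = elev + (smooth / sd).ravel() * config.noise_sd_m
    return study, elev.reshape(grid.shape)


def study_area_mask(study: Polygon, grid: GridSpec) -> np.ndarray:
    cx, cy = grid.cell_centers()
    return shapely.contains_xy(study, cx, cy).reshape(grid.shape)


def _grow_connected(
    seed_cell: int,
    n_cells: int,
    allowed: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a connected cell set from a seed by random frontier accretion."""
    n_rows, n_cols = shape
    in_set = np.zeros(n_rows * n_cols, dtype=bool)
    in_set[seed_cell] = True
    frontier = [seed_cell]
    size = 1
    while size < n_cells and frontier:
        k = rng.integers(len(frontier))
        cell = frontier[k]
        r, c = divmod(cell, n_cols)
        nbrs = []
        if r + 1 < n_rows:
            nbrs.append(cell + n_cols)
        if r > 0:
            nbrs.append(cell - n_cols)
        if c + 1 < n_cols:
            nbrs.append(cell + 1)
        if c > 0:
            nbrs.append(cell - 1)
        nbrs = [j for j in nbrs if allowed[j] and not in_set[j]]
        if not nbrs:
            frontier[k] = frontier[-1]
            frontier.pop()
            continue
        j = nbrs[rng.integers(len(nbrs))]
        in_set[j] = True
        frontier.append(j)
        size += 1
    return in_set


def make_species(
    config: SyntheticWorldConfig,
    study: Polygon,
    elevation: np.ndarray,
) -> tuple[list[SpeciesRecord], dict[str, BinaryRangeMap]]:
    """Generate species records and their current binary range maps.

    Range sizes are log-normal per group; each range is a connected cell
    set grown from a seed cell drawn from the group's Gaussian elevation
    density, then clipped to the study area. Occurrence points are sampled
    uniformly over range cells. The threatened flag is Bernoulli with
    probability decreasing in range size.
    """
    grid = config.grid
    rng = _stage_rng(config.seed, 1)
    mask = study_area_mask(study, grid).ravel()
    if not mask.any():
        raise GenerationError("study area contains no grid cells")
    elev_flat = elevation.ravel()
    allowed_idx = np.flatnonzero(mask)

    species: list[SpeciesRecord] = []
    range_maps: dict[str, BinaryRangeMap] = {}
    for group in GROUPS:
        gc = config.groups.get(group)
        if gc is None or gc.n_species == 0:
            continue
        # seed-cell density: Gaussian in elevation over study-area cells
        w = np.exp(
            -0.5 * ((elev_flat[allowed_idx] - gc.elev_pref) / max(gc.elev_sd, 1e-9)) ** 2
        )
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()
        sizes_km2 = gc.median_range_km2 * np.exp(
            gc.log_sd * rng.standard_normal(gc.n_species)
        )
        for i in range(gc.n_species):
            sid = f"{group}_{i:04d}"
            n_cells = max(1, int(round(sizes_km2[i] / grid.cell_area_km2)))
            if n_cells > allowed_idx.size:
                log.warning(
                    "%s: requested range %.0f km2 exceeds study area; clipping",
                    sid, sizes_km2[i],
                )
                n_cells = allowed_idx.size
            seed_cell = int(rng.choice(allowed_idx, p=w))
            in_set = _grow_connected(seed_cell, n_cells, mask, grid.shape, rng)
            presence = in_set.reshape(grid.shape)
            realized_km2 = float(in_set.sum() * grid.cell_area_km2)
            occ_cells = rng.choice(
                np.flatnonzero(in_set),
                size=min(gc.n_occurrences, int(in_set.sum())),
                replace=False,
            )
            rr, cc = np.divmod(occ_cells, grid.n_cols)
            jitter = rng.uniform(0.05, 0.95, size=(occ_cells.size, 2))
            occ = np.column_stack(
                [
                    grid.origin_x + (cc + jitter[:, 0]) * grid.cell_side,
                    grid.origin_y + (rr + jitter[:, 1]) * grid.cell_side,
                ]
            )
            threatened = bool(
                rng.random() < config.threat.probability(realized_km2)
            )
            species.append(
                SpeciesRecord(sid, group, threatened, realized_km2, occ)
            )
            range_maps[sid] = BinaryRangeMap(
                species_id=sid, scenario="current", presence=presence, grid=grid
            )
    return species, range_maps


def _sample_pa_polygon(
    area_km2: float,
    center: tuple[float, float],
    angle_deg: float,
) -> Polygon:
    half = math.sqrt(area_km2) / 2.0
    sq = box(center[0] - half, center[1] - half, center[0] + half, center[1] + half)
    return affinity.rotate(sq, angle_deg, origin=center)


def make_pa_history(
    config: SyntheticWorldConfig,
    study: Polygon,
    elevation: np.ndarray,
) -> list[ProtectedArea]:
    """Generate the decadal PA declaration history.

    Each decade places ``n_pas`` non-overlapping square reserves (randomly
    rotated) whose areas are log-normal draws rescaled to the decade's
    exact configured total, centred at cells drawn from a Gaussian density
    around the decade's target elevation. Placement is rejection-sampled
    for containment in the study area and disjointness from every PA
    placed so far; exhausting the retry budget raises an error naming the
    decade.
    """
    grid = config.grid
    rng = _stage_rng(config.seed, 2)
    mask = study_area_mask(study, grid).ravel()
    elev_flat = elevation.ravel()
    allowed_idx = np.flatnonzero(mask)
    shapely.prepare(study)

    placed: list[ProtectedArea] = []
    for decade in config.pa_history:
        if decade.n_pas == 0:
            continue
        raw = np.exp(0.5 * rng.standard_normal(decade.n_pas))
        areas = raw / raw.sum() * decade.total_area_km2
        w = np.exp(
            -0.5 * ((elev_flat[allowed_idx] - decade.elev_mean) / decade.elev_sd) ** 2
        )
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()
        for j, area in enumerate(sorted(areas, reverse=True)):
            year = int(rng.integers(decade.start_year, decade.end_year + 1))
            pa_id = f"pa_{decade.label}_{j:02d}"
            for _ in range(config.max_place_attempts):
                cell = int(rng.choice(allowed_idx, p=w))
                r, c = divmod(cell, grid.n_cols)
                center = (
                    grid.origin_x + (c + rng.random()) * grid.cell_side,
                    grid.origin_y + (r + rng.random()) * grid.cell_side,
                )
                poly = _sample_pa_polygon(area, center, rng.uniform(0.0, 360.0))
                if not shapely.covers(study, poly):
                    continue
                if any(
                    poly.intersection(p.geometry).area > 1e-12
                    for p in placed
                    if _bbox_overlap(poly.bounds, p.geometry.bounds)
                ):
                    continue
                placed.append(ProtectedArea(pa_id, poly, year))
                break
            else:
                raise GenerationError(
                    f"could not place PA of {area:.1f} km2 in decade {decade.label} "
                    f"after {config.max_place_attempts} attempts"
                )
    return placed


def _bbox_overlap(a: tuple, b: tuple) -> bool:
    return a[0] < b[2] and a[2] > b[0] and a[1] < b[3] and a[3] > b[1]


def make_future_ranges(
    current: dict[str, BinaryRangeMap],
    config: SyntheticWorldConfig,
    scenario: str,
    study_mask: np.ndarray,
) -> dict[str, BinaryRangeMap]:
    """Project each current range into a future scenario.

    The range is translated upslope (along the elevation gradient) by the
    scenario's displacement, clipped to the study area, then randomly
    eroded from its boundary inward until only ``shrink_factor`` of the
    original cell count remains. Ranges pushed off the study area come
    back empty — the synthetic analogue of a bioclimatic niche
    disappearing.
    """
    if scenario not in config.future_shift:
        raise InvalidConfigError(
            f"unknown scenario {scenario!r}; configured: {sorted(config.future_shift)}"
        )
    shift = config.future_shift[scenario]
    grid = config.grid
    dx, dy = config.gradient_direction
    dc = int(round(shift.displacement_km * dx / grid.cell_side))
    dr = int(round(shift.displacement_km * dy / grid.cell_side))
    rng = _stage_rng(config.seed, 3 if scenario == "rcp45" else 4)

    out: dict[str, BinaryRangeMap] = {}
    for sid in sorted(current):
        cur = current[sid].presence
        shifted = _shift_mask(cur, dr, dc)
        shifted &= study_mask
        target = int(round(shift.shrink_factor * cur.sum()))
        eroded = _erode_to(shifted, target, rng)
        out[sid] = BinaryRangeMap(
            species_id=sid, scenario=scenario, presence=eroded, grid=grid
        )
    return out


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean raster by whole cells without wrap-around."""
    out = np.zeros_like(mask)
    n_rows, n_cols = mask.shape
    r0, r1 = max(dr, 0), min(n_rows + dr, n_rows)
    c0, c1 = max(dc, 0), min(n_cols + dc, n_cols)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def _erode_to(mask: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly peel boundary cells until at most ``target`` cells remain."""
    out = mask.copy()
    n = int(out.sum())
    if n <= target:
        return out
    n_rows, n_cols = out.shape
    while n > target:
        # boundary cells: present with at least one absent 4-neighbour
        up = np.zeros_like(out)
        up[:-1, :] = out[1:, :]
        down = np.zeros_like(out)
        down[1:, :] = out[:-1, :]
        left = np.zeros_like(out)
        left[:, 1:] = out[:, :-1]
        right = np.zeros_like(out)
        right[:, :-1] = out[:, 1:]
        boundary = out & ~(up & down & left & right)
        cand = np.flatnonzero(boundary.ravel())
        if cand.size == 0:
            cand = np.flatnonzero(out.ravel())
        k = min(n - target, max(1, cand.size // 2))
        drop = rng.choice(cand, size=k, replace=False)
        out.ravel()[drop] = False
        n -= k
    return out


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Run all generation stages and bundle the result."""
    study, elevation = make_study_area(config)
    mask = study_area_mask(study, config.grid)
    species, current = make_species(config, study, elevation)
    pas = make_pa_history(config, study, elevation)
    ranges: dict[str, dict[str, BinaryRangeMap]] = {"current": current}
    for scenario in config.future_shift:
        ranges[scenario] = make_future_ranges(current, config, scenario, mask)
    return SyntheticWorld(
        config=config,
        study_area=study,
        elevation=elevation,
        study_mask=mask,
        species=species,
        ranges=ranges,
        protected_areas=pas,
    )
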