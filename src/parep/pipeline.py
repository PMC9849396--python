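"""End-to-end orchestration: world → post-processing → gap analysis →
randomization → climate scenarios → tables and plots.

Each stage reads and writes plain files (GeoJSON, ASCII grids, CSV) under
one output directory, records itself in ``manifest.json``, and is skipped
on re-runs when its outputs already exist (unless forced). CSVs are the
contract surface; plots are conveniences.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import io as pio
from . import sdm
from .grid import GridSpec
from .nullmodel import climate_randomization, decade_randomization_tests
from .representation import (
    DecadalCohort,
    ProtectedArea,
    assign_cohorts,
    build_snapshots,
    compute_target,
    descriptive_series,
    gap_analysis,
)
from .synthetic import (
    SyntheticWorldConfig,
    DecadeSpec,
    GroupConfig,
    ScenarioShift,
    ThreatConfig,
    generate_world,
    study_area_mask,
)

log = logging.getLogger(__name__)

STAGES = ("world", "postprocess", "represent", "randomize", "climate", "plots")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    mode: str = "synthetic"
    seed: int = 0
    alpha: float = 0.05
    n_replicates: int = 100
    max_attempts: int = 1000
    target_lower_km2: float = 1000.0
    target_upper_km2: float = 55000.0
    target_floor: float = 0.2
    #: per-group dispersal distances (km) used to restrict future ranges
    dispersal_km: dict[str, float] = field(
        default_factory=lambda: {
            "bird": 20.0,
            "mammal": 20.0,
            "amphibian": 5.0,
            "reptile": 5.0,
            "plant": 5.0,
        }
    )
    decades: list[tuple[str, int, int]] = field(default_factory=list)
    synthetic: SyntheticWorldConfig | None = None
    real_paths: dict[str, str] = field(default_factory=dict)
    #: also write each cohort's null placements as GeoJSON (large output)
    save_replicates: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be synthetic|real, got {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = SyntheticWorldConfig(seed=self.seed)
        if not self.decades and self.synthetic is not None:
            self.decades = [
                (d.label, d.start_year, d.end_year)
                for d in self.synthetic.pa_history
            ]
        years = [(y0, y1) for (_, y0, y1) in self.decades]
        if years != sorted(years):
            raise ConfigError("decade intervals must be ordered")
        for (l1, a0, a1), (l2, b0, b1) in zip(self.decades, self.decades[1:]):
            if b0 <= a1:
                raise ConfigError(f"decades {l1} and {l2} overlap")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = pio.read_yaml(path) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "RunConfig":
        raw = dict(raw)
        if seed is not None:
            raw["seed"] = seed
        syn = raw.pop("synthetic", None)
        cfg = cls(
            mode=raw.get("mode", "synthetic"),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            n_replicates=int(raw.get("n_replicates", 100)),
            max_attempts=int(raw.get("max_attempts", 1000)),
            target_lower_km2=float(raw.get("target_lower_km2", 1000.0)),
            target_upper_km2=float(raw.get("target_upper_km2", 55000.0)),
            target_floor=float(raw.get("target_floor", 0.2)),
            dispersal_km=raw.get("dispersal_km")
            or cls.__dataclass_fields__["dispersal_km"].default_factory(),
            decades=[tuple(d) for d in raw.get("decades", [])],
            synthetic=_synthetic_from_dict(syn, seed=int(raw.get("seed", 0))),
            real_paths=raw.get("real_paths", {}),
            save_replicates=bool(raw.get("save_replicates", False)),
        )
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_as_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_plain(cfg: RunConfig) -> dict:
    d = {
        k: getattr(cfg, k)
        for k in (
            "mode", "seed", "alpha", "n_replicates", "max_attempts",
            "target_lower_km2", "target_upper_km2", "target_floor",
            "dispersal_km", "real_paths",
        )
    }
    d["decades"] = [list(x) for x in cfg.decades]
    d["synthetic"] = cfg.synthetic.to_dict() if cfg.synthetic else None
    return d


def _synthetic_from_dict(raw: dict | None, seed: int) -> SyntheticWorldConfig | None:
    if raw is None:
        return SyntheticWorldConfig(seed=seed)
    raw = dict(raw)
    kwargs: dict = {"seed": seed}
    if "grid" in raw:
        kwargs["grid"] = GridSpec(**raw.pop("grid"))
    if "groups" in raw:
        kwargs["groups"] = {
            g: GroupConfig(**v) for g, v in raw.pop("groups").items()
        }
    if "pa_history" in raw:
        kwargs["pa_history"] = [DecadeSpec(**d) for d in raw.pop("pa_history")]
    if "future_shift" in raw:
        kwargs["future_shift"] = {
            s: ScenarioShift(**v) for s, v in raw.pop("future_shift").items()
        }
    if "threat" in raw:
        kwargs["threat"] = ThreatConfig(**raw.pop("threat"))
    raw.pop("seed", None)
    kwargs.update(raw)
    return SyntheticWorldConfig(**kwargs)


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def complete(self, stage: str, outputs: list[str], t0: float) -> None:
        self.stages[stage] = {
            "outputs": outputs,
            "elapsed_s": round(time.time() - t0, 3),
            "done": True,
        }

    def is_done(self, stage: str) -> bool:
        return self.stages.get(stage, {}).get("done", False)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "stages": self.stages},
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config_hash"], d["seed"], d["stages"])


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: RunConfig) -> dict:
    """Cross-check inputs before any compute.

    Returns ``{"fatal": [...], "warnings": [...]}``; synthetic mode with a
    valid config yields an empty report.
    """
    fatal: list[str] = []
    warnings: list[str] = []
    if config.mode == "real":
        paths = config.real_paths
        for key in ("pa_geojson", "species_csv", "ranges_dir"):
            if key not in paths:
                fatal.append(f"real mode requires path {key!r}")
            elif not Path(paths[key]).exists():
                fatal.append(f"missing input {key}: {paths[key]}")
        if not fatal:
            _, props = pio.read_geojson(paths["pa_geojson"])
            lo = min(y for (_, y, _) in config.decades) if config.decades else None
            hi = max(y for (_, _, y) in config.decades) if config.decades else None
            for p in props:
                year = p.get("year")
                if year is None:
                    fatal.append(f"PA {p.get('id')} lacks a declaration year")
                elif lo is not None and not (lo <= year <= hi):
                    fatal.append(
                        f"PA {p.get('id')} year {year} outside decade definitions"
                    )
            table = pd.read_csv(paths["species_csv"])
            ranges_dir = Path(paths["ranges_dir"])
            grids = set()
            for sid in table["species_id"]:
                f = ranges_dir / "current" / f"{sid}.asc"
                if not f.exists():
                    warnings.append(f"species {sid} in table has no current raster")
                else:
                    _, g = pio.read_ascii_grid(f)
                    grids.add((g.n_rows, g.n_cols, round(g.cell_side, 9)))
            if len(grids) > 1:
                fatal.append(f"range rasters on {len(grids)} different grids")
    else:
        try:
            _ = config.synthetic and config.synthetic.to_dict()
        except Exception as err:  # pragma: no cover - config already validated
            fatal.append(str(err))
    return {"fatal": fatal, "warnings": warnings}


# ---------------------------------------------------------------------------
# stage implementations


def _write_world(world, out: Path) -> list[str]:
    grid = world.grid
    outputs = []
    pio.write_geojson(
        out / "study_area.geojson", [world.study_area], [{"id": "study_area"}]
    )
    pio.write_ascii_grid(out / "elevation.asc", world.elevation, grid)
    pio.write_geojson(
        out / "pa_network.geojson",
        [pa.geometry for pa in world.protected_areas],
        [
            {"id": pa.pa_id, "year": pa.year, "area_km2": round(pa.area_km2, 6)}
            for pa in world.protected_areas
        ],
    )
    rows = [
        {
            "species_id": s.species_id,
            "group": s.group,
            "threatened": s.threatened,
            "range_km2": s.range_km2,
        }
        for s in world.species
    ]
    pd.DataFrame(rows).to_csv(out / "species.csv", index=False)
    occ = pd.concat(
        [
            pd.DataFrame(
                {"species_id": s.species_id, "x": s.occurrences[:, 0],
                 "y": s.occurrences[:, 1]}
            )
            for s in world.species
        ],
        ignore_index=True,
    )
    occ.to_csv(out / "occurrences.csv", index=False)
    for scenario, maps in world.ranges.items():
        d = out / "ranges" / scenario
        d.mkdir(parents=True, exist_ok=True)
        for sid, m in maps.items():
            arr = np.where(world.study_mask, m.presence.astype(float), np.nan)
            pio.write_ascii_grid(d / f"{sid}.asc", arr, grid)
    pio.write_yaml(out / "world_config.yaml", world.config.to_dict())
    outputs = [
        "study_area.geojson", "elevation.asc", "pa_network.geojson",
        "species.csv", "occurrences.csv", "ranges/", "world_config.yaml",
    ]
    return outputs


@dataclass
class _LoadedWorld:
    grid: GridSpec
    study_area: object
    study_mask: np.ndarray
    elevation: np.ndarray
    species_table: pd.DataFrame
    ranges: dict[str, dict[str, sdm.BinaryRangeMap]]
    protected_areas: list[ProtectedArea]


def load_world(out: Path, dispersal_applied: bool = False) -> _LoadedWorld:
    """Reload a world stage (or ingested real inputs) from its files."""
    elevation, grid = pio.read_ascii_grid(out / "elevation.asc")
    geoms, _ = pio.read_geojson(out / "study_area.geojson")
    study = geoms[0]
    pa_geoms, pa_props = pio.read_geojson(out / "pa_network.geojson")
    pas = [
        ProtectedArea(p["id"], g, int(p["year"]))
        for g, p in zip(pa_geoms, pa_props)
    ]
    table = pd.read_csv(out / "species.csv")
    ranges: dict[str, dict[str, sdm.BinaryRangeMap]] = {}
    base = out / ("ranges_dispersal" if dispersal_applied else "ranges")
    if not base.exists():
        base = out / "ranges"
    for sdir in sorted(base.iterdir()):
        scenario = sdir.name
        ranges[scenario] = {}
        for f in sorted(sdir.glob("*.asc")):
            arr, g = pio.read_ascii_grid(f)
            ranges[scenario][f.stem] = sdm.BinaryRangeMap(
                species_id=f.stem,
                scenario=scenario,
                presence=np.nan_to_num(arr, nan=0.0) > 0.5,
                grid=g,
            )
    return _LoadedWorld(
        grid=grid,
        study_area=study,
        study_mask=study_area_mask(study, grid),
        elevation=elevation,
        species_table=table,
        ranges=ranges,
        protected_areas=pas,
    )


def _stage_world(config: RunConfig, out: Path) -> list[str]:
    if config.mode == "synthetic":
        world = generate_world(config.synthetic)
        return _write_world(world, out)
    return _ingest_real(config, out)


def _ingest_real(config: RunConfig, out: Path) -> list[str]:
    """Normalise pre-gridded real inputs into the run-directory layout.

    Expects equal-area planar inputs: PA polygons with ``id``/``year``
    properties, per-species binary rasters under
    ``ranges_dir/<scenario>/<species_id>.asc`` on one shared grid, a
    species table, and optionally an elevation raster and a study-area
    polygon (defaults: zero elevation, the grid bounding box).
    """
    from shapely.geometry import box

    paths = config.real_paths
    table = pd.read_csv(paths["species_csv"])
    ranges_dir = Path(paths["ranges_dir"])
    grid = None
    for scenario_dir in sorted(p for p in ranges_dir.iterdir() if p.is_dir()):
        d = out / "ranges" / scenario_dir.name
        d.mkdir(parents=True, exist_ok=True)
        for f in sorted(scenario_dir.glob("*.asc")):
            arr, g = pio.read_ascii_grid(f)
            if grid is None:
                grid = g
            elif not grid.same_geometry(g):
                raise ConfigError(f"range raster {f} is on a different grid")
            pio.write_ascii_grid(d / f.name, arr, g)
    if grid is None:
        raise ConfigError(f"no range rasters found under {ranges_dir}")

    if "elevation_asc" in paths:
        elevation, g = pio.read_ascii_grid(paths["elevation_asc"])
        if not grid.same_geometry(g):
            raise ConfigError("elevation raster is on a different grid")
    else:
        elevation = np.zeros(grid.shape)
    pio.write_ascii_grid(out / "elevation.asc", elevation, grid)

    if "study_geojson" in paths:
        geoms, _ = pio.read_geojson(paths["study_geojson"])
        study = geoms[0]
    else:
        study = box(*grid.bounds)
    pio.write_geojson(out / "study_area.geojson", [study], [{"id": "study_area"}])

    pa_geoms, pa_props = pio.read_geojson(paths["pa_geojson"])
    props = []
    for i, p in enumerate(pa_props):
        props.append(
            {
                "id": p.get("id", f"pa_{i:04d}"),
                "year": int(p["year"]),
                "area_km2": round(pa_geoms[i].area, 6),
            }
        )
    pio.write_geojson(out / "pa_network.geojson", pa_geoms, props)
    table.to_csv(out / "species.csv", index=False)
    return [
        "study_area.geojson", "elevation.asc", "pa_network.geojson",
        "species.csv", "ranges/",
    ]


def _stage_postprocess(config: RunConfig, out: Path) -> list[str]:
    """Apply per-group dispersal restrictions to the future binary ranges."""
    world = load_world(out)
    group_of = dict(
        zip(world.species_table["species_id"], world.species_table["group"])
    )
    outputs = []
    for scenario, maps in world.ranges.items():
        d = out / "ranges_dispersal" / scenario
        d.mkdir(parents=True, exist_ok=True)
        for sid, m in maps.items():
            if scenario == "current":
                restricted = m
            else:
                cur = world.ranges["current"][sid]
                restricted = sdm.apply_dispersal(
                    m, cur, config.dispersal_km.get(group_of.get(sid), np.inf)
                )
            arr = np.where(
                world.study_mask, restricted.presence.astype(float), np.nan
            )
            pio.write_ascii_grid(d / f"{sid}.asc", arr, world.grid)
        outputs.append(f"ranges_dispersal/{scenario}/")
    return outputs


def _stage_represent(config: RunConfig, out: Path) -> list[str]:
    world = load_world(out, dispersal_applied=True)
    grid = world.grid
    cohorts = assign_cohorts(world.protected_areas, config.decades)
    snapshots = build_snapshots(cohorts, grid)
    targets = {
        sid: compute_target(
            m.range_km2,
            config.target_lower_km2,
            config.target_upper_km2,
            config.target_floor,
        )
        for sid, m in world.ranges["current"].items()
        if m.n_cells > 0
    }
    all_records = []
    all_summaries = []
    for scenario, maps in sorted(world.ranges.items()):
        snaps = snapshots if scenario == "current" else snapshots[-1:]
        rec, summ = gap_analysis(
            world.species_table, maps, snaps, scenario, targets
        )
        all_records.append(rec)
        all_summaries.append(summ)
    records = pd.concat(all_records, ignore_index=True)
    summaries = pd.concat(all_summaries, ignore_index=True)
    records.to_csv(
        out / "coverage_records.csv", index=False, float_format="%.6f"
    )
    summaries.to_csv(
        out / "group_summaries.csv", index=False, float_format="%.6f"
    )
    series = descriptive_series(
        cohorts, world.study_area.area, world.elevation, grid
    )
    series.to_csv(out / "descriptive_series.csv", index=False, float_format="%.6f")
    return ["coverage_records.csv", "group_summaries.csv", "descriptive_series.csv"]


def _targets_for(config: RunConfig, world) -> dict[str, float]:
    return {
        sid: compute_target(
            m.range_km2,
            config.target_lower_km2,
            config.target_upper_km2,
            config.target_floor,
        )
        for sid, m in world.ranges["current"].items()
        if m.n_cells > 0
    }


def _stage_randomize(config: RunConfig, out: Path) -> list[str]:
    world = load_world(out, dispersal_applied=True)
    cohorts = assign_cohorts(world.protected_areas, config.decades)
    results = decade_randomization_tests(
        cohorts,
        world.study_area,
        world.grid,
        world.species_table,
        world.ranges["current"],
        _targets_for(config, world),
        n_replicates=config.n_replicates,
        alpha=config.alpha,
        seed=config.seed,
        max_attempts=config.max_attempts,
        replicates_dir=(out / "null_replicates") if config.save_replicates
        else None,
    )
    results.to_csv(out / "rand_test_results.csv", index=False, float_format="%.6f")
    outputs = ["rand_test_results.csv"]
    if config.save_replicates:
        outputs.append("null_replicates/")
    return outputs


def _stage_climate(config: RunConfig, out: Path) -> list[str]:
    world = load_world(out, dispersal_applied=True)
    cohorts = assign_cohorts(world.protected_areas, config.decades)
    ordered = sorted(cohorts, key=lambda c: c.end_year)
    last = next((c for c in reversed(ordered) if c.members), None)
    future = {s: m for s, m in world.ranges.items() if s != "current"}
    if last is None or not future:
        pd.DataFrame().to_csv(out / "rand_test_results_climate.csv", index=False)
        return ["rand_test_results_climate.csv"]
    fixed = [pa for c in ordered for pa in c.members if c.end_year < last.end_year]
    results = climate_randomization(
        last,
        fixed,
        world.study_area,
        world.grid,
        world.species_table,
        future,
        _targets_for(config, world),
        n_replicates=config.n_replicates,
        alpha=config.alpha,
        seed=config.seed,
        max_attempts=config.max_attempts,
    )
    results.to_csv(
        out / "rand_test_results_climate.csv", index=False, float_format="%.6f"
    )
    return ["rand_test_results_climate.csv"]


def _stage_plots(config: RunConfig, out: Path) -> list[str]:
    from . import plots

    outputs = []
    series = pd.read_csv(out / "descriptive_series.csv")
    plots.plot_network_growth(series, out / "fig_network_growth.png")
    outputs.append("fig_network_growth.png")
    summ = pd.read_csv(out / "group_summaries.csv")
    plots.plot_representation_trajectories(
        summ, out / "fig_representation.png"
    )
    outputs.append("fig_representation.png")
    frames = []
    for f in ("rand_test_results.csv", "rand_test_results_climate.csv"):
        p = out / f
        if p.exists():
            df = pd.read_csv(p)
            if not df.empty:
                frames.append(df)
    if frames:
        plots.plot_randomization(
            pd.concat(frames, ignore_index=True), out / "fig_randomization.png"
        )
        outputs.append("fig_randomization.png")
    return outputs


_STAGE_FN = {
    "world": _stage_world,
    "postprocess": _stage_postprocess,
    "represent": _stage_represent,
    "randomize": _stage_randomize,
    "climate": _stage_climate,
    "plots": _stage_plots,
}


def run(
    config: RunConfig,
    out_dir: str | Path,
    stages: list[str] | None = None,
    force: bool = False,
) -> RunManifest:
    """Run the pipeline (or a subset of stages) into ``out_dir``.

    Completed stages recorded in the manifest are skipped unless ``force``
    or the config hash changed. Stage errors propagate after the manifest
    is saved, so a partial run can be resumed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if report["fatal"]:
        raise ConfigError("; ".join(report["fatal"]))
    for w in report["warnings"]:
        log.warning("%s", w)

    wanted = list(stages) if stages else list(STAGES)
    for s in wanted:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; stages are {STAGES}")
    manifest_path = out / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists() and not force:
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != chash:
            manifest = RunManifest(chash, config.seed)
    else:
        manifest = RunManifest(chash, config.seed)

    # stages must run in dependency order regardless of request order
    for stage in STAGES:
        if stage not in wanted:
            continue
        if manifest.is_done(stage) and not force:
            log.info("stage %s already complete; skipping", stage)
            continue
        t0 = time.time()
        log.info("stage %s: starting", stage)
        try:
            outputs = _STAGE_FN[stage](config, out)
        except Exception:
            manifest.save(manifest_path)
            raise
        manifest.complete(stage, outputs, t0)
        manifest.save(manifest_path)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    manifest.save(manifest_path)
    return manifest
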