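"""End-to-end orchestration: estimate -> simulate -> validate -> metrics.

Mirrors the study workflow: estimate an annual transition matrix from an
early pair of observed maps, run the CA-Markov simulator forward from the
later of the two, score every simulated year that has a matching observed
map (confusion matrix, accuracy, kappa), and compute baseline-referenced
zonation profiles, movements and area series for both the observed and the
simulated sequences.  A single YAML config drives the whole run; outputs
are deterministic per seed and accompanied by a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ca import SimulationConfig, run as ca_run
from .markov import TransitionMatrix, annualize, estimate_transitions
from .raster_io import LandscapeGrid, load_scheme, read_grid, write_grid
from .validation import cross_tabulate
from .zonation import ClassAbsentError, area_series, boundary_profile, movement

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    maps: list[dict]                       # [{path, date}, ...] strictly increasing dates
    scheme_path: str
    output_dir: str
    baseline_edge: str = "north"
    cell_size: float | None = None
    matrix_estimate_dates: tuple[int, int] | None = None
    matrix_file: str | None = None
    matrix_step_years: float = 1.0
    annualize_to: float | None = 1.0
    simulation_years: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    metric_classes: list[int] = field(default_factory=list)
    map_format: str = "ascii"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        dates = [m["date"] for m in self.maps]
        if dates != sorted(dates) or len(set(dates)) != len(dates):
            raise ValueError("map dates must be strictly increasing")
        if not self.metric_classes:
            raise ValueError("at least one metric class is required")
        if self.matrix_estimate_dates is None and self.matrix_file is None:
            raise ValueError("matrix source missing: give estimate dates or a file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.get("simulation", {})
        sim_cfg = SimulationConfig(
            filter_size=sim.get("filter_size", 5),
            n_iterations=sim.get("iterations", 20),
            seed=sim.get("seed", 0),
        )
        mat = raw.get("matrix", {})
        est = mat.get("estimate")
        return cls(
            maps=raw["maps"],
            scheme_path=raw["scheme"],
            output_dir=raw["output"],
            baseline_edge=raw.get("baseline_edge", "north"),
            cell_size=raw.get("cell_size"),
            matrix_estimate_dates=tuple(est) if est else None,
            matrix_file=mat.get("file"),
            matrix_step_years=mat.get("step_years", 1.0),
            annualize_to=mat.get("annualize_to", 1.0),
            simulation_years=sim.get("years", 0),
            simulation=sim_cfg,
            metric_classes=list(raw["metric_classes"]),
            map_format=raw.get("map_format", "ascii"),
            log_level=raw.get("log_level", "INFO"),
        )


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # hash the science, not the destination
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _profiles_table(grids: list[LandscapeGrid], classes: list[int]) -> pd.DataFrame:
    rows = []
    for g in grids:
        for c in classes:
            try:
                p = boundary_profile(g, c)
            except ClassAbsentError:
                continue
            rows.append({
                "date": g.date, "class_code": c,
                "class_name": g.scheme.name_of(c),
                "L_near_m": p.mean_distance_nearest,
                "L_far_m": p.mean_distance_farthest,
                "centroid_m": p.centroid_distance,
                "band_width_m": p.band_width,
                "projected_length_m": p.projected_length,
            })
    return pd.DataFrame(rows)


def _movement_table(grids: list[LandscapeGrid], classes: list[int]) -> pd.DataFrame:
    rows = []
    for a, b in zip(grids[:-1], grids[1:]):
        for c in classes:
            try:
                recs = movement(boundary_profile(a, c), boundary_profile(b, c))
            except ClassAbsentError:
                continue
            for r in recs:
                rows.append({
                    "class_code": c, "class_name": a.scheme.name_of(c),
                    "date_a": r.date_a, "date_b": r.date_b, "which": r.which,
                    "displacement_m_seaward_positive": r.displacement,
                    "rate_m_per_yr": r.rate,
                })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict it also writes."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = load_scheme(config.scheme_path)

    observed = [
        read_grid(m["path"], scheme, date=m["date"],
                  baseline_edge=config.baseline_edge, cell_size=config.cell_size)
        for m in config.maps
    ]
    by_date = {g.date: g for g in observed}

    # --- matrix -----------------------------------------------------------
    if config.matrix_estimate_dates is not None:
        d0, d1 = config.matrix_estimate_dates
        matrix = _stage("estimate")(estimate_transitions)(by_date[d0], by_date[d1])
        log.info("estimated %d-class matrix over %s years", matrix.k, matrix.step_years)
    else:
        matrix = TransitionMatrix.from_csv(config.matrix_file,
                                           step_years=config.matrix_step_years)
    if config.annualize_to and matrix.step_years != config.annualize_to:
        matrix = _stage("annualize")(annualize)(matrix, config.annualize_to)
        log.info("annualized matrix, residual %.3g", matrix.residual)
    matrix.to_csv(out / "transition_matrix.csv", names=scheme.names)

    # --- simulate ---------------------------------------------------------
    simulated: list[LandscapeGrid] = []
    if config.simulation_years > 0:
        start = (by_date[config.matrix_estimate_dates[1]]
                 if config.matrix_estimate_dates else observed[0])
        simulated = _stage("simulate")(ca_run)(
            start, matrix, config.simulation, config.simulation_years)
        ext = "tif" if config.map_format == "geotiff" else "asc"
        for g in simulated:
            write_grid(g, out / f"simulated_{g.date}.{ext}", format=config.map_format)

    # --- validate ---------------------------------------------------------
    agreements = {}
    for g in simulated:
        obs = by_date.get(g.date)
        if obs is None:
            continue
        rep = _stage("validate")(cross_tabulate)(obs, g)
        rep.write(out, stem=f"agreement_{g.date}", names=scheme.names)
        agreements[g.date] = rep.summary()

    # --- metrics ----------------------------------------------------------
    _profiles_table(observed, config.metric_classes).to_csv(
        out / "observed_profiles.csv", index=False)
    _movement_table(observed, config.metric_classes).to_csv(
        out / "observed_movement.csv", index=False)
    area_series(observed).to_csv(out / "observed_area_series.csv", index=False)
    if simulated:
        _profiles_table(simulated, config.metric_classes).to_csv(
            out / "simulated_profiles.csv", index=False)
        _movement_table(simulated, config.metric_classes).to_csv(
            out / "simulated_movement.csv", index=False)
        area_series(simulated).to_csv(out / "simulated_area_series.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed,
        "matrix_step_years": matrix.step_years,
        "matrix_residual": matrix.residual,
        "simulated_years": [g.date for g in simulated],
        "agreement": agreements,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
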