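"""End-to-end orchestration: simulate → metrics → landscape → classify → index.

``run_pipeline`` wires the stages in dependency order on a single synthetic
biome, collects thresholds, class fractions, transition-potential fractions
and safe-boundary flags into one JSON-serialisable report, and (optionally)
writes the report plus the exact configuration into the output directory so
every run is reproducible from its own provenance. Fixed seed ⇒
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import climate, potential, stability, synthetic, transition
from .grids import GridDescriptor

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("biomeshift")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration for a full synthetic-biome pipeline run."""

    seed: int = 0
    grid_shape: tuple[int, int] = (120, 200)
    biome: synthetic.SyntheticBiomeConfig | None = None
    climate: synthetic.SyntheticClimateConfig | None = None
    disturbance: synthetic.SyntheticDisturbanceConfig | None = None
    tp: transition.TransitionPotentialConfig = field(
        default_factory=transition.TransitionPotentialConfig
    )
    window_half_width: float = 50.0
    out_dir: str | None = None
    run_moisture: bool = False

    def resolved(self) -> "RunConfig":
        """Fill unset sub-configs from the run seed (deterministic)."""
        cfg = dataclasses.replace(self)
        if cfg.biome is None:
            cfg.biome = synthetic.SyntheticBiomeConfig(
                grid_shape=self.grid_shape, seed=self.seed
            )
        if cfg.climate is None:
            cfg.climate = synthetic.SyntheticClimateConfig(seed=self.seed + 1)
        if cfg.disturbance is None:
            cfg.disturbance = synthetic.SyntheticDisturbanceConfig(seed=self.seed + 2)
        return cfg

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            k: enc(v) for k, v in dataclasses.asdict(self).items()
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage '{name}' failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages on one synthetic biome and return the report dict."""
    cfg = cfg.resolved()
    report: dict = {"seed": cfg.seed}
    grid = cfg.biome.grid

    @_stage("simulate")
    def simulate():
        axis = synthetic.generate_axis_field(cfg.biome)
        tree = synthetic.generate_tree_cover(cfg.biome, axis)
        dist = synthetic.generate_disturbances(
            cfg.disturbance, grid, road_buffer_km=cfg.tp.road_buffer_km
        )
        pcube, tcube, truth = synthetic.generate_climate_cube(cfg.climate, grid)
        log.info("simulate: %d pixels, %d roads", grid.n_pixels, len(dist.roads))
        return axis, tree, dist, pcube, tcube, truth

    axis, tree, dist, pcube, tcube, truth = simulate()

    @_stage("metrics")
    def metrics():
        map_field = climate.ClimateMetricMap("map", axis, grid)
        dst = climate.dry_season_temperature(tcube)
        temp_trend = climate.fit_trend(dst, tcube.years, grid)
        mcwd_series = climate.mcwd_annual(pcube)
        log.info(
            "metrics: %.1f%% pixels with significant warming",
            100 * temp_trend.significant.mean(),
        )
        return map_field, temp_trend, mcwd_series

    map_field, temp_trend, mcwd_series = metrics()
    report["mean_warming_c_per_decade"] = float(
        np.nanmean(np.where(temp_trend.significant, temp_trend.slope, np.nan)) * 10
    )

    @_stage("landscape")
    def landscape_stage():
        window = potential.WindowSpec.for_variable("map", half_width=cfg.window_half_width)
        landscape = potential.build_stability_landscape(
            tree, axis, window, exclusion_mask=dist.deforested
        )
        thr = potential.extract_thresholds(landscape)
        return landscape, thr

    landscape, thr = landscape_stage()
    report["thresholds"] = {
        "variable": thr.variable,
        "lower_critical": thr.collapse_threshold,
        "upper_critical": thr.forest_edge,
        "bistable_range": list(thr.bistable_range) if thr.bistable_range else None,
        "fragmented": thr.fragmented,
    }

    @_stage("classify")
    def classify():
        lower = thr.collapse_threshold or 1000.0
        upper = thr.forest_edge or 1800.0
        current = stability.classify_stability(map_field, lower, upper)
        # rainfall trends from the synthetic precip cube
        annual = pcube.values.sum(axis=1)
        rain_trend = climate.fit_trend(annual, pcube.years, grid)
        projected, transitions = stability.project_stability_2050(
            map_field, rain_trend, lower, upper
        )
        return current, projected, transitions

    current, projected, transitions = classify()
    report["class_fractions_current"] = current.fractions().to_dict()
    report["class_fractions_2050"] = projected.fractions().to_dict()
    report["class_transitions"] = {
        f"{r['from']}->{r['to']}": r["fraction"]
        for r in transitions.to_dict("records")
        if r["fraction"] > 0
    }

    @_stage("transition_potential")
    def tp_stage():
        savanna_biome = current.values == stability.CLASS_SAVANNA
        stack = transition.DisturbanceStack(
            temp_trend=temp_trend,
            stability_2050=projected,
            drought_counts=dist.drought_counts,
            road_near=dist.road_near,
            protected=dist.protected,
            deforested=dist.deforested,
            savanna_biome=savanna_biome,
            grid=grid,
        )
        tp_map = transition.compute_transition_potential(stack, cfg.tp)
        return transition.categorize_tp(tp_map, cfg.tp)

    tp_map = tp_stage()
    report["tp_fractions"] = tp_map.area_fractions.to_dict()

    @_stage("safe_boundaries")
    def boundaries():
        pmap = climate.compute_map(pcube)
        mcwd = climate.compute_mcwd(pcube)
        dsl = climate.compute_dsl(pcube)
        metrics_now = {
            "annual_rainfall_mm": float(np.nanmean(pmap.values)),
            "mcwd_mm": float(np.nanmean(mcwd.values)),
            "dsl_months": float(np.nanmean(dsl.values)),
            "deforested_fraction": float(dist.deforested.mean()),
        }
        return transition.safe_boundary_report(metrics_now)

    report["safe_boundaries"] = boundaries()

    if cfg.run_moisture:

        @_stage("moisture")
        def moisture_stage():
            from . import moisture as mt

            mg = GridDescriptor(rows=40, cols=40, pixel_size=0.25)
            forcing = synthetic.generate_moisture_forcing(mg)
            result = mt.run_tracking(forcing, seed=cfg.seed)
            half = np.zeros(mg.shape, dtype=bool)
            half[:, : mg.cols // 2] = True
            flows = mt.aggregate_flows(
                result, {"west": half, "east": ~half}, forcing.precip
            )
            return {
                "conservation_error": result.audit_error(),
                "n_parcels": result.n_parcels,
                "rainfall_fractions": {
                    s: flows.target_rainfall_fraction.loc[s].to_dict()
                    for s in flows.target_rainfall_fraction.index
                },
            }

        report["moisture"] = moisture_stage()

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_config.json").write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
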