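"""End-to-end orchestration: synthetic country → matrices → optimization →
metrics → sweep, with every artifact written to disk deterministically.

This is the composition layer behind the command-line interface and the
reproduction script. All randomness flows from the named seeds in the
config; artifacts embed the config echo, never timestamps, so a fixed
config yields byte-identical files across runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demand import DemandSet, save_demand
from .hospitals import HospitalSet, save_hospitals
from .kmeans_alloc import KMeansConfig, kmeans_allocate
from .metrics import (
    DEFAULT_THRESHOLD_MIN,
    compare_distributions,
    metrics_frame,
    relative_change,
    stratified_metrics,
)
from .pmedian import AllocationSolution, evaluate_site_set, solve_scenario
from .sweep import export_sweep, run_sweep
from .synth import SyntheticCountryConfig, generate_country, write_sidecar
from .travel import (
    SyntheticTravelParams,
    TravelMatrix,
    build_matrix,
    nearest_assignment,
    weight_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, in one place."""

    country: SyntheticCountryConfig = field(default_factory=SyntheticCountryConfig)
    travel: SyntheticTravelParams = field(default_factory=SyntheticTravelParams)
    threshold_minutes: float = DEFAULT_THRESHOLD_MIN
    sweep_p: tuple[int, ...] = (20, 25, 30, 35, 40)
    kmeans_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "country": self.country.to_dict(),
            "travel": {"speed_kmh": self.travel.speed_kmh,
                       "detour_factor": self.travel.detour_factor},
            "threshold_minutes": self.threshold_minutes,
            "sweep_p": list(self.sweep_p),
            "kmeans_seed": self.kmeans_seed,
        }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis and write all artifacts under ``outdir``.

    Stages: synthesize the country; build travel and weighted matrices;
    score the current service configuration; optimize with the exact
    p-median model (liberal, p = current service count) and with the
    k-means heuristic; compute overall and stratified metrics plus the
    current-vs-optimized change report and distribution comparison; sweep
    facility quantities in both scenario modes. Returns a summary dict of
    the headline numbers (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    cfg = config.country

    regions, demand, hospitals = generate_country(cfg)
    save_demand(demand, outdir / "demand.geojson")
    save_demand(demand, outdir / "demand.csv")
    save_hospitals(hospitals, outdir / "hospitals.geojson")
    write_sidecar(outdir / "demand.geojson", cfg)
    write_sidecar(outdir / "hospitals.geojson", cfg)
    logger.info("synth: m=%d demand points, n=%d sites, %d service sites",
                demand.m, hospitals.n, len(hospitals.service_ids))

    T = build_matrix(demand, hospitals, params=config.travel)
    W = weight_matrix(T, demand)
    T.to_csv(outdir / "travel_minutes.csv")
    W.to_csv(outdir / "weighted_travel.csv")

    service = hospitals.service_ids
    p = len(service)

    # current state
    _, cur_minutes = nearest_assignment(T, service)
    current_metrics = stratified_metrics(cur_minutes, demand, config.threshold_minutes)
    current_objective = evaluate_site_set(W, service)

    # exact p-median, liberal, at the current service count
    milp_sol = solve_scenario(W, service, p, mode="liberal")
    _, milp_minutes = nearest_assignment(T, milp_sol.open_sites)
    milp_metrics = stratified_metrics(milp_minutes, demand, config.threshold_minutes)
    milp_sol.to_json(outdir / "solution_pmedian.json", minutes=milp_minutes,
                     demand_ids=demand.ids)

    # k-means heuristic at the same k
    km_sol = kmeans_allocate(
        W, T, demand, KMeansConfig(k=p, seed=config.kmeans_seed),
        hospitals=hospitals, travel_params=config.travel,
    )
    _, km_minutes = nearest_assignment(T, km_sol.open_sites)
    km_metrics = stratified_metrics(km_minutes, demand, config.threshold_minutes)
    km_sol.to_json(outdir / "solution_kmeans.json", minutes=km_minutes,
                   demand_ids=demand.ids)

    metrics_frame(current_metrics).to_csv(outdir / "metrics_current.csv", index=False)
    metrics_frame(milp_metrics).to_csv(outdir / "metrics_pmedian.csv", index=False)
    metrics_frame(km_metrics).to_csv(outdir / "metrics_kmeans.csv", index=False)
    relative_change(current_metrics["overall"], milp_metrics["overall"]).to_csv(
        outdir / "change_current_vs_pmedian.csv", index=False
    )
    comparison = compare_distributions(cur_minutes, milp_minutes)

    # quantity sweeps, both scenario modes
    for mode in ("liberal", "prioritized"):
        sw = run_sweep(
            W, config.sweep_p, mode=mode, service_set=service,
            T_eval=T, demand_eval=demand, threshold=config.threshold_minutes,
        )
        export_sweep(sw, outdir / f"sweep_{mode}.csv")

    summary = {
        "config": config.to_dict(),
        "m": demand.m,
        "n_hospitals": hospitals.n,
        "n_service": p,
        "current": {
            "objective": current_objective,
            "weighted_mean": current_metrics["overall"].weighted_mean,
            "weighted_median": current_metrics["overall"].weighted_median,
            "unweighted_mean": current_metrics["overall"].unweighted_mean,
            "prop_above_threshold": current_metrics["overall"].prop_above_threshold,
        },
        "pmedian": {
            "objective": milp_sol.objective_z,
            "weighted_mean": milp_metrics["overall"].weighted_mean,
            "weighted_median": milp_metrics["overall"].weighted_median,
            "unweighted_mean": milp_metrics["overall"].unweighted_mean,
            "prop_above_threshold": milp_metrics["overall"].prop_above_threshold,
        },
        "kmeans": {
            "objective": km_sol.objective_z,
            "weighted_mean": km_metrics["overall"].weighted_mean,
            "weighted_median": km_metrics["overall"].weighted_median,
            "unweighted_mean": km_metrics["overall"].unweighted_mean,
            "prop_above_threshold": km_metrics["overall"].prop_above_threshold,
        },
        "mannwhitney_current_vs_pmedian_p": comparison.p_value,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary
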