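"""Facility-quantity sweeps.

How does accessibility respond to opening more or fewer sites? The sweep
re-optimizes the p-median model for a grid of p values (in liberal or
prioritized mode), evaluates each chosen site set on an evaluation grid
(which may be finer than the optimization grid), and tabulates the
objective together with the headline accessibility metrics. The liberal
objective is non-increasing in p by feasible-set nesting and is asserted;
evaluation-grid means carry no such guarantee (reallocating a site can
trade unweighted minutes against weighted ones), so they are reported
unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .demand import DemandSet
from .errors import ValidationError
from .metrics import DEFAULT_THRESHOLD_MIN, summarize
from .pmedian import AllocationSolution, solve_scenario
from .travel import TravelMatrix, WeightedMatrix, nearest_assignment

logger = logging.getLogger(__name__)

SWEEP_CSV_COLUMNS = [
    "mode",
    "p",
    "objective",
    "weighted_mean",
    "unweighted_mean",
    "prop_above_threshold",
    "population_above",
]


@dataclass
class SweepRow:
    mode: str
    p: int
    status: str
    objective: float | None
    open_count: int
    weighted_mean: float | None
    unweighted_mean: float | None
    prop_above_threshold: float | None
    population_above: float | None
    open_sites: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    rows: list[SweepRow]
    threshold_minutes: float = DEFAULT_THRESHOLD_MIN

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {c: getattr(r, "population_above" if c == "population_above" else c)
             for c in SWEEP_CSV_COLUMNS}
            for r in self.rows
            if r.status == "optimal"
        ]
        return pd.DataFrame(recs, columns=SWEEP_CSV_COLUMNS)


def run_sweep(
    W_opt: WeightedMatrix,
    p_values: Sequence[int],
    mode: str = "liberal",
    service_set: Sequence[str] = (),
    T_eval: TravelMatrix | None = None,
    demand_eval: DemandSet | None = None,
    threshold: float = DEFAULT_THRESHOLD_MIN,
    options: dict | None = None,
) -> SweepResult:
    """Optimize and evaluate for every p in ``p_values``.

    ``T_eval``/``demand_eval`` define the evaluation grid for the metrics
    (minutes to the nearest open site); they default to none, in which case
    only objectives are tabulated. Failures at individual p values are
    recorded as non-optimal rows, not raised. Rows come back sorted by p.
    """
    if len(p_values) == 0:
        raise ValidationError("p_values must be non-empty")
    n = len(W_opt.hospital_ids)
    for p in p_values:
        if not 1 <= int(p) <= n:
            raise ValidationError(f"p={p} outside [1, {n}]")
    if (T_eval is None) != (demand_eval is None):
        raise ValidationError("provide both T_eval and demand_eval, or neither")

    rows: list[SweepRow] = []
    for p in sorted(int(p) for p in p_values):
        try:
            sol = solve_scenario(W_opt, service_set, p, mode=mode, options=options)
        except Exception as exc:  # recorded, not fatal
            logger.warning("sweep p=%d failed: %s", p, exc)
            rows.append(SweepRow(mode, p, "error", None, 0, None, None, None, None))
            continue
        if sol.status != "optimal":
            rows.append(SweepRow(mode, p, sol.status, None, 0, None, None, None, None))
            continue
        wm = um = pa = pop_above = None
        if T_eval is not None and demand_eval is not None:
            _, minutes = nearest_assignment(T_eval, sol.open_sites)
            m = summarize(minutes, demand_eval, threshold)
            wm, um = m.weighted_mean, m.unweighted_mean
            pa, pop_above = m.prop_above_threshold, m.population_above_threshold
        rows.append(
            SweepRow(mode, p, "optimal", sol.objective_z, sol.p, wm, um, pa,
                     pop_above, open_sites=list(sol.open_sites))
        )

    if mode == "liberal":
        objs = [r.objective for r in rows if r.status == "optimal"]
        if any(b > a + 1e-6 * max(1.0, abs(a)) for a, b in zip(objs, objs[1:])):
            raise RuntimeError(
                "liberal p-median objective increased with p — solver defect"
            )
    return SweepResult(rows=rows, threshold_minutes=threshold)


def export_sweep(result: SweepResult, path: str | Path) -> None:
    """Tidy CSV with the fixed column schema (one row per optimal p)."""
    result.to_frame().to_csv(path, index=False)


def load_sweep(path: str | Path) -> pd.DataFrame:
    """Load an exported sweep CSV, validating the schema."""
    df = pd.read_csv(path)
    if list(df.columns) != SWEEP_CSV_COLUMNS:
        raise ValidationError(
            f"unexpected sweep columns {list(df.columns)}; "
            f"expected {SWEEP_CSV_COLUMNS}"
        )
    return df
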