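"""Exact p-median optimization of facility allocation.

The p-median problem: given demand points c with population-weighted travel
times w[c,h] to candidate facilities h, open exactly p facilities so that
the total weighted travel time to the nearest open facility,

    z = Σ_c min_{h open} w[c,h],

is minimal. As a mixed-integer program with assignment variables
x[c,h] ∈ {0,1} and open indicators y[h] ∈ {0,1}:

    min z = Σ_c Σ_h x[c,h]·w[c,h]
    s.t.  Σ_h x[c,h] = 1              ∀c      (every patient assigned)
          x[c,h] ≤ y[h]               ∀c,h    (per-pair linking)
          Σ_h y[h] = p                        (exactly p sites open)

The aggregated Big-M alternative replaces the linking block with
Σ_c x[c,h] ≤ M·y[h] ∀h (fewer constraints, weaker LP relaxation); the
tightest valid constant is M = m, the number of demand points, which is
the default.

Three policy scenarios control the candidate pool relative to the current
service set S (the sites already providing the service):

* ``liberal`` — any candidate may be opened; Σ y = p over all of them.
* ``prioritized`` with p < |S| — only current service sites are eligible;
  choose the best p among them.
* ``prioritized`` with p = |S| — the current configuration is kept as is;
  no optimization runs.
* ``prioritized`` with p > |S| — all current service sites stay open and
  p − |S| additional sites are chosen from the rest.

Solved with HiGHS branch-and-cut (``scipy.optimize.milp``). The assignment
variables are declared continuous: for any fixed integral y an optimal x
assigns each demand point wholly to its cheapest open facility, so the
relaxation is exact for the objective, and the reported assignment is in
any case re-derived from y by nearest-open-in-w (the x block can be
degenerate at solver tolerance). An exhaustive-enumeration oracle
(:func:`brute_force_pmedian`) provides an independent check at small sizes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import ValidationError
from .travel import TravelMatrix, WeightedMatrix

INTEGRALITY_TOL = 1e-6


@dataclass
class ScenarioConfig:
    """Which sites may open, how many, and how linking is formulated.

    p : number of sites to open (the target service-site count).
    mode : "liberal" or "prioritized".
    service_set : current service sites S (required for prioritized mode).
    linking : "per_pair" (x ≤ y) or "big_m" (Σ_c x ≤ M·y).
    big_m_value : constant for big_m linking; defaults to m.
    """

    p: int
    mode: str = "liberal"
    service_set: tuple[str, ...] = ()
    linking: str = "per_pair"
    big_m_value: float | None = None

    def __post_init__(self) -> None:
        self.service_set = tuple(self.service_set)
        if self.p < 1:
            raise ValidationError("p must be a positive integer")
        if self.mode not in ("liberal", "prioritized"):
            raise ValidationError(f"unknown scenario mode {self.mode!r}")
        if self.linking not in ("per_pair", "big_m"):
            raise ValidationError(f"unknown linking {self.linking!r}")
        if self.mode == "prioritized" and not self.service_set:
            raise ValidationError("prioritized mode requires a non-empty service_set")
        if self.big_m_value is not None and self.big_m_value <= 0:
            raise ValidationError("big_m_value must be positive")


@dataclass
class AllocationSolution:
    """Result of an allocation method (exact MILP, fixed set, or k-means).

    open_sites : ids of the opened facilities (original column order).
    assignment : per-demand assigned hospital id (nearest open in w).
    objective_z : Σ_c min over open sites of w[c,·].
    status : "optimal" | "infeasible".
    solver_gap : relative MILP gap reported by the solver (0 for exact).
    meta : method/scenario echo for provenance.
    """

    open_sites: list[str]
    assignment: np.ndarray | None
    objective_z: float | None
    status: str
    solver_gap: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.open_sites)

    def to_json(self, path: str | Path, minutes: np.ndarray | None = None,
                demand_ids: Sequence[str] | None = None) -> None:
        doc = {
            "schema": "careloc.solution/1",
            "status": self.status,
            "objective_z": self.objective_z,
            "open_sites": list(self.open_sites),
            "solver_gap": self.solver_gap,
            "meta": _jsonable(self.meta),
        }
        if self.assignment is not None and demand_ids is not None:
            entry = {}
            for i, pid in enumerate(demand_ids):
                rec = {"hospital_id": str(self.assignment[i])}
                if minutes is not None:
                    rec["minutes"] = float(minutes[i])
                entry[pid] = rec
            doc["assignment"] = entry
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "AllocationSolution":
        doc = json.loads(Path(path).read_text())
        assignment = None
        if "assignment" in doc:
            assignment = np.array(
                [rec["hospital_id"] for rec in doc["assignment"].values()],
                dtype=object,
            )
        return cls(
            open_sites=list(doc["open_sites"]),
            assignment=assignment,
            objective_z=doc["objective_z"],
            status=doc["status"],
            solver_gap=float(doc.get("solver_gap", 0.0)),
            meta=doc.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PMedianModel:
    """Explicit MILP description produced by :func:`build_model`.

    ``candidates`` are the columns of W that own a y variable (prioritized
    mode with p < |S| restricts them to the service set); ``pinned_open``
    are candidates whose y is fixed to 1.
    """

    W: WeightedMatrix
    scenario: ScenarioConfig
    candidates: list[int]          # column indices with a y variable
    pinned_open: list[int]         # subset of candidates fixed open
    cardinality_rhs: int

    @property
    def m(self) -> int:
        return len(self.W.demand_ids)

    @property
    def n_y_vars(self) -> int:
        return len(self.candidates)

    @property
    def n_x_vars(self) -> int:
        return self.m * len(self.candidates)

    @property
    def n_free_y(self) -> int:
        return len(self.candidates) - len(self.pinned_open)


def build_model(W: WeightedMatrix, scenario: ScenarioConfig) -> PMedianModel:
    """Translate a scenario into the explicit MILP over W's columns."""
    if not np.all(np.isfinite(W.values)):
        raise ValidationError("weighted matrix must be finite")
    n = len(W.hospital_ids)
    col = {h: j for j, h in enumerate(W.hospital_ids)}
    service_idx = []
    if scenario.service_set:
        unknown = [h for h in scenario.service_set if h not in col]
        if unknown:
            raise ValidationError(
                f"service_set contains non-candidate hospitals: {unknown}"
            )
        service_idx = sorted(col[h] for h in set(scenario.service_set))

    if scenario.mode == "liberal":
        candidates = list(range(n))
        pinned: list[int] = []
    else:
        s = len(service_idx)
        if scenario.p < s:
            candidates = service_idx       # others excluded entirely (y=0)
            pinned = []
        elif scenario.p == s:
            candidates = service_idx
            pinned = list(service_idx)     # fully pinned, nothing free
        else:
            candidates = list(range(n))
            pinned = list(service_idx)     # current sites retained
    return PMedianModel(
        W=W,
        scenario=scenario,
        candidates=candidates,
        pinned_open=pinned,
        cardinality_rhs=scenario.p,
    )


def _objective_for(W: WeightedMatrix, open_cols: Sequence[int]) -> float:
    return float(np.sum(np.min(W.values[:, list(open_cols)], axis=1)))


def _solution_from_open(
    W: WeightedMatrix, open_cols: Sequence[int], meta: dict, gap: float = 0.0
) -> AllocationSolution:
    open_cols = sorted(open_cols)
    sub = W.values[:, open_cols]
    arg = np.argmin(sub, axis=1)
    assignment = np.array(
        [W.hospital_ids[open_cols[j]] for j in arg], dtype=object
    )
    return AllocationSolution(
        open_sites=[W.hospital_ids[j] for j in open_cols],
        assignment=assignment,
        objective_z=float(np.sum(sub[np.arange(sub.shape[0]), arg])),
        status="optimal",
        solver_gap=gap,
        meta=meta,
    )


def solve(model: PMedianModel, options: dict | None = None) -> AllocationSolution:
    """Solve the MILP with HiGHS and re-derive the assignment from y.

    Returns status "infeasible" (no solution fields) when the cardinality
    cannot be met, e.g. p exceeds the candidate pool after pinning.
    """
    options = dict(options or {})
    scenario = model.scenario
    m = model.m
    cand = model.candidates
    k = len(cand)
    if scenario.p > k:
        return AllocationSolution(
            open_sites=[], assignment=None, objective_z=None,
            status="infeasible", meta={"method": "pmedian_milp",
                                       "reason": f"p={scenario.p} > {k} candidates"},
        )
    if model.n_free_y == 0:
        # fully pinned: nothing to optimize
        return _solution_from_open(
            model.W, model.pinned_open,
            meta={"method": "pmedian_milp", "note": "fully pinned, no solve"},
        )

    Wsub = model.W.values[:, cand]
    nx = m * k
    nvar = nx + k
    c = np.concatenate([Wsub.ravel(), np.zeros(k)])

    constraints = []
    rows = np.repeat(np.arange(m), k)
    A_assign = sparse.csr_matrix(
        (np.ones(nx), (rows, np.arange(nx))), shape=(m, nvar)
    )
    constraints.append(LinearConstraint(A_assign, 1.0, 1.0))

    if scenario.linking == "per_pair":
        rr = np.concatenate([np.arange(nx), np.arange(nx)])
        cc = np.concatenate([np.arange(nx), nx + np.tile(np.arange(k), m)])
        data = np.concatenate([np.ones(nx), -np.ones(nx)])
        A_link = sparse.csr_matrix((data, (rr, cc)), shape=(nx, nvar))
        constraints.append(LinearConstraint(A_link, -np.inf, 0.0))
    else:
        M = scenario.big_m_value if scenario.big_m_value is not None else float(m)
        rr = np.concatenate([np.tile(np.arange(k), m), np.arange(k)])
        cc = np.concatenate([np.arange(nx), nx + np.arange(k)])
        data = np.concatenate([np.ones(nx), -M * np.ones(k)])
        A_link = sparse.csr_matrix((data, (rr, cc)), shape=(k, nvar))
        constraints.append(LinearConstraint(A_link, -np.inf, 0.0))

    A_card = sparse.csr_matrix(
        (np.ones(k), (np.zeros(k, dtype=int), nx + np.arange(k))), shape=(1, nvar)
    )
    rhs = float(scenario.p)
    constraints.append(LinearConstraint(A_card, rhs, rhs))

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    pos_in_cand = {j: idx for idx, j in enumerate(cand)}
    for j in model.pinned_open:
        lb[nx + pos_in_cand[j]] = 1.0

    integrality = np.concatenate([np.zeros(nx), np.ones(k)])
    milp_options = {"presolve": True}
    if "time_limit" in options:
        milp_options["time_limit"] = options["time_limit"]
    if "mip_rel_gap" in options:
        milp_options["mip_rel_gap"] = options["mip_rel_gap"]
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=milp_options,
    )
    if res.status == 2 or res.x is None:  # infeasible
        return AllocationSolution(
            open_sites=[], assignment=None, objective_z=None,
            status="infeasible", meta={"method": "pmedian_milp"},
        )
    if res.status != 0:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    y = res.x[nx:]
    if np.any(np.abs(y - np.round(y)) > 1e-4):
        raise RuntimeError("solver returned non-integral open indicators")
    open_cols = [cand[idx] for idx in np.flatnonzero(np.round(y) > 0.5)]
    if len(open_cols) != scenario.p:
        raise RuntimeError(
            f"solver opened {len(open_cols)} sites, expected {scenario.p}"
        )
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    sol = _solution_from_open(
        model.W, open_cols,
        meta={
            "method": "pmedian_milp",
            "mode": scenario.mode,
            "linking": scenario.linking,
            "p": scenario.p,
            "solver": "highs",
        },
        gap=gap,
    )
    # consistency: solver objective vs nearest-open recomputation
    if abs(res.fun - sol.objective_z) > 1e-6 * max(1.0, abs(sol.objective_z)):
        raise RuntimeError(
            f"objective mismatch: solver {res.fun} vs nearest-open {sol.objective_z}"
        )
    return sol


def solve_scenario(
    W: WeightedMatrix,
    service_set: Sequence[str],
    p: int,
    mode: str = "liberal",
    options: dict | None = None,
    linking: str = "per_pair",
) -> AllocationSolution:
    """Dispatch the liberal case and the three prioritized cases.

    In prioritized mode with p equal to the current service count the
    existing configuration is returned as-is, without invoking a solver.
    """
    scenario = ScenarioConfig(
        p=p, mode=mode, service_set=tuple(service_set), linking=linking
    )
    if mode == "prioritized" and p == len(set(service_set)):
        col = {h: j for j, h in enumerate(W.hospital_ids)}
        unknown = [h for h in service_set if h not in col]
        if unknown:
            raise ValidationError(
                f"service_set contains non-candidate hospitals: {unknown}"
            )
        open_cols = sorted(col[h] for h in set(service_set))
        return _solution_from_open(
            W, open_cols, meta={"method": "fixed_current", "mode": mode, "p": p}
        )
    return solve(build_model(W, scenario), options=options)


def evaluate_site_set(W: WeightedMatrix, open_sites: Sequence[str]) -> float:
    """Objective Σ_c min over the given open sites of w — used to score a
    user-supplied (e.g. current) configuration on the shared objective."""
    col = {h: j for j, h in enumerate(W.hospital_ids)}
    unknown = [h for h in open_sites if h not in col]
    if unknown:
        raise ValidationError(f"unknown hospitals: {unknown}")
    if not open_sites:
        raise ValidationError("open site set must be non-empty")
    return _objective_for(W, [col[h] for h in set(open_sites)])


def brute_force_pmedian(
    W: WeightedMatrix,
    scenario: ScenarioConfig,
    subset_cap: int = 2_000_000,
) -> AllocationSolution:
    """Exhaustive-enumeration oracle.

    Enumerates every feasible open set in lexicographic candidate order,
    scores each as Σ_c min w, and returns the minimum; ties resolve to the
    lexicographically smallest site set. Refuses (never samples) when the
    number of subsets exceeds ``subset_cap``.
    """
    model = build_model(W, scenario)
    cand = model.candidates
    pinned = set(model.pinned_open)
    free = [j for j in cand if j not in pinned]
    n_choose = scenario.p - len(pinned)
    if n_choose < 0 or n_choose > len(free):
        return AllocationSolution(
            open_sites=[], assignment=None, objective_z=None,
            status="infeasible", meta={"method": "brute_force"},
        )
    n_subsets = math.comb(len(free), n_choose)
    if n_subsets > subset_cap:
        raise ValidationError(
            f"{n_subsets} candidate subsets exceed the cap {subset_cap}; "
            "refusing to enumerate"
        )
    best: tuple[float, tuple[int, ...]] | None = None
    base = tuple(sorted(pinned))
    for extra in itertools.combinations(free, n_choose):
        open_cols = tuple(sorted(base + extra))
        z = _objective_for(W, open_cols)
        # strict improvement only: combinations iterate in lexicographic
        # order over the sorted candidates, so the first minimum encountered
        # is the lexicographically smallest optimal site set
        if best is None or z < best[0]:
            best = (z, open_cols)
    assert best is not None
    return _solution_from_open(
        W, list(best[1]), meta={"method": "brute_force", "mode": scenario.mode,
                                "p": scenario.p}
    )
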