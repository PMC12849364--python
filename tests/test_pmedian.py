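"""Exact p-median model: structure, scenarios, solver-vs-oracle agreement."""

import numpy as np
import pytest

import careloc as cl
from careloc.errors import ValidationError
from careloc.pmedian import ScenarioConfig, brute_force_pmedian, build_model, solve

from conftest import random_instance


class TestBuildModel:
    def test_liberal_structure_counts(self, toy1):
        model = build_model(toy1["W"], ScenarioConfig(p=3))
        assert model.n_x_vars == 9
        assert model.n_y_vars == 3
        assert model.cardinality_rhs == 3

    def test_cardinality_rhs_at_national_scale(self):
        # 1023 candidates, 315 to open — the full-scale national configuration
        rng = np.random.default_rng(0)
        W = cl.WeightedMatrix(rng.uniform(1, 10, (2, 1023)), ["a", "b"],
                              [f"h{j}" for j in range(1023)])
        model = build_model(W, ScenarioConfig(p=315))
        assert model.cardinality_rhs == 315
        assert model.n_y_vars == 1023

    def test_fully_pinned_prioritized_case(self, toy1):
        model = build_model(
            toy1["W"], ScenarioConfig(p=1, mode="prioritized", service_set=("H2",))
        )
        assert model.candidates == [1]
        assert model.pinned_open == [1]
        assert model.n_free_y == 0

    def test_restricted_case_drops_outsiders(self, toy1):
        model = build_model(
            toy1["W"],
            ScenarioConfig(p=1, mode="prioritized", service_set=("H1", "H3")),
        )
        assert model.candidates == [0, 2]
        assert model.pinned_open == []

    def test_augmented_case_pins_service(self, toy1):
        model = build_model(
            toy1["W"], ScenarioConfig(p=2, mode="prioritized", service_set=("H1",))
        )
        assert model.candidates == [0, 1, 2]
        assert model.pinned_open == [0]

    def test_unknown_service_site_rejected(self, toy1):
        with pytest.raises(ValidationError, match="non-candidate"):
            build_model(
                toy1["W"],
                ScenarioConfig(p=1, mode="prioritized", service_set=("H9",)),
            )

    def test_prioritized_requires_service_set(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(p=1, mode="prioritized")


class TestSolveToy:
    @pytest.mark.parametrize(
        "p,expected_open,expected_z",
        [(1, ["H2"], 50.0), (2, ["H2", "H3"], 35.0), (3, ["H1", "H2", "H3"], 25.0)],
    )
    def test_liberal_optima(self, toy1, p, expected_open, expected_z):
        sol = solve(build_model(toy1["W"], ScenarioConfig(p=p)))
        assert sol.status == "optimal"
        assert sol.objective_z == pytest.approx(expected_z)
        assert sorted(sol.open_sites) == expected_open

    def test_prioritized_pinned_h1(self, toy1):
        sol = solve(
            build_model(
                toy1["W"],
                ScenarioConfig(p=2, mode="prioritized", service_set=("H1",)),
            )
        )
        assert sol.objective_z == pytest.approx(40.0)
        assert sorted(sol.open_sites) == ["H1", "H2"]

    def test_infeasible_when_p_exceeds_candidates(self, toy1):
        sol = solve(build_model(toy1["W"], ScenarioConfig(p=4)))
        assert sol.status == "infeasible"
        assert sol.objective_z is None
        assert sol.open_sites == []

    def test_assignment_is_nearest_open_in_w(self, toy1):
        sol = solve(build_model(toy1["W"], ScenarioConfig(p=2)))
        W = toy1["W"]
        cols = [W.hospital_ids.index(h) for h in sol.open_sites]
        expect = [W.hospital_ids[cols[j]]
                  for j in np.argmin(W.values[:, cols], axis=1)]
        assert list(sol.assignment) == expect

    def test_objective_equals_nearest_open_sum(self, toy1):
        sol = solve(build_model(toy1["W"], ScenarioConfig(p=2)))
        W = toy1["W"]
        cols = [W.hospital_ids.index(h) for h in sol.open_sites]
        assert sol.objective_z == pytest.approx(
            float(np.min(W.values[:, cols], axis=1).sum()), rel=1e-9
        )


class TestBruteForce:
    @pytest.mark.parametrize("p,z", [(1, 50.0), (3, 25.0)])
    def test_toy_objectives(self, toy1, p, z):
        sol = brute_force_pmedian(toy1["W"], ScenarioConfig(p=p))
        assert sol.objective_z == pytest.approx(z)

    def test_cap_refusal(self, toy1):
        with pytest.raises(ValidationError, match="cap"):
            brute_force_pmedian(toy1["W"], ScenarioConfig(p=2), subset_cap=1)

    def test_lexicographic_tie_rule(self):
        # two identical columns: p=1 ties; oracle must pick the first id
        W = cl.WeightedMatrix(np.array([[3.0, 3.0], [4.0, 4.0]]), ["a", "b"],
                              ["h0", "h1"])
        sol = brute_force_pmedian(W, ScenarioConfig(p=1))
        assert sol.open_sites == ["h0"]

    def test_matches_milp_on_random_instance(self):
        inst = random_instance(seed=42, m=8, n=5)
        scen = ScenarioConfig(p=2)
        assert solve(build_model(inst["W"], scen)).objective_z == pytest.approx(
            brute_force_pmedian(inst["W"], scen).objective_z
        )


def _scenarios(inst, p):
    # liberal plus prioritized; with |service| = 2 the p grid 1..3 covers
    # the restricted, pinned and augmented prioritized cases
    yield ScenarioConfig(p=p, mode="liberal")
    yield ScenarioConfig(p=p, mode="prioritized", service_set=inst["service"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("linking", ["per_pair", "big_m"])
    def test_milp_equals_enumeration(self, seed, linking):
        inst = random_instance(seed=seed, m=15, n=6)
        for p in (1, 2, 3):
            for scen in _scenarios(inst, p):
                scen = ScenarioConfig(p=scen.p, mode=scen.mode,
                                      service_set=scen.service_set, linking=linking)
                milp_sol = solve(build_model(inst["W"], scen))
                oracle = brute_force_pmedian(inst["W"], scen)
                assert milp_sol.status == oracle.status == "optimal"
                assert milp_sol.objective_z == pytest.approx(
                    oracle.objective_z, abs=1e-6
                )

    def test_linking_formulations_agree(self):
        inst = random_instance(seed=77, m=20, n=7)
        for p in (2, 4):
            z_pp = solve(build_model(inst["W"], ScenarioConfig(p=p))).objective_z
            z_bm = solve(
                build_model(inst["W"], ScenarioConfig(p=p, linking="big_m"))
            ).objective_z
            assert z_pp == pytest.approx(z_bm, rel=1e-9)


class TestScenarioDispatch:
    def test_current_count_returns_fixed_set_without_solver(self, toy1):
        sol = cl.solve_scenario(toy1["W"], ("H1", "H3"), 2, mode="prioritized")
        assert sorted(sol.open_sites) == ["H1", "H3"]
        assert sol.meta["method"] == "fixed_current"

    def test_reduction_stays_within_service_set(self, toy1):
        sol = cl.solve_scenario(toy1["W"], ("H1", "H3"), 1, mode="prioritized")
        assert set(sol.open_sites) <= {"H1", "H3"}

    def test_augmentation_retains_service_set(self, toy1):
        sol = cl.solve_scenario(toy1["W"], ("H1",), 2, mode="prioritized")
        assert "H1" in sol.open_sites
        assert sol.p == 2


class TestStructuralInvariants:
    def test_monotone_objective_in_p(self):
        inst = random_instance(seed=5, m=25, n=8)
        zs = [cl.solve_scenario(inst["W"], (), p).objective_z for p in range(1, 6)]
        assert all(b <= a + 1e-9 for a, b in zip(zs, zs[1:]))

    def test_scenario_dominance(self):
        inst = random_instance(seed=9, m=20, n=8)
        for p in (2, 3):
            z_lib = cl.solve_scenario(inst["W"], inst["service"], p).objective_z
            z_pri = cl.solve_scenario(
                inst["W"], inst["service"], p, mode="prioritized"
            ).objective_z
            assert z_lib <= z_pri + 1e-9

    def test_incumbent_dominance(self):
        inst = random_instance(seed=13, m=20, n=8)
        service = inst["service"]
        z_current = cl.evaluate_site_set(inst["W"], service)
        z_opt = cl.solve_scenario(inst["W"], service, len(service)).objective_z
        assert z_opt <= z_current + 1e-9

    def test_two_grid_protocol(self):
        # optimize on a coarse subsample, evaluate the chosen set on the
        # fine grid: evaluation must agree with direct recomputation
        inst = random_instance(seed=21, m=30, n=6)
        coarse_rows = list(range(0, 30, 3))
        W = inst["W"]
        W_coarse = cl.WeightedMatrix(
            W.values[coarse_rows], [W.demand_ids[i] for i in coarse_rows],
            list(W.hospital_ids),
        )
        sol = cl.solve_scenario(W_coarse, (), 3)
        z_fine = cl.evaluate_site_set(W, sol.open_sites)
        cols = [W.hospital_ids.index(h) for h in sol.open_sites]
        assert z_fine == pytest.approx(float(W.values[:, cols].min(axis=1).sum()))


class TestSolutionIO:
    def test_json_round_trip(self, tmp_path, toy1):
        sol = solve(build_model(toy1["W"], ScenarioConfig(p=2)))
        _, minutes = cl.nearest_assignment(toy1["T"], sol.open_sites)
        sol.to_json(tmp_path / "sol.json", minutes=minutes,
                    demand_ids=toy1["W"].demand_ids)
        loaded = cl.AllocationSolution.from_json(tmp_path / "sol.json")
        assert loaded.open_sites == sol.open_sites
        assert loaded.objective_z == pytest.approx(sol.objective_z)
        assert loaded.status == "optimal"
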