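"""Equilibria, stability classification and co-culture prediction."""

import numpy as np
import pytest

from glvcom.assembly import (assess_stability, enumerate_stable_communities,
                             interior_equilibrium, predict_coculture,
                             sensitivity_envelope)
from glvcom.config import ModelConfig
from glvcom.model import integrate, to_absolute
from glvcom.synthetic import sample_world, world_interactions

from conftest import make_iset


class TestInteriorEquilibrium:
    def test_singleton_is_monoculture_fixed_point(self):
        iset = make_iset(np.zeros((2, 2)))
        state = interior_equilibrium(["sp01"], iset)
        assert state.feasible and state.method == "linear"
        assert state.equilibrium == pytest.approx([1.0])

    def test_symmetric_pair_hand_solution(self):
        # X = 1 - 0.5 X  =>  X = 2/3 for both
        iset = make_iset([[0.0, -0.5], [-0.5, 0.0]])
        state = interior_equilibrium(["sp01", "sp02"], iset)
        assert state.equilibrium == pytest.approx([2 / 3, 2 / 3])

    def test_asymmetric_pair_back_substitution(self):
        iset = make_iset([[0.0, -0.5], [0.0, 0.0]])
        state = interior_equilibrium(["sp01", "sp02"], iset)
        assert state.equilibrium == pytest.approx([0.5, 1.0])

    def test_singular_system_flagged_infeasible(self):
        iset = make_iset([[0.0, 1.0], [1.0, 0.0]])  # (I - B) singular
        state = interior_equilibrium(["sp01", "sp02"], iset)
        assert not state.feasible and state.stable is False
        assert state.method == "linear"

    def test_cap_activating_solution_falls_back_to_simulation(self):
        # strong mutualism: linear solution 1/(1-0.6) = 2.5 >= cap
        iset = make_iset([[0.0, 0.6], [0.6, 0.0]])
        state = interior_equilibrium(["sp01", "sp02"], iset)
        assert state.method == "simulated"
        assert state.feasible
        # capped equilibrium: both species pinned at the capacity cap
        assert state.equilibrium == pytest.approx([2.0, 2.0], rel=1e-3)


class TestStability:
    def test_singleton_logistic_is_stable(self):
        iset = make_iset(np.zeros((1, 1)), species=["s"])
        state = assess_stability(interior_equilibrium(["s"], iset), iset)
        assert state.stable and state.jacobian_stable and state.perturbation_stable

    def test_weak_mutual_inhibition_pair_is_stable(self):
        iset = make_iset([[0.0, -0.5], [-0.5, 0.0]])
        state = assess_stability(
            interior_equilibrium(["sp01", "sp02"], iset), iset)
        assert state.stable

    def test_strong_mutual_inhibition_excludes_coexistence(self):
        # b = -2 both ways: bistable exclusion, no interior attractor
        iset = make_iset([[0.0, -2.0], [-2.0, 0.0]])
        state = interior_equilibrium(["sp01", "sp02"], iset)
        if state.feasible:
            state = assess_stability(state, iset)
        assert not state.stable
        # oracle: from asymmetric starts, one species always excludes the other
        for x0 in ([0.06, 0.04], [0.04, 0.06]):
            traj = integrate(x0, iset.mono_rates, iset.A, iset.B,
                             horizon_h=200.0)
            assert np.min(traj.final_state) < 1e-6
            assert np.max(traj.final_state) > 0.9


class TestEnumeration:
    def test_single_species_pool(self):
        res = enumerate_stable_communities(make_iset(np.zeros((1, 1))))
        assert len(res.states) == 1
        assert res.stable_fraction == 1.0
        assert res.max_stable_richness == 1

    def test_subset_counts_partition_by_richness(self, pool_iset, pool_stable):
        n = pool_iset.n_species
        assert len(pool_stable.states) == 2 ** n - 1
        by_rich = {}
        for s in pool_stable.states:
            by_rich[s.richness] = by_rich.get(s.richness, 0) + 1
        from math import comb
        assert by_rich == {k: comb(n, k) for k in range(1, n + 1)}

    def test_stable_fraction_invariant_to_species_order(self):
        world = sample_world(4, seed=21)
        iset = world_interactions(world)
        res = enumerate_stable_communities(iset)
        perm = [2, 0, 3, 1]
        shuffled = iset.subset([iset.species[i] for i in perm])
        res_p = enumerate_stable_communities(shuffled)
        assert res_p.stable_fraction == pytest.approx(res.stable_fraction)
        assert res_p.max_stable_richness == res.max_stable_richness

    def test_combinatorial_guard_refuses_large_pools(self):
        iset = make_iset(np.zeros((21, 21)))
        with pytest.raises(ValueError, match="override_guard"):
            enumerate_stable_communities(iset)


class TestEquilibriumOracle:
    def test_linear_equilibria_match_long_horizon_ode(self, pool_iset,
                                                      pool_stable,
                                                      model_config):
        """Linear-system fixed points coincide with the dynamics' attractors."""
        checked = 0
        for state in pool_stable.stable_states:
            if state.method != "linear":
                continue
            idx = [pool_iset.index(m) for m in state.members]
            ix = np.ix_(idx, idx)
            traj = integrate(np.full(len(idx), 0.05),
                             pool_iset.mono_rates[idx], pool_iset.A[ix],
                             pool_iset.B[ix], model_config, horizon_h=500.0)
            assert np.max(np.abs(traj.final_state - state.equilibrium)) < 1e-6
            checked += 1
        assert checked >= 5


class TestPredictCoculture:
    def test_identical_species_split_evenly(self):
        iset = make_iset([[0.0, -0.3], [-0.3, 0.0]], rates=[0.7, 0.7],
                         caps=[1.0, 1.0])
        assert predict_coculture(["sp01", "sp02"], iset) == pytest.approx(
            [0.5, 0.5], abs=1e-6)

    def test_independent_pair_fractions_follow_capacities(self):
        iset = make_iset(np.zeros((2, 2)), rates=[0.8, 0.8], caps=[1.0, 3.0])
        assert predict_coculture(["sp01", "sp02"], iset) == pytest.approx(
            [0.25, 0.75], abs=1e-3)

    def test_matches_fine_tolerance_ode_oracle(self):
        world = sample_world(3, seed=17)
        iset = world_interactions(world)
        members = list(world.species)
        fractions = predict_coculture(members, iset)
        fine = ModelConfig(rel_tol=1e-11, abs_tol=1e-13)
        x0 = (fine.inoculum_od / 3) / world.capacities
        traj = integrate(x0, world.growth_rates, world.A, world.B, fine,
                         horizon_h=24.0)
        oracle = to_absolute(traj.final_state, world.capacities).fractions
        assert fractions == pytest.approx(oracle, abs=1e-4)

    def test_agrees_with_stable_interior_equilibrium(self):
        iset = make_iset([[0.0, -0.4], [-0.2, 0.0]], rates=[0.9, 0.7],
                         caps=[1.1, 0.8])
        members = ["sp01", "sp02"]
        state = assess_stability(interior_equilibrium(members, iset), iset)
        assert state.stable
        fractions = predict_coculture(members, iset, horizon_h=300.0)
        eq_frac = to_absolute(state.equilibrium,
                              iset.mono_capacities).fractions
        assert fractions == pytest.approx(eq_frac, abs=1e-5)


class TestSensitivity:
    def test_zero_sds_give_zero_envelope(self):
        iset = make_iset([[0.0, -0.3], [-0.2, 0.0]])
        env = sensitivity_envelope(["sp01", "sp02"], iset, n_draws=5, seed=1)
        assert np.all(env.sd == 0.0)
        assert env.mean == pytest.approx(env.point)

    def test_default_draw_count_is_100(self):
        import inspect
        assert inspect.signature(sensitivity_envelope).parameters[
            "n_draws"].default == 100

    def test_envelope_mean_converges_to_point_as_sds_shrink(self):
        iset = make_iset([[0.0, -0.3], [-0.2, 0.0]])
        iset.B_sd = np.full((2, 2), 1e-6); np.fill_diagonal(iset.B_sd, 0.0)
        iset.mono_rate_sd = np.full(2, 1e-6)
        env = sensitivity_envelope(["sp01", "sp02"], iset, n_draws=20, seed=2)
        assert env.mean == pytest.approx(env.point, abs=1e-4)
        assert np.all(env.sd < 1e-4)

    def test_deterministic_per_seed(self):
        iset = make_iset([[0.0, -0.3], [-0.2, 0.0]])
        iset.B_sd = np.full((2, 2), 0.05); np.fill_diagonal(iset.B_sd, 0.0)
        a = sensitivity_envelope(["sp01", "sp02"], iset, n_draws=10, seed=7)
        b = sensitivity_envelope(["sp01", "sp02"], iset, n_draws=10, seed=7)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sd, b.sd)
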