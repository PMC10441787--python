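"""Community simulator: Monod closed forms, Euler step contracts,
non-negativity, mass conservation, symmetry and step-size consistency."""

import numpy as np
import pytest
from dataclasses import replace

from microfit import (
    CommunityState,
    KineticParams,
    ReactorConfig,
    exchange_bounds,
    initial_state,
    monod_rate,
    simulate,
    step,
)
from microfit.dynamics import step_with_record
from microfit.synth import generate_community, generate_toy_model, make_attainable_target


class TestMonodRate:
    def test_half_saturation_point(self):
        assert monod_rate(10.0, 0.1, 0.1) == pytest.approx(5.0)

    def test_no_substrate_no_rate(self):
        assert monod_rate(10.0, 0.1, 0.0) == 0.0

    def test_saturation_limit(self):
        assert monod_rate(10.0, 0.1, 1e6) == pytest.approx(10.0, rel=1e-5)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(10.0, 0.1, -1e-3)

    def test_nonpositive_ks_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(10.0, 0.0, 1.0)


class TestExchangeBounds:
    def test_empty_pool_closes_uptake(self, glucose_toy):
        params = KineticParams.uniform([glucose_toy], 10.0)
        ov = exchange_bounds(glucose_toy, params, {"glc": 0.0})
        assert ov["EX_glc"] == (0.0, 0.0)  # base ub is 0 (uptake-only)

    def test_half_saturation_bound(self, glucose_toy):
        params = KineticParams.uniform([glucose_toy], 10.0, ks=0.1)
        ov = exchange_bounds(glucose_toy, params, {"glc": 0.1})
        assert ov["EX_glc"][0] == pytest.approx(-5.0)

    def test_two_compounds_independent_bounds(self):
        m = generate_toy_model("sp", ["glc", "ac"], seed=0)
        params = KineticParams(
            vmax={("sp", "EX_glc"): 8.0, ("sp", "EX_ac"): 2.0}, ks=0.1)
        pool = {"glc": 0.4, "ac": 0.3}
        ov = exchange_bounds(m, params, pool)
        # direct Monod evaluation per compound
        assert ov["EX_glc"][0] == pytest.approx(-8.0 * 0.4 / 0.5)
        assert ov["EX_ac"][0] == pytest.approx(-2.0 * 0.3 / 0.4)

    def test_missing_compound_is_named(self, glucose_toy):
        params = KineticParams.uniform([glucose_toy], 10.0)
        with pytest.raises(KeyError, match="glc"):
            exchange_bounds(glucose_toy, params, {"other": 1.0})

    def test_secretion_only_exchange_is_never_widened(self):
        m = generate_toy_model("sp", ["glc"], seed=0, secretes="byp")
        params = KineticParams.uniform([m], 10.0)
        ov = exchange_bounds(m, params, {"glc": 1.0, "byp": 5.0})
        assert "EX_byp" not in ov  # lb = 0: not an uptake exchange


class TestStep:
    def _abiotic_state(self, compounds, C):
        return CommunityState(0.0, ("sp",), np.array([0.0]),
                              tuple(compounds), np.asarray(C, float))

    def test_no_biology_no_flow_leaves_state_unchanged(self, glucose_toy):
        state = self._abiotic_state(["glc"], [3.0])
        params = KineticParams.uniform([glucose_toy], 10.0)
        reactor = ReactorConfig(c0={"glc": 3.0})
        new = step(state, [glucose_toy], params, reactor)
        assert new.t == pytest.approx(0.1)
        assert np.array_equal(new.X, state.X)
        assert np.array_equal(new.C, state.C)

    def test_washout_step_matches_linear_chemostat_formula(self, glucose_toy):
        # dC/dt = (c_in - C) q/V; one explicit Euler step has the closed form
        # C' = C + dt (c_in - C) q/V
        state = self._abiotic_state(["glc"], [2.0])
        params = KineticParams.uniform([glucose_toy], 10.0)
        reactor = ReactorConfig(q=0.5, V=2.0, c_in={"glc": 10.0})
        new = step(state, [glucose_toy], params, reactor)
        expected = 2.0 + 0.1 * (10.0 - 2.0) * 0.5 / 2.0
        assert new.C[0] == pytest.approx(expected, abs=1e-12)

    def test_near_exhaustion_pool_stays_nonnegative(self):
        m = generate_toy_model("sp", ["glc"], seed=1)
        params = KineticParams.uniform([m], 20.0)
        reactor = ReactorConfig(c0={"glc": 0.05})
        state = CommunityState(0.0, ("sp",), np.array([5.0]), ("glc",),
                               np.array([0.05]))
        new, rec = step_with_record(state, [m], params, reactor)
        assert new.C[0] >= -reactor.accuracy
        consumed = -rec.pool_fluxes[0, 0] * state.X[0] * reactor.dt
        assert consumed <= 0.05 + 1e-9

    def test_frozen_species_biomass_is_pinned(self):
        m = generate_toy_model("sp", ["glc"], seed=1)
        params = KineticParams.uniform([m], 10.0)
        reactor = ReactorConfig(c0={"glc": 40.0}, frozen_species=("sp",))
        state = initial_state([m], reactor)
        new = step(state, [m], params, reactor)
        assert new.X[0] == state.X[0]
        assert new.C[0] < state.C[0]  # it still consumes


class TestSimulate:
    def test_growth_capped_at_xmax_and_stays(self):
        m = generate_toy_model("solo", ["glc"], seed=3)
        reactor = ReactorConfig(c0={"glc": 50000.0}, t_end=24.0,
                                steady_state_accuracy=0.0)
        traj = simulate([m], KineticParams.uniform([m], 10.0), reactor)
        X = traj.biomass()
        assert X.max() <= 50.0 + 1e-9
        assert traj.final.X[0] == pytest.approx(50.0)

    def test_identical_twins_end_at_equal_fractions(self):
        a = generate_toy_model("a", ["glc"], seed=5)
        b = generate_toy_model("b", ["glc"], seed=5)
        reactor = ReactorConfig(c0={"glc": 40.0}, steady_state_accuracy=0.0)
        params = KineticParams.uniform([a, b], 10.0)
        traj = simulate([a, b], params, reactor)
        f = traj.final.X / traj.final.X.sum()
        assert abs(f[0] - 0.5) < 1e-6

    def test_species_permutation_permutes_trajectory(self):
        com = generate_community(3, cross_feeding=False, seed=2)
        reactor = ReactorConfig(c0=dict(com.medium), steady_state_accuracy=0.0,
                                t_end=6.0)
        params = KineticParams.uniform(com.models, 10.0)
        perm = [2, 0, 1]
        t_fwd = simulate(com.models, params, reactor)
        t_perm = simulate([com.models[i] for i in perm], params, reactor)
        for s_f, s_p in zip(t_fwd.states, t_perm.states):
            for j, i in enumerate(perm):
                assert s_p.X[j] == pytest.approx(s_f.X[i], abs=1e-12)

    def test_closed_reactor_mass_balance_closes(self, community4x):
        com, reactor = community4x
        reactor = replace(reactor, steady_state_accuracy=0.0, t_end=12.0)
        profile, hidden = make_attainable_target(com.models, reactor, seed=0)
        traj = simulate(com.models, hidden, reactor)
        audit_mass_balance(traj, tol=10 * reactor.accuracy)

    def test_nonnegativity_and_caps_along_trajectory(self, community4x):
        com, reactor = community4x
        traj = simulate(com.models, KineticParams.uniform(com.models, 15.0),
                        reactor)
        assert traj.concentrations().min() >= -1e-9
        X = traj.biomass()
        assert X.min() >= 0.0 and X.max() <= 50.0 + 1e-9

    def test_halving_dt_changes_endpoint_by_less_than_5pct(self, community3):
        com, reactor = community3
        reactor = replace(reactor, steady_state_accuracy=0.0, t_end=12.0)
        profile, hidden = make_attainable_target(com.models, reactor, seed=0)
        t1 = simulate(com.models, hidden, reactor)
        t2 = simulate(com.models, hidden, replace(reactor, dt=0.05))
        rel = np.abs(t2.final.X - t1.final.X) / np.maximum(t1.final.X, 1e-6)
        assert rel.max() < 0.05
        assert np.abs(t2.final.C - t1.final.C).max() < 0.05 * 40.0

    def test_trajectory_invariants(self, community3):
        com, reactor = community3
        traj = simulate(com.models, KineticParams.uniform(com.models, 10.0),
                        reactor)
        t = traj.times()
        assert np.all(np.diff(t) > 0)
        assert traj.states[0].t == 0.0
        assert np.allclose(traj.states[0].X, 0.1)


def audit_mass_balance(traj, tol):
    """Discrete audit: per compound, the recorded flux-weighted transfers
    must reproduce the concentration change exactly (closed reactor)."""
    C0, C1 = traj.states[0].C, traj.states[-1].C
    total = np.zeros_like(C0)
    for k, rec in enumerate(traj.records):
        X = traj.states[k].X
        total += 0.1 * rec.pool_fluxes.T @ X
    assert np.max(np.abs((C1 - C0) - total)) <= tol
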