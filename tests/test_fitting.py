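"""The recurrent Vmax-fitting loop: performance functional closed forms,
update-rule algebra, convergence on attainable targets, termination."""

import numpy as np
import pytest

from microfit import (
    AbundanceProfile,
    FitConfig,
    KineticParams,
    ReactorConfig,
    community_fractions,
    fit,
    performance_j,
    simulate,
    vmax_update,
    weighted_errors,
)
from microfit.fitting import MAX_UPDATE_FACTOR
from microfit.synth import generate_community, generate_toy_model, make_attainable_target


class TestCommunityFractions:
    def test_simple_shares(self):
        assert np.allclose(community_fractions([1.0, 1.0, 2.0]),
                           [0.25, 0.25, 0.5])

    def test_single_species(self):
        assert community_fractions([5.0]) == pytest.approx([1.0])

    def test_extinct_member_keeps_zero(self):
        assert np.allclose(community_fractions([0.0, 3.0]), [0.0, 1.0])

    def test_all_zero_community_rejected(self):
        with pytest.raises(ValueError):
            community_fractions([0.0, 0.0])


class TestPerformanceJ:
    def test_identity_scores_zero(self):
        f = np.array([0.2, 0.3, 0.5])
        assert performance_j(f, f) == 0.0

    def test_hand_computed_value(self):
        assert performance_j([0.5, 0.5], [0.6, 0.4]) == pytest.approx(0.02)

    def test_random_pair_matches_direct_summation(self):
        rng = np.random.default_rng(8)
        a = rng.random(8); a /= a.sum()
        b = rng.random(8); b /= b.sum()
        expected = sum((x - y) ** 2 for x, y in zip(a, b))
        assert performance_j(a, b) == pytest.approx(expected, abs=1e-14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            performance_j([1.0], [0.5, 0.5])

    def test_unnormalized_fractions_rejected(self):
        with pytest.raises(ValueError):
            performance_j([0.5, 0.4], [0.5, 0.5])


class TestWeightedErrors:
    def test_identical_fractions_score_zero(self):
        we = weighted_errors([0.3, 0.7], [0.3, 0.7])
        assert np.allclose(we.errors, 0.0) and we.mean == 0.0

    def test_percent_point_scale(self):
        we = weighted_errors([0.5, 0.5], [0.6, 0.4])
        assert np.allclose(we.errors, [10.0, 10.0])
        assert we.mean == pytest.approx(10.0)

    def test_random_pair_matches_hand_mean(self):
        rng = np.random.default_rng(4)
        a = rng.random(8); a /= a.sum()
        b = rng.random(8); b /= b.sum()
        we = weighted_errors(a, b)
        assert we.mean == pytest.approx(np.mean(np.abs(a - b)) * 100.0)
        assert we.sd == pytest.approx(np.std(np.abs(a - b) * 100.0))


class TestVmaxUpdate:
    def _params(self):
        return KineticParams(vmax={("a", "EX_glc"): 10.0, ("b", "EX_glc"): 4.0})

    def test_matched_fractions_leave_params_unchanged(self):
        p = self._params()
        f = {"a": 0.5, "b": 0.5}
        out = vmax_update(p, f, f, FitConfig(alpha=0.125))
        assert out.vmax == p.vmax

    def test_multiplicative_closed_form(self):
        p = self._params()
        out = vmax_update(p, {"a": 0.6, "b": 0.4}, {"a": 0.3, "b": 0.7},
                          FitConfig(alpha=0.125))
        assert out.vmax[("a", "EX_glc")] == pytest.approx(10.0 * 2.0 ** 0.125)
        assert out.vmax[("b", "EX_glc")] == pytest.approx(4.0 * (4 / 7) ** 0.125)

    def test_factor_is_clipped_for_extreme_mismatch(self):
        p = self._params()
        out = vmax_update(p, {"a": 1.0, "b": 0.0}, {"a": 1e-6, "b": 1.0 - 1e-6},
                          FitConfig(alpha=0.5))
        assert out.vmax[("a", "EX_glc")] == pytest.approx(10.0 * MAX_UPDATE_FACTOR)
        assert out.vmax[("b", "EX_glc")] == pytest.approx(4.0 / MAX_UPDATE_FACTOR)

    def test_vmax_stays_positive(self):
        p = KineticParams(vmax={("a", "EX_glc"): 1e-6, ("b", "EX_glc"): 4.0})
        out = vmax_update(p, {"a": 0.0, "b": 1.0}, {"a": 0.5, "b": 0.5},
                          FitConfig(alpha=0.25))
        assert all(v > 0 for v in out.vmax.values())

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vmax_update(self._params(), {"a": 1.0}, {"b": 1.0}, FitConfig())

    def test_finite_difference_gradient_sign_matches_central_oracle(self):
        com = generate_community(3, cross_feeding=False, seed=11)
        reactor = ReactorConfig(c0=dict(com.medium), t_end=12.0,
                                steady_state_accuracy=0.0)
        profile, hidden = make_attainable_target(com.models, reactor, seed=11)
        params = KineticParams.uniform(com.models, 10.0)

        def objective(p):
            traj = simulate(com.models, p, reactor)
            return performance_j(profile.fractions,
                                 community_fractions(traj.final.X))

        cfg = FitConfig(alpha=0.125, update_mode="finite_difference",
                        fd_eps=0.05)
        f_sim0 = None
        traj = simulate(com.models, params, reactor)
        f_sim0 = community_fractions(traj.final.X)
        f_ref = profile.as_mapping()
        f_sim = dict(zip(profile.species_ids, f_sim0))
        out = vmax_update(params, f_ref, f_sim, cfg, objective_fn=objective)
        # the update moves each species along -gradient; compare against a
        # central difference at eps/10
        for sp in profile.species_ids:
            eps = cfg.fd_eps / 10.0
            up = KineticParams({k: (v * (1 + eps) if k[0] == sp else v)
                                for k, v in params.vmax.items()})
            dn = KineticParams({k: (v * (1 - eps) if k[0] == sp else v)
                                for k, v in params.vmax.items()})
            grad = (objective(up) - objective(dn)) / (2 * eps)
            moved = np.log(out.vmax[(sp, "EX_glc")] / params.vmax[(sp, "EX_glc")])
            if abs(grad) > 1e-4:  # only assert where the slope is resolvable
                assert np.sign(moved) == -np.sign(grad)

    def test_finite_difference_requires_objective(self):
        with pytest.raises(ValueError):
            vmax_update(self._params(), {"a": 0.5, "b": 0.5},
                        {"a": 0.4, "b": 0.6},
                        FitConfig(update_mode="finite_difference"))


class TestFit:
    def test_self_consistent_profile_stops_at_first_cycle(self, community3):
        com, reactor = community3
        params = KineticParams.uniform(com.models, 10.0)
        traj = simulate(com.models, params,
                        ReactorConfig(c0=dict(com.medium),
                                      steady_state_accuracy=0.0))
        profile = AbundanceProfile(
            tuple(m.species_id for m in com.models),
            community_fractions(traj.final.X))
        res = fit(com.models, profile, params, reactor, FitConfig())
        assert res.n_cycles == 1
        assert res.stop_reason == "j_stop"
        assert res.final_j < 1e-9

    def test_attainable_target_reaches_j_stop(self, community3):
        com, reactor = community3
        profile, hidden = make_attainable_target(com.models, reactor, seed=5)
        res = fit(com.models, profile, KineticParams.uniform(com.models, 10.0),
                  reactor, FitConfig(alpha=0.125, max_cycles=100))
        assert res.stop_reason == "j_stop"
        assert res.final_j <= 1e-3
        assert res.final_j < res.j_history[0]

    def test_hidden_params_reproduce_target_immediately(self, community3):
        com, reactor = community3
        profile, hidden = make_attainable_target(com.models, reactor, seed=6)
        res = fit(com.models, profile, hidden, reactor, FitConfig())
        assert res.n_cycles == 1
        assert res.final_j < 1e-9

    def test_unattainable_target_terminates_and_flags_species(self):
        grower = generate_toy_model("grower", ["glc"], seed=0)
        starved = generate_toy_model("starved", ["xyl"], seed=1)
        reactor = ReactorConfig(c0={"glc": 40.0, "xyl": 0.0}, t_end=6.0)
        profile = AbundanceProfile(("grower", "starved"), np.array([0.5, 0.5]))
        res = fit([grower, starved], profile,
                  KineticParams.uniform([grower, starved], 10.0),
                  reactor, FitConfig(alpha=0.125, max_cycles=15))
        assert res.stop_reason in ("plateau", "max_cycles")
        assert "starved" in res.extinct_species

    def test_profile_model_mismatch_rejected(self, community3):
        com, reactor = community3
        profile = AbundanceProfile(("nope", "sp2", "sp3"),
                                   np.array([0.2, 0.3, 0.5]))
        with pytest.raises(ValueError):
            fit(com.models, profile, KineticParams.uniform(com.models, 10.0),
                reactor, FitConfig())

    def test_history_lengths_are_consistent(self, community3):
        com, reactor = community3
        profile, _ = make_attainable_target(com.models, reactor, seed=7)
        res = fit(com.models, profile, KineticParams.uniform(com.models, 10.0),
                  reactor, FitConfig(alpha=0.25, max_cycles=8))
        assert len(res.j_history) == len(res.fraction_history) \
            == len(res.vmax_history) == res.n_cycles
        assert res.n_cycles <= 8
        assert all(j >= 0 for j in res.j_history)


class TestAbundanceProfile:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AbundanceProfile(("a", "b"), np.array([0.5, 0.4]))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            AbundanceProfile(("a", "b"), np.array([-0.1, 1.1]))

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError):
            AbundanceProfile(("a", "a"), np.array([0.5, 0.5]))
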