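import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import advicehgf as a
from advicehgf.inversion import (
    FreeParam,
    ModelSpec,
    _neg_log_joint,
    default_sampler,
    model_spec,
    predict_p_take,
)


class TestTransforms:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        omega=st.floats(-8.0, 2.0),
        zeta=st.floats(0.01, 50.0),
        alpha=st.floats(0.001, 0.999),
    )
    def test_round_trip_identity(self, omega, zeta, alpha):
        for name, value in [("hgf3", {"omega": omega, "zeta": zeta}),
                            ("rw", {"alpha": alpha, "beta": zeta})]:
            spec = model_spec(name)
            vec = spec.to_transformed(value)
            native = spec.to_native(vec)
            for k, v in value.items():
                assert native[k] == pytest.approx(v, rel=1e-12, abs=1e-12)

    def test_every_free_param_has_prior_and_transform(self):
        for name in a.inversion.MODEL_NAMES:
            for fp in model_spec(name).free:
                assert fp.transform in ("identity", "log", "logit")
                assert fp.prior_var > 0


class TestRescorlaWagner:
    def test_unit_alpha_tracks_input_exactly(self):
        u = np.array([1, 0, 0, 1, 1])
        V, _ = a.rescorla_wagner(u, alpha=1.0, beta=2.0)
        np.testing.assert_array_equal(V, u)

    def test_zero_alpha_is_constant_chance(self):
        V, p = a.rescorla_wagner(np.array([1, 1, 0]), alpha=0.0, beta=5.0)
        assert (V == 0.5).all() and (p == 0.5).all()

    def test_two_step_hand_iteration(self):
        # V1 = 0.5 + 0.5*(1-0.5) = 0.75; V2 = 0.75 + 0.5*(1-0.75) = 0.875
        V, _ = a.rescorla_wagner(np.ones(2, dtype=int), alpha=0.5, beta=1.0)
        assert V[1] == pytest.approx(0.875, rel=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            a.rescorla_wagner(np.ones(3), alpha=1.5, beta=1.0)


class TestFitMap:
    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            a.fit_map(np.ones(10), np.ones(11), "rw")

    def test_zero_free_parameter_model_needs_no_search(self):
        spec = ModelSpec(name="rw", free=(), fixed={"alpha": 0.3, "beta": 4.0})
        u = np.ones(20, dtype=int)
        y = np.ones(20, dtype=int)
        fit = a.fit_map(y, u, spec, n_starts=1, seed=0)
        _, p = a.rescorla_wagner(u, 0.3, 4.0)
        assert fit.log_likelihood == pytest.approx(a.log_likelihood(y, p))
        assert fit.n_function_evals == 1

    def test_rw_simulate_and_refit_recovers_alpha(self):
        true = {"alpha": 0.3, "beta": 5.0}
        seq = a.generate_task(a.default_config(seed=21, n_reps=2))
        _, p = a.rescorla_wagner(seq.inputs, **true)
        y = a.simulate_choices(p, seed=22).took_advice
        fit = a.fit_map(y, seq.inputs, "rw", n_starts=4, seed=23)
        assert abs(fit.estimates["alpha"] - true["alpha"]) < 0.1

    def test_information_criteria_identities(self):
        seq = a.generate_task(a.default_config(seed=30))
        _, p = a.rescorla_wagner(seq.inputs, 0.4, 4.0)
        y = a.simulate_choices(p, seed=31).took_advice
        fit = a.fit_map(y, seq.inputs, "rw", n_starts=2, seed=32)
        k, n, ll = 2, fit.n_trials, fit.log_likelihood
        assert fit.aic == pytest.approx(2 * k - 2 * ll)
        assert fit.bic == pytest.approx(k * np.log(n) - 2 * ll)
        assert fit.log_evidence == pytest.approx(-fit.bic / 2)

    def test_objective_matches_response_model_likelihood(self):
        """The fitting objective's likelihood term equals log_likelihood."""
        spec = model_spec("hgf3")
        seq = a.generate_task(a.default_config(seed=33))
        params = {"omega": -2.5, "zeta": 3.0}
        p = predict_p_take("hgf3", params | dict(spec.fixed), seq.inputs)
        y = a.simulate_choices(p, seed=34).took_advice
        vec = spec.to_transformed(params)
        nlj = _neg_log_joint(vec, spec, y, seq.inputs)
        ll = a.log_likelihood(y, p)
        assert nlj == pytest.approx(-(ll + spec.log_prior(vec)), abs=1e-10)

    def test_fit_result_json_round_trip(self, tmp_path):
        seq = a.generate_task(a.default_config(seed=35))
        _, p = a.rescorla_wagner(seq.inputs, 0.4, 4.0)
        y = a.simulate_choices(p, seed=36).took_advice
        fit = a.fit_map(y, seq.inputs, "rw", n_starts=1, seed=37)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        assert a.FitResult.from_json(path) == fit


def _fake_fit(model, log_ev, n=160):
    """FitResult carrying a chosen -BIC/2 log evidence."""
    bic = -2.0 * log_ev
    ll = (2 * np.log(n) - bic) / 2.0
    return a.FitResult(
        model=model, estimates={}, estimates_transformed={},
        neg_log_joint=-ll, log_likelihood=ll, n_trials=n,
        aic=4 - 2 * ll, bic=bic, converged=True,
        multistart_index=0, n_function_evals=1,
    )


class TestCompareModels:
    def test_identical_evidences_symmetric_exceedance(self):
        fits = [{m: _fake_fit(m, -100.0) for m in ("m1", "m2", "m3")}
                for _ in range(10)]
        res = a.compare_models(fits, seed=0)
        np.testing.assert_allclose(res.exceedance, 1 / 3, atol=0.02)
        assert res.exceedance.sum() == pytest.approx(1.0, abs=1e-6)

    def test_fixed_effects_bayes_factor_from_evidence_gap(self):
        fits = [{"m1": _fake_fit("m1", -90.0), "m2": _fake_fit("m2", -100.0)}]
        res = a.compare_models(fits, seed=0)
        log_bf = res.fixed_effects["m1"] - res.fixed_effects["m2"]
        assert log_bf == pytest.approx(10.0)
        assert res.fixed_effects_winner == "m1"

    def test_exceedance_invariant_to_model_ordering(self):
        rng = np.random.default_rng(3)
        ev = rng.normal(-100, 3, size=(12, 3))
        names = ("m1", "m2", "m3")
        fits = [{n: _fake_fit(n, ev[i, j]) for j, n in enumerate(names)}
                for i in range(12)]
        res1 = a.compare_models(fits, seed=11)
        # present the same fits with permuted insertion order
        fits_perm = [{n: row[n] for n in ("m3", "m1", "m2")} for row in fits]
        res2 = a.compare_models(fits_perm, seed=11)
        assert res1.models == res2.models  # canonical (sorted) order
        np.testing.assert_allclose(res1.exceedance, res2.exceedance, atol=0.01)

    def test_missing_cells_rejected(self):
        fits = [{"m1": _fake_fit("m1", -90.0), "m2": _fake_fit("m2", -95.0)},
                {"m1": _fake_fit("m1", -91.0)}]
        with pytest.raises(ValueError):
            a.compare_models(fits)

    def test_dirichlet_counts_dominated_by_better_model(self):
        fits = [{"m1": _fake_fit("m1", -90.0), "m2": _fake_fit("m2", -110.0)}
                for _ in range(8)]
        res = a.compare_models(fits, seed=0)
        assert res.expected_frequencies[list(res.models).index("m1")] > 0.8
        assert (res.dirichlet_alpha >= 1.0 - 1e-9).all()


class TestRecoveryStudies:
    def test_single_agent_correlation_undefined(self):
        rep = a.parameter_recovery("rw", n_agents=1, n_trials=160, seed=2,
                                   n_starts=2)
        assert rep["correlation"].isna().all()

    def test_small_rw_recovery_correlates(self):
        rep = a.parameter_recovery("rw", n_agents=8, n_trials=320, seed=4,
                                   n_starts=3)
        assert rep.loc["alpha", "correlation"] > 0
        assert rep.loc["alpha", "rmse"] < 0.3

    def test_sampler_respects_free_parameters(self):
        spec = model_spec("hgf3")
        draw = default_sampler(spec)(np.random.default_rng(0))
        assert set(draw) == {"omega", "zeta"}
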