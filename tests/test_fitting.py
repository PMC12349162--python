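"""Weighted residual, R-squared, single- and multi-start estimation, model ranking."""

import numpy as np
import pytest

import zskin
from zskin.circuits import make_model
from zskin.errors import ConfigurationError
from zskin.fitting import (
    FitConfig,
    compare_models,
    fit_multistart,
    fit_single_start,
    linearized_stddevs,
    r_squared,
    residual,
)


def single_point_spectrum(mag, phase_rad):
    # two points are needed for a valid spectrum/R^2; duplicate magnitude at a 2nd freq
    return zskin.ImpedanceSpectrum(
        frequencies=np.array([100.0]),
        magnitudes=np.array([mag]),
        phases=np.array([phase_rad]),
    )


class TestResidual:
    def test_zero_at_generating_truth(self, gold_profile, noiseless_gold_spectrum):
        r = residual(noiseless_gold_spectrum, gold_profile.model, gold_profile.truth)
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_hand_computed_single_point_components(self):
        # measured (|Z|, theta) = (100, -0.5 rad); model gives (110, -0.4 rad);
        # weights 0.5 each -> (0.5*10/100, 0.5*0.1/0.5) = (0.05, 0.1)
        s = single_point_spectrum(100.0, -0.5)
        m = make_model("custom", [{"series": {"kind": "resistor", "name": "Rs"}}])
        z_model = 110.0 * np.exp(-0.4j)
        # build an equivalent via direct parts: use residual parts formula through a stub model
        # simplest: compute residual of a model that reproduces (110, -0.4) is not expressible
        # with a lone resistor, so evaluate the formula directly instead:
        cfg = FitConfig()
        r_mag = cfg.w_mod * abs(abs(z_model) - 100.0) / 100.0
        r_phi = cfg.w_phi * abs(np.angle(z_model) - (-0.5)) / max(0.5, cfg.phase_floor)
        assert r_mag == pytest.approx(0.05, rel=1e-12)
        assert r_phi == pytest.approx(0.1, rel=1e-12)
        # and the package residual agrees for a model it CAN express (resistor = 110 at phase 0):
        s0 = single_point_spectrum(100.0, -0.5)
        r = residual(s0, m, {"Rs": 110.0}, cfg)
        assert r[0] == pytest.approx(0.05, rel=1e-12)
        assert r[1] == pytest.approx(cfg.w_phi * 0.5 / 0.5, rel=1e-12)

    def test_linear_in_weights(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=1)
        p = gold_profile.truth
        r1 = residual(s, gold_profile.model, p, FitConfig(w_mod=0.5, w_phi=0.5))
        r2 = residual(s, gold_profile.model, p, FitConfig(w_mod=1.0, w_phi=1.0))
        assert np.allclose(r2, 2.0 * r1, rtol=1e-12)

    def test_phase_floor_guards_zero_phase(self):
        s = single_point_spectrum(100.0, 0.0)
        m = make_model("custom", [{"series": {"kind": "resistor", "name": "Rs"}}])
        r = residual(s, m, {"Rs": 100.0}, FitConfig(phase_floor=1e-3))
        assert np.all(np.isfinite(r))

    def test_elementwise_non_negative(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=2)
        r = residual(s, gold_profile.model, gold_profile.truth)
        assert np.all(r >= 0)
        assert r.size == 2 * len(s)


class TestRSquared:
    def test_perfect_and_mean_predictors(self):
        obs = [1.0, 2.0, 5.0]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, [np.mean(obs)] * 3) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self):
        # SS_res = (3-4)^2 = 1, SS_tot = (1-2)^2 + (3-2)^2 = 2 -> R^2 = 0.5
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_invariant_to_pair_reordering_and_degraded_by_noise(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(1, 10, 30)
        fit = obs + rng.normal(0, 0.1, 30)
        base = r_squared(obs, fit)
        perm = rng.permutation(30)
        assert r_squared(obs[perm], fit[perm]) == pytest.approx(base, rel=1e-12)
        noisier = fit + rng.normal(0, 0.5, 30)
        assert r_squared(obs, noisier) < base

    def test_constant_observed_is_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestSingleStart:
    def test_truth_is_a_fixed_point(self, gold_profile, noiseless_gold_spectrum):
        res = fit_single_start(
            noiseless_gold_spectrum, gold_profile.model, gold_profile.truth
        )
        assert res.residual_norm < 1e-10
        assert res.r2_mag == pytest.approx(1.0, abs=1e-12)
        assert res.r2_phase == pytest.approx(1.0, abs=1e-12)

    def test_recovers_from_threefold_perturbation_on_model0(self):
        m = make_model("model0")
        truth = {"Rs": 800.0, "R0": 3e4, "C0": 8e-8}
        z = np.atleast_1d(zskin.circuit_impedance(m, truth, zskin.default_frequency_grid()))
        s = zskin.ImpedanceSpectrum(zskin.default_frequency_grid(), np.abs(z), np.angle(z))
        p0 = {k: v * 3.0 for k, v in truth.items()}
        res = fit_single_start(s, m, p0)
        for k, v in truth.items():
            assert abs(res.parameters.values[k] / v - 1.0) < 1e-3

    def test_start_on_boundary_stays_within_bounds(self, noiseless_gold_spectrum, gold_profile):
        m = gold_profile.model
        cfg = FitConfig()
        bounds = cfg.resolve_bounds(m)
        p0 = {k: bounds[k][0] for k in m.parameter_names}
        res = fit_single_start(noiseless_gold_spectrum, m, p0, cfg)
        for k, (lo, hi) in bounds.items():
            assert lo <= res.parameters.values[k] <= hi


class TestMultiStart:
    def test_default_trial_count_is_300(self):
        assert FitConfig().n_starts == 300

    def test_same_seed_gives_identical_result(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=4)
        m = make_model("model0")
        cfg = FitConfig(n_starts=8, rng_seed=11)
        r1 = fit_multistart(s, m, cfg)
        r2 = fit_multistart(s, m, cfg)
        assert r1.parameters.values == r2.parameters.values
        assert r1.residual_norm == r2.residual_norm
        assert r1.best_start_index == r2.best_start_index

    def test_best_norm_non_increasing_in_n_starts(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=5)
        m = make_model("model1")
        norms = [
            fit_multistart(s, m, FitConfig(n_starts=k, rng_seed=3)).residual_norm
            for k in (2, 6, 12)
        ]
        assert norms[0] >= norms[1] >= norms[2]

    def test_result_within_bounds_and_reports_convergence(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=6)
        m = make_model("model0")
        res = fit_multistart(s, m, FitConfig(n_starts=10, rng_seed=0))
        bounds = res.parameters.bounds
        for k, v in res.parameters.values.items():
            assert bounds[k][0] <= v <= bounds[k][1]
        assert 1 <= res.n_converged <= 10
        assert res.trial_norms.size == 10


class TestLinearizedStddevs:
    def test_parsimonious_model_is_far_better_determined(self, gold_profile, noiseless_gold_spectrum):
        sig3 = linearized_stddevs(noiseless_gold_spectrum, gold_profile.model, gold_profile.truth)
        assert set(sig3) == set(gold_profile.model.parameter_names)
        assert all(np.isfinite(v) and v > 0 for v in sig3.values())
        # interface pair is the best-determined part of the full model
        assert sig3["R0"] < 0.2 and sig3["C0"] < 0.2
        m0 = zskin.make_model("model0")
        fit0 = fit_multistart(noiseless_gold_spectrum, m0, FitConfig(n_starts=20, rng_seed=0))
        sig0 = linearized_stddevs(noiseless_gold_spectrum, m0, fit0.parameters)
        assert sig0["R0"] < sig3["R0"]


class TestCompareModels:
    def test_nested_models_tie_break_on_parsimony(self):
        m0 = make_model("model0")
        truth = {"Rs": 900.0, "R0": 2.5e4, "C0": 9e-8}
        grid = zskin.default_frequency_grid()
        z = np.atleast_1d(zskin.circuit_impedance(m0, truth, grid))
        s = zskin.ImpedanceSpectrum(grid, np.abs(z), np.angle(z))
        table = compare_models(s, [make_model("model3"), m0], FitConfig(n_starts=30, rng_seed=2))
        names = list(table["model"])
        assert names.index("model0") < names.index("model3")
        assert table.iloc[0]["r2_mag"] > 0.999

    def test_cpe_data_favors_cpe_model_on_phase(self, gold_profile):
        s = zskin.generate_spectrum(gold_profile, 0.0, rng=7)
        table = compare_models(
            s, [make_model("model0"), make_model("model3")], FitConfig(n_starts=40, rng_seed=1)
        )
        row = table.set_index("model")
        assert row.loc["model3", "r2_phase"] > row.loc["model0", "r2_phase"]
        assert list(table["model"])[0] == "model3"

    def test_single_model_is_an_error(self, noiseless_gold_spectrum):
        with pytest.raises(ConfigurationError, match="at least 2"):
            compare_models(noiseless_gold_spectrum, [make_model("model0")])
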