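"""Circuit-element algebra: element formulas, chain evaluation, topologies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zskin
from zskin.circuits import (
    Element,
    ParallelSegment,
    circuit_impedance_jacobian,
    default_bounds,
    make_model,
)
from zskin.errors import ConfigurationError

from conftest import oracle_impedance, random_circuit

FREQS = zskin.default_frequency_grid()


class TestElementImpedance:
    def test_resistor_is_frequency_independent(self):
        e = Element.resistor(100.0)
        for f in (1.0, 20.0, 1e6):
            assert zskin.element_impedance(e, f) == pytest.approx(100.0 + 0j)

    def test_cpe_alpha_zero_reduces_to_resistor(self):
        e = Element.cpe(Q=1e-3, alpha=0.0)
        assert zskin.element_impedance(e, 123.4) == pytest.approx(1000.0 + 0j)

    def test_cpe_alpha_one_equals_capacitor_via_oracle(self):
        # 2*pi*f = 1000 rad/s, C = 1 uF
        f = 1000.0 / (2 * np.pi)
        z_cpe = zskin.element_impedance(Element.cpe(Q=1e-6, alpha=1.0), f)
        z_cap_oracle = 1.0 / (1j * 1000.0 * 1e-6)  # independent direct arithmetic
        assert z_cpe == pytest.approx(z_cap_oracle, rel=1e-12)

    def test_cpe_phase_is_minus_alpha_90_degrees_at_any_frequency(self):
        for alpha in (0.25, 0.5, 0.8):
            e = Element.cpe(Q=3e-7, alpha=alpha)
            for f in (20.0, 1000.0, 5e4):
                assert np.angle(zskin.element_impedance(e, f)) == pytest.approx(
                    -alpha * np.pi / 2, abs=1e-12
                )

    def test_cpe_is_continuous_in_alpha_and_matches_endpoints(self):
        f = 100.0
        q = 2e-6
        alphas = np.linspace(0.0, 1.0, 201)
        z = np.array([zskin.element_impedance(Element.cpe(q, a), f) for a in alphas])
        # endpoints equal resistor 1/Q and capacitor C=Q
        assert z[0] == pytest.approx(zskin.element_impedance(Element.resistor(1 / q), f), rel=1e-12)
        assert z[-1] == pytest.approx(zskin.element_impedance(Element.capacitor(q), f), rel=1e-12)
        steps = np.abs(np.diff(z)) / np.abs(z[:-1])
        assert np.all(steps < 0.1)  # no jumps on a fine alpha grid

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        alpha=st.floats(0.0, 1.0),
        log_q=st.floats(-10, -3),
        log_f=st.floats(np.log10(20.0), 3.0),
    )
    def test_cpe_constant_phase_property(self, alpha, log_q, log_f):
        z = zskin.element_impedance(Element.cpe(10.0**log_q, alpha), 10.0**log_f)
        expected_mag = 1.0 / (10.0**log_q * (2 * np.pi * 10.0**log_f) ** alpha)
        assert np.angle(z) == pytest.approx(-alpha * np.pi / 2, abs=1e-12)
        assert abs(z) == pytest.approx(expected_mag, rel=1e-12)

    def test_inadmissible_parameters_name_the_field(self):
        with pytest.raises(ConfigurationError, match="'R'"):
            Element.resistor(-5.0)
        with pytest.raises(ConfigurationError, match="'alpha'"):
            Element.cpe(1e-6, 1.5)
        with pytest.raises(ValueError, match="frequency"):
            zskin.element_impedance(Element.resistor(10.0), 0.0)


class TestCircuitImpedance:
    def test_degenerate_chain_single_resistor(self):
        m = make_model("custom", [{"series": {"kind": "resistor", "name": "Rs"}}])
        z = zskin.circuit_impedance(m, {"Rs": 50.0}, FREQS)
        assert np.allclose(z, 50.0 + 0j)

    def test_model0_against_closed_form_oracle(self):
        # Rs + R0/(1 + j*2*pi*f*R0*C0) evaluated independently
        m = make_model("model0")
        vals = {"Rs": 100.0, "R0": 1e4, "C0": 1e-6}
        f = 20.0
        expected = 100.0 + 1e4 / (1.0 + 1j * 2 * np.pi * f * 1e4 * 1e-6)
        assert zskin.circuit_impedance(m, vals, f) == pytest.approx(expected, rel=1e-14)

    def test_high_frequency_limit_is_series_resistance(self):
        m = make_model("model0")
        vals = {"Rs": 100.0, "R0": 1e4, "C0": 1e-6}
        assert abs(zskin.circuit_impedance(m, vals, 1e9) - 100.0) < 1.0

    def test_missing_parameter_error_lists_names(self):
        m = make_model("model0")
        with pytest.raises(ConfigurationError, match="C0"):
            zskin.circuit_impedance(m, {"Rs": 10.0, "R0": 1e3}, 100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle_on_random_circuits(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            config, values = random_circuit(rng)
            m = make_model("custom", config)
            z = np.atleast_1d(zskin.circuit_impedance(m, values, FREQS))
            z_ref = np.array([oracle_impedance(config, values, f) for f in FREQS])
            assert np.max(np.abs(z - z_ref) / np.abs(z_ref)) < 1e-12


class TestBuiltinModelProperties:
    @pytest.mark.parametrize("name", zskin.BUILTIN_MODELS)
    def test_passivity_and_monotone_magnitude(self, name):
        m = make_model(name)
        bounds = default_bounds(m.parameter_names)
        rng = np.random.default_rng(hash(name) % 2**31)
        for _ in range(25):
            vals = {
                n: rng.uniform(lo, hi) if n.startswith("alpha")
                else 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
                for n, (lo, hi) in bounds.items()
            }
            z = np.atleast_1d(zskin.circuit_impedance(m, vals, FREQS))
            assert np.all(np.isfinite(z))
            assert np.all(z.real > 0)
            assert np.all(z.imag <= 1e-12 * np.abs(z))
            assert np.all(np.angle(z) >= -np.pi / 2 - 1e-12)
            assert np.all(np.diff(np.abs(z)) <= 1e-9 * np.abs(z[:-1]))

    @pytest.mark.parametrize("name", zskin.BUILTIN_MODELS)
    def test_frequency_limits_bracket_the_resistances(self, name):
        m = make_model(name)
        rng = np.random.default_rng(1)
        vals = {
            n: rng.uniform(0.7, 0.9) if n.startswith("alpha")
            else 10.0 ** rng.uniform(2, 4) if n.startswith("R")
            else 10.0 ** rng.uniform(-8, -6)
            for n in m.parameter_names
        }
        r_sum = sum(v for n, v in vals.items() if n.startswith("R") and n != "Rs")
        z_low = zskin.circuit_impedance(m, vals, 1e-7)
        assert abs(z_low - (vals["Rs"] + r_sum)) / (vals["Rs"] + r_sum) < 1e-3
        z_high = zskin.circuit_impedance(m, vals, 1e12)
        assert abs(z_high - vals["Rs"]) / vals["Rs"] < 1e-3

    def test_model0_is_single_time_constant_with_three_parameters(self):
        m = make_model("model0")
        assert m.parameter_names == ("Rs", "R0", "C0")

    def test_model3_first_segment_is_rc_and_has_nine_parameters(self):
        m = make_model("model3")
        assert m.parameter_names[:3] == ("Rs", "R0", "C0")
        assert m.n_parameters == 9
        seg0 = m.chain[1]
        assert isinstance(seg0, ParallelSegment)
        assert {e.kind for e in seg0.elements} == {"resistor", "capacitor"}


class TestTopologyConfig:
    def test_yaml_round_trip_preserves_parameters_and_impedance(self):
        m = make_model("model3")
        m2 = make_model("custom", m.to_yaml())
        assert m2.parameter_names == m.parameter_names
        vals = zskin.default_profiles()["gold"].truth.values
        z1 = zskin.circuit_impedance(m, vals, FREQS)
        z2 = zskin.circuit_impedance(m2, vals, FREQS)
        assert np.allclose(z1, z2, rtol=0, atol=0)

    def test_unknown_model_and_bad_config_raise(self):
        with pytest.raises(ConfigurationError, match="unknown model"):
            make_model("model7")
        with pytest.raises(ConfigurationError):
            make_model("custom", [{"nonsense": 1}])
        with pytest.raises(ConfigurationError):
            make_model("custom")


class TestJacobian:
    @pytest.mark.parametrize("name", ["model0", "model3"])
    def test_analytic_gradient_matches_finite_differences(self, name, profiles):
        m = make_model(name)
        vals = {
            n: v
            for n, v in profiles["gold"].truth.values.items()
            if n in m.parameter_names
        }
        z, dz = circuit_impedance_jacobian(m, vals, FREQS)
        for j, n in enumerate(m.parameter_names):
            h = (vals[n] if not n.startswith("alpha") else 1.0) * 1e-7
            up = dict(vals)
            up[n] += h
            fd = (np.atleast_1d(zskin.circuit_impedance(m, up, FREQS)) - z) / h
            denom = np.abs(dz[:, j]) + 1e-3 * np.max(np.abs(dz[:, j]))
            assert np.max(np.abs(fd - dz[:, j]) / denom) < 1e-4
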