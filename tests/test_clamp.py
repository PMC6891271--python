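"""Voltage-clamp simulation, normalization, similarity and fitting."""

import numpy as np
import pytest

from uterosim.channels import ChannelSpec, GateSpec, TauSpec
from uterosim.clamp import (ClampProtocol, fit_channel, normalize_trace,
                            simulate_clamp, trace_similarity)
from uterosim.errors import FitError, InputError
from uterosim.synthetic import SyntheticSpec, generate_clamp_fixture


class TestSimulateClamp:
    def test_step_at_reversal_gives_flat_zero(self, sodium_channel):
        proto = ClampProtocol(holding_mV=-80, steps_mV=[sodium_channel.e_rev],
                              duration_ms=50.0)
        exp = simulate_clamp(sodium_channel, proto)
        assert np.allclose(exp.traces, 0.0)

    def test_single_activation_gate_closed_form(self):
        tau, n_exp, v_step, e_rev = 5.0, 3, 0.0, -80.0
        ch = ChannelSpec(name="t", gbar=1.0, e_rev=e_rev, gates=[
            GateSpec(name="a", kind="activation", v_half=-120.0, slope=4.0,
                     exponent=n_exp, tau=TauSpec(ms=tau))])
        proto = ClampProtocol(holding_mV=-200.0, steps_mV=[v_step],
                              onset_ms=10.0, duration_ms=60.0, dt_ms=0.05)
        exp = simulate_clamp(ch, proto)
        t = exp.time_ms
        post = t >= 10.0
        x_inf = 1.0 / (1.0 + np.exp(-(v_step + 120.0) / 4.0))
        x0 = 1.0 / (1.0 + np.exp(-(-200.0 + 120.0) / 4.0))
        x = x_inf + (x0 - x_inf) * np.exp(-(t[post] - 10.0) / tau)
        expected = x ** n_exp * (v_step - e_rev)
        assert np.allclose(exp.traces[0][post], expected, rtol=1e-10)

    def test_sodium_morphology_fast_peak_then_decay(self, sodium_channel, na_protocol):
        exp = simulate_clamp(sodium_channel, na_protocol)
        onset = int(round(11.0 / 0.1))
        for v_step, trace in zip(na_protocol.steps_mV, exp.traces):
            post = trace[onset:]
            i_peak = np.argmax(np.abs(post))
            assert post[i_peak] < 0  # inward sodium current
            assert i_peak < 0.25 * len(post)  # peak well before 25% of sweep
            assert abs(post[-1]) < 0.85 * abs(post[i_peak])  # decays
        # at the most depolarized step inactivation is near-complete
        strongest = exp.traces[-1][onset:]
        assert abs(strongest[-1]) < 0.1 * np.max(np.abs(strongest))


class TestNormalizeTrace:
    def test_divides_by_peak_magnitude(self):
        out = normalize_trace([0.0, -2.0, -4.0, -1.0])
        assert np.allclose(out, [0.0, -0.5, -1.0, -0.25])

    def test_idempotent(self):
        tr = np.array([0.1, -0.4, 1.0, 0.3])
        assert np.allclose(normalize_trace(normalize_trace(tr)), normalize_trace(tr))

    def test_invariant_to_conductance_scaling(self, sodium_channel, na_protocol):
        exp1 = simulate_clamp(sodium_channel, na_protocol)
        scaled = sodium_channel.model_copy(update={"gbar": 7.3 * sodium_channel.gbar})
        exp2 = simulate_clamp(scaled, na_protocol)
        onset = int(round(11.0 / 0.1))
        assert np.allclose(normalize_trace(exp1.traces[0], onset),
                           normalize_trace(exp2.traces[0], onset))

    def test_zero_trace_rejected(self):
        with pytest.raises(InputError):
            normalize_trace(np.zeros(10))


class TestTraceSimilarity:
    def test_identical(self, rng):
        a = rng.normal(size=200)
        corr, mse = trace_similarity(a, a)
        assert corr == pytest.approx(1.0)
        assert mse == pytest.approx(0.0)

    def test_sign_flip(self, rng):
        a = rng.normal(size=200)
        corr, mse = trace_similarity(a, -a)
        assert corr == pytest.approx(-1.0)
        assert mse == pytest.approx(np.mean(4 * a ** 2))

    def test_small_noise_keeps_high_correlation(self, rng):
        a = np.sin(np.linspace(0, 6 * np.pi, 1000))
        b = a + rng.normal(0.0, 0.01, size=a.size)
        corr, _ = trace_similarity(a, b)
        assert corr > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            trace_similarity(np.ones(10), np.arange(10.0))


class TestFitChannel:
    def test_noiseless_round_trip_recovers_parameters(self, sodium_channel, na_protocol):
        exp = simulate_clamp(sodium_channel, na_protocol)
        template = sodium_channel.model_copy(update={"gates": [
            g.model_copy(update={"v_half": g.v_half + 6.0,
                                 "slope": g.slope * 1.3,
                                 "tau": TauSpec(ms=g.tau.ms * 1.6)})
            for g in sodium_channel.gates]})
        fit = fit_channel(exp, template, seed=7)
        for got, truth in zip(fit.channel.gates, sodium_channel.gates):
            assert got.v_half == pytest.approx(truth.v_half, abs=0.5)
            assert got.slope == pytest.approx(truth.slope, rel=0.05)
        assert all(c > 0.999 for c in fit.correlations)

    def test_noisy_fixture_fits_with_high_correlation(self, sodium_channel):
        """A transient-focused sweep concentrates signal variance, so the fit
        traces noisy data at the correlation level seen for clamp fits."""
        proto = ClampProtocol(holding_mV=-80.0, steps_mV=[-40.0, -20.0, 0.0],
                              onset_ms=11.0, duration_ms=20.0, dt_ms=0.05)
        spec = SyntheticSpec(channel=sodium_channel, protocol=proto,
                             noise_sd=0.05, seed=42)
        exp = generate_clamp_fixture(spec)
        fit = fit_channel(exp, sodium_channel, seed=3)
        assert all(c > 0.99 for c in fit.correlations)
        assert all(m < 0.02 for m in fit.mse)

    def test_swapped_gate_roles_fit_poorly(self, sodium_channel, na_protocol):
        """Negative control: data from an activation/inactivation-swapped
        channel cannot be traced by the physiological template."""
        swapped = sodium_channel.model_copy(update={"gates": [
            GateSpec(name="m", kind="inactivation", v_half=-20.3, slope=6.2,
                     exponent=3, tau=TauSpec(ms=0.45)),
            GateSpec(name="h", kind="activation", v_half=-46.2, slope=7.2,
                     exponent=1, tau=TauSpec(ms=30.0))]})
        exp = simulate_clamp(swapped, na_protocol)
        fit = fit_channel(exp, sodium_channel, seed=5, n_starts=2)
        assert min(fit.correlations) < 0.9

    def test_single_step_rejected(self, sodium_channel):
        proto = ClampProtocol(steps_mV=[-20.0])
        exp = simulate_clamp(sodium_channel, proto)
        with pytest.raises(FitError):
            fit_channel(exp, sodium_channel)


def test_potassium_steady_state_curves_cross(potassium_channel):
    """Activation and inactivation sigmoids cross between their half-potentials."""
    from uterosim.channels import boltzmann_steady_state
    n, q = potassium_channel.gates
    v = np.linspace(-80, 40, 500)
    act = boltzmann_steady_state(n, v)
    inact = boltzmann_steady_state(q, v)
    idx = np.argmin(np.abs(act - inact))
    assert q.v_half < v[idx] < n.v_half
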