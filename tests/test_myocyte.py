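"""Cell-model assembly, integration, and AP feature extraction."""

import numpy as np
import pytest

from uterosim.defaults import (build_config, default_full_config,
                               default_simplified_config, preset)
from uterosim.errors import InputError
from uterosim.myocyte import (CellConfig, SimplifiedModelSpec,
                              SimulationResult, StimulusProtocol,
                              calcium_balance, extract_ap_features,
                              full_model_rhs, get_model, simulate)
from uterosim.reduction import find_steady_state


def passive_config(gbar=0.0):
    return build_config({
        "name": "passive", "variant": "full",
        "calcium": {"alpha": 0.0, "tau_ms": 1000.0, "rest_uM": 0.1},
        "channels": [
            {"name": "leak", "gbar": gbar, "e_rev": -50.0, "gates": []},
        ],
        "ca_sources": [],
    })


class TestRHS:
    def test_zero_conductances_give_zero_dvdt(self):
        cfg = passive_config(0.0)
        y = get_model(cfg).initial_state(v=-37.0)
        dy = full_model_rhs(y, 0.0, cfg)
        assert dy[0] == 0.0

    def test_steady_state_is_rhs_root(self):
        cfg = default_full_config()
        ss = find_steady_state(cfg)
        dy = full_model_rhs(ss.to_vector(cfg), 0.0, cfg)
        assert np.max(np.abs(dy)) < 1e-10

    def test_calcium_balance_fixed_points(self):
        cfg = default_full_config()
        assert calcium_balance(cfg.calcium.rest_uM, 0.0, 0.0, cfg) == 0.0
        # constant inward current -> analytic fixed point
        i = -2.0
        ca_fix = cfg.calcium.rest_uM + cfg.calcium.alpha * cfg.calcium.tau_ms * 2.0
        assert calcium_balance(ca_fix, i, 0.0, cfg) == pytest.approx(0.0, abs=1e-15)

    def test_removing_sodium_slows_upstroke(self):
        cfg, proto, dur = preset("spike", "full")
        cfg_no_na = cfg.model_copy(update={"channels": [
            (c.model_copy(update={"gbar": 0.0}) if c.name == "na" else c)
            for c in cfg.channels]})
        slopes = []
        for c in (cfg, cfg_no_na):
            r = simulate(c, proto, 2000.0, equil_ms=4000.0, dt_out=0.5)
            m = (r.time_ms >= proto.onset_ms) & (r.time_ms < proto.onset_ms + 500)
            slopes.append(np.max(np.diff(r.v[m]) / np.diff(r.time_ms[m])))
        assert slopes[1] < slopes[0]


class TestSimulate:
    def test_zero_stimulus_stays_at_rest(self):
        cfg, proto, _ = preset("spike", "simplified")
        quiet = proto.model_copy(update={"amplitude": 0.0})
        r = simulate(cfg, quiet, 3000.0)
        f = extract_ap_features(r)
        assert f.n_spikes == 0
        assert np.ptp(r.v[r.time_ms >= 0]) < 0.5

    def test_single_spike_preset_gives_one_spike(self):
        cfg, proto, dur = preset("spike", "simplified")
        r = simulate(cfg, proto, dur)
        assert extract_ap_features(r).n_spikes == 1

    def test_solver_tolerance_convergence(self):
        cfg, proto, _ = preset("spike", "simplified")
        peaks = []
        for rtol in (1e-7, 5e-8):
            r = simulate(cfg, proto, 2500.0, equil_ms=5000.0, rtol=rtol,
                         atol=rtol * 1e-2)
            peaks.append(np.max(r.v))
        assert abs(peaks[0] - peaks[1]) < 0.1

    def test_determinism(self):
        cfg, proto, _ = preset("spike", "simplified")
        r1 = simulate(cfg, proto, 1500.0, equil_ms=2000.0)
        r2 = simulate(cfg, proto, 1500.0, equil_ms=2000.0)
        assert np.array_equal(r1.v, r2.v)
        assert r1.metadata["config_hash"] == r2.metadata["config_hash"]

    def test_state_bounds_over_presets(self):
        for variant, name in [("simplified", "spike"), ("simplified", "plateau")]:
            cfg, proto, dur = preset(name, variant)
            r = simulate(cfg, proto, dur)
            assert np.all(r.v > -100) and np.all(r.v < 60)
            for g, arr in r.gates.items():
                assert np.all(arr > -1e-9) and np.all(arr < 1 + 1e-9), g
            assert np.all(r.ca > 0)

    def test_simplified_reports_offset_potential(self):
        cfg, proto, _ = preset("spike", "simplified")
        base = cfg.model_copy(update={
            "membrane": cfg.membrane.model_copy(update={"vb": 0.0})})
        r0 = simulate(base, proto, 1200.0, equil_ms=1500.0)
        r1 = simulate(cfg, proto, 1200.0, equil_ms=1500.0)
        vb = cfg.membrane.vb
        assert np.allclose(r1.v, r0.v + vb, atol=1e-6)


class TestFeatures:
    def make_result(self, t, v):
        n = len(t)
        zeros = np.zeros(n)
        return SimulationResult(time_ms=t, v=v, ca=np.full(n, 0.1),
                                gates={}, currents={}, stim=zeros,
                                metadata={"stim_onset_ms": 0.0})

    def test_constant_trace(self):
        t = np.arange(-2000.0, 3000.0, 10.0)
        f = extract_ap_features(self.make_result(t, np.full(len(t), -45.0)))
        assert f.resting == pytest.approx(-45.0)
        assert f.amplitude == pytest.approx(0.0)
        assert f.n_spikes == 0

    def test_square_pulse_plateau(self):
        t = np.arange(-2000.0, 8000.0, 5.0)
        v = np.full(len(t), -45.0)
        v[(t >= 100) & (t < 5100)] = 5.0
        f = extract_ap_features(self.make_result(t, v))
        assert f.plateau_s == pytest.approx(5.0, abs=0.02)
        assert f.amplitude == pytest.approx(50.0)
        assert f.v_range == pytest.approx(50.0)

    def test_missing_equilibration_rejected(self):
        t = np.arange(0.0, 1000.0, 10.0)
        with pytest.raises(InputError):
            extract_ap_features(self.make_result(t, np.full(len(t), -45.0)))


class TestSimplifiedSpec:
    def test_canonical_model_has_13_state_variables(self):
        cfg = default_simplified_config()
        assert len(cfg.state_names()) == 13

    def test_simplified_spec_roundtrip(self):
        from uterosim.defaults import default_simplified_spec
        spec = default_simplified_spec()
        assert spec.n_state_vars == 13
        cfg = spec.to_cell_config()
        assert {c.name for c in cfg.channels} == {"cal", "cat", "k1", "k2", "nscc"}

    def test_wrong_variable_count_rejected(self):
        cfg = default_simplified_config()
        broken = [c.model_copy(update={"gates": c.gates[:1]})
                  if c.name == "k1" else c for c in cfg.channels]
        with pytest.raises(ValueError):
            SimplifiedModelSpec(channels=broken)

    def test_full_model_has_21_state_variables(self):
        assert len(default_full_config().state_names()) == 21


def test_burst_preset_fires_multiple_spikes():
    cfg, proto, dur = preset("long-burst", "simplified")
    r = simulate(cfg, proto, dur)
    assert extract_ap_features(r).n_spikes > 3
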