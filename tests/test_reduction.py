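"""Jacobian linearization and diagonal-perturbation stability analysis."""

import math

import numpy as np
import pytest

from uterosim.defaults import build_config
from uterosim.myocyte import get_model
from uterosim.reduction import (jacobian, max_real_eig,
                                min_stabilizing_perturbation)


def brute_force_min_perturbation(jac, index, bound=5.0, step=1e-3):
    """Independent oracle: scan a linear delta grid on both signs."""
    mags = np.arange(step, bound + step / 2, step)
    best = math.inf
    for sign in (1.0, -1.0):
        for m in mags:
            trial = jac.copy()
            trial[index, index] += sign * m
            if np.max(np.linalg.eigvals(trial).real) < 0:
                best = min(best, m)
                break
    return best


class TestMinStabilizingPerturbation:
    def test_stable_matrix_needs_no_perturbation(self):
        jac = np.diag([-1.0, -2.0, -0.5])
        for i in range(3):
            assert min_stabilizing_perturbation(jac, i) == 0.0

    def test_diagonal_two_by_two_example(self):
        """diag(1, -2): the unstable entry needs |delta| = 1 (just past
        marginal); the stable entry cannot fix the other eigenvalue."""
        jac = np.diag([1.0, -2.0])
        d0 = min_stabilizing_perturbation(jac, 0, bound=50.0)
        assert d0 == pytest.approx(1.0, abs=2e-3)
        assert math.isinf(min_stabilizing_perturbation(jac, 1, bound=50.0))

    def test_companion_matrix_routh_hurwitz_boundary(self):
        """Companion form [[0, 1], [-a0, -a1]] with a1 < 0 is unstable;
        perturbing index 1 by delta shifts a1 -> a1 - delta, and the
        Routh-Hurwitz condition flips exactly at delta = a1."""
        jac = np.array([[0.0, 1.0], [-2.0, 0.7]])  # trace 0.7 > 0: unstable
        d1 = min_stabilizing_perturbation(jac, 1, bound=50.0)
        assert d1 == pytest.approx(0.7, abs=2e-3)

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_grid_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        jac = rng.normal(0.0, 1.0, size=(5, 5))
        for index in range(5):
            oracle = brute_force_min_perturbation(jac, index, bound=5.0)
            got = min_stabilizing_perturbation(jac, index, bound=5.0)
            if math.isinf(oracle):
                assert math.isinf(got) or got > 5.0 - 1e-6
            else:
                assert got == pytest.approx(oracle, abs=2e-3)

    def test_reducing_delta_by_ten_percent_leaves_instability(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            jac = rng.normal(0.0, 1.0, size=(4, 4))
            if max_real_eig(jac) < 0:
                continue
            for i in range(4):
                d = min_stabilizing_perturbation(jac, i, bound=20.0)
                if math.isinf(d) or d == 0.0:
                    continue
                for sign in (1.0, -1.0):
                    trial = jac.copy()
                    trial[i, i] += sign * 0.9 * d
                    # at 90 % of the critical size neither sign stabilizes
                    assert max_real_eig(trial) >= -1e-9


class TestJacobian:
    def test_recovers_linear_system_matrix(self):
        """On the cell model with all conductances zero the voltage row is
        zero and each gate row is linear with slope -1/tau."""
        cfg = build_config({
            "name": "lin", "variant": "full",
            "membrane": {"cm": 1.0},
            "calcium": {"alpha": 0.0, "tau_ms": 500.0, "rest_uM": 0.1},
            "channels": [
                {"name": "na", "gbar": 0.0, "e_rev": 80.0, "gates": [
                    {"name": "m", "kind": "activation", "v_half": -20.3,
                     "slope": 6.2, "exponent": 3, "tau": 2.0},
                    {"name": "h", "kind": "inactivation", "v_half": -46.2,
                     "slope": 7.2, "tau": 50.0}]},
            ],
            "ca_sources": [],
        })
        model = get_model(cfg)
        y = model.initial_state(v=-40.0)
        jac = jacobian(cfg, y)
        assert jac[0] == pytest.approx([0.0] * 4, abs=1e-9)
        assert jac[1, 1] == pytest.approx(-1 / 500.0, rel=1e-5)
        assert jac[2, 2] == pytest.approx(-1 / 2.0, rel=1e-5)
        assert jac[3, 3] == pytest.approx(-1 / 50.0, rel=1e-5)
        # gate rows depend only on v and themselves
        assert jac[2, 3] == pytest.approx(0.0, abs=1e-9)
        assert jac[3, 2] == pytest.approx(0.0, abs=1e-9)

    def test_gate_diagonal_is_negative_inverse_tau(self):
        from uterosim.defaults import default_full_config
        cfg = default_full_config()
        model = get_model(cfg)
        y = model.initial_state(v=-45.0)
        jac = jacobian(cfg, y)
        names = model.state_names
        for i, g in enumerate(model.gate_specs):
            row = 2 + i
            assert jac[row, row] == pytest.approx(-1.0 / g.tau(-45.0), rel=1e-4), names[row]

    def test_rank_falls_back_to_magnitude_on_stable_system(self):
        """With a stable steady state every perturbation is zero; the
        ranking then orders currents by magnitude, and a missing candidate
        for the magnitude slot yields a reduced model with a warning."""
        import warnings as _warnings

        from uterosim.reduction import rank_and_select
        cfg = build_config({
            "name": "toy", "variant": "full",
            "membrane": {"v_init": -50.0},
            "calcium": {"alpha": 0.0, "tau_ms": 1000.0, "rest_uM": 0.1},
            "channels": [
                {"name": "cal", "gbar": 0.05, "e_rev": 45.0, "gates": [
                    {"name": "d", "kind": "activation", "v_half": -26.0,
                     "slope": 6.5, "exponent": 2, "tau": 5.0}]},
                {"name": "k1", "gbar": 0.4, "e_rev": -80.0, "gates": [
                    {"name": "n", "kind": "activation", "v_half": -13.0,
                     "slope": 13.0, "exponent": 4, "tau": 20.0}]},
                {"name": "nscc", "gbar": 0.02, "e_rev": -11.8, "gates": []},
            ],
            "ca_sources": ["cal"],
        })
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            report = rank_and_select(cfg, n_rank=2)
        assert all(p == 0.0 for p in report.perturbations.values())
        # the two gated currents rank by magnitude; nscc fills the slot
        assert set(report.selected) == {"cal", "k1", "nscc"}
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            report4 = rank_and_select(cfg, n_rank=2,
                                      candidates=["cal", "k1"])
        assert "nscc" not in report4.selected
        assert report4.warnings

    def test_permutation_similarity(self):
        """Reordering state variables permutes the Jacobian consistently."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        perm = rng.permutation(6)
        p = np.eye(6)[perm]
        assert np.allclose((p @ a @ p.T)[np.ix_(range(6), range(6))],
                           a[np.ix_(perm, perm)])
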