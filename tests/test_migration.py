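"""Null-model machinery: angles, Rayleigh/von-Mises estimation, arc integrals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import i0

from chemodetect import (KAPPA_MAX, DegenerateCellError, Trajectory,
                         estimate_kappa, estimate_sigma, momentary_params,
                         persistence_cone_halfwidth, step_width,
                         turning_angle, vonmises_arc_integral)


def vm_density(theta, kappa):
    return np.exp(kappa * np.cos(theta)) / (2 * np.pi * i0(kappa))


def trapezoid_arc_mass(kappa, a, b, n=200001):
    """Independent quadrature oracle: high-resolution trapezoid rule over
    the raw (periodic) interval."""
    th = np.linspace(a, b, n)
    return float(np.trapezoid(vm_density(th, kappa), th))


class TestKinematics:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 0), (1, 0), (2, 0)], 0.0),
        ([(0, 0), (1, 0), (1, 1)], np.pi / 2),
        ([(0, 0), (1, 0), (0, 0)], np.pi),
        ([(0, 0), (1, 0), (2, -1)], -np.pi / 4),
    ])
    def test_turning_angle_examples(self, pts, expected):
        assert turning_angle(*pts) == pytest.approx(expected)

    def test_turning_angle_rejects_zero_step(self):
        with pytest.raises(DegenerateCellError):
            turning_angle((0, 0), (0, 0), (1, 0))

    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0), (3, 4), 5.0), ((1, 1), (1, 1), 0.0),
        ((1, 1), (2, 2), np.sqrt(2)),
    ])
    def test_step_width(self, a, b, expected):
        assert step_width(a, b) == pytest.approx(expected)


class TestEstimators:
    def test_sigma_closed_forms(self):
        assert estimate_sigma([np.sqrt(2)] * 8) == pytest.approx(1.0)
        assert estimate_sigma([3.0]) == pytest.approx(3.0 / np.sqrt(2))
        with pytest.raises(DegenerateCellError):
            estimate_sigma([0.0, 0.0])

    def test_sigma_monte_carlo_recovery(self, rng):
        w = rng.rayleigh(3.0, 100_000)
        assert 2.97 <= estimate_sigma(w) <= 3.03

    def test_kappa_degenerate_and_uniform_limits(self, rng):
        assert estimate_kappa(np.zeros(50)) == KAPPA_MAX
        assert estimate_kappa(rng.uniform(-np.pi, np.pi, 100_000)) < 0.02

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 5.0])
    def test_kappa_monte_carlo_recovery(self, rng, kappa):
        th = rng.vonmises(0.0, kappa, 100_000)
        assert estimate_kappa(th) == pytest.approx(kappa, abs=0.05 * max(1, kappa))

    def test_recovery_error_shrinks_at_root_n_rate(self, rng):
        errs = {}
        for n in (1_000, 100_000):
            reps = [abs(estimate_kappa(rng.vonmises(0.0, 2.0, n)) - 2.0)
                    for _ in range(20)]
            errs[n] = np.mean(reps)
        ratio = errs[1_000] / errs[100_000]   # expect ~ sqrt(100) = 10
        assert 4 < ratio < 25
        serrs = {}
        for n in (1_000, 100_000):
            reps = [abs(estimate_sigma(rng.rayleigh(2.0, n)) - 2.0)
                    for _ in range(20)]
            serrs[n] = np.mean(reps)
        assert 4 < serrs[1_000] / serrs[100_000] < 25


class TestArcIntegral:
    @pytest.mark.parametrize("kappa", [0.0, 0.7, 2.0, 10.0])
    def test_full_circle_normalizes_to_one(self, kappa):
        assert vonmises_arc_integral(kappa, -np.pi, np.pi) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_limit(self):
        assert vonmises_arc_integral(0.0, 0.3, 1.8) == pytest.approx(1.5 / (2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("kappa,a,b", [
        (2.0, -np.pi / 2, np.pi / 2), (2.0, 0.5, 2.5), (0.3, -3.0, 3.1),
        (5.0, 2.0, 7.0), (100.0, -0.1, 0.1),
    ])
    def test_matches_trapezoid_oracle(self, kappa, a, b):
        assert vonmises_arc_integral(kappa, a, b) == pytest.approx(
            trapezoid_arc_mass(kappa, a, b), abs=1e-8)

    def test_matches_scipy_vonmises_cdf(self):
        # independent cross-check against a second implementation route
        a, b = -1.2, 0.7
        for kappa in (0.4, 2.0, 8.0):
            expected = stats.vonmises.cdf(b, kappa) - stats.vonmises.cdf(a, kappa)
            assert vonmises_arc_integral(kappa, a, b) == pytest.approx(expected, abs=1e-7)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(kappa=st.floats(0, 50), a=st.floats(-np.pi, np.pi),
           length=st.floats(0, 2 * np.pi))
    def test_symmetry_and_monotonicity(self, kappa, a, length):
        b = a + length
        sym = vonmises_arc_integral(kappa, -b, -a)
        assert vonmises_arc_integral(kappa, a, b) == pytest.approx(sym, abs=1e-10)
        shorter = vonmises_arc_integral(kappa, a + 0.1 * length, b)
        assert shorter <= vonmises_arc_integral(kappa, a, b) + 1e-12

    def test_cone_halfwidth_solves_quantile(self):
        for kappa, p_ord in [(2.0, 0.95), (0.5, 0.8), (10.0, 0.99)]:
            thr = persistence_cone_halfwidth(kappa, p_ord)
            assert trapezoid_arc_mass(kappa, -thr, thr) == pytest.approx(p_ord, abs=1e-8)


class TestMomentary:
    def _traj(self, xy):
        xy = np.asarray(xy, float)
        xyz = np.column_stack([xy, np.zeros(len(xy))])
        return Trajectory(0, 0, np.arange(len(xy)), xyz)

    def test_straight_track(self):
        steps = momentary_params(self._traj([(2.0 * t, 0.0) for t in range(6)]),
                                 frame_interval=0.5)
        assert all(s.cos_theta == pytest.approx(1.0) for s in steps)
        assert all(s.speed == pytest.approx(4.0) for s in steps)

    def test_back_and_forth_track(self):
        xy = [(0, 0), (1, 0), (0, 0), (1, 0), (0, 0)]
        steps = momentary_params(self._traj(xy), frame_interval=1.0)
        assert all(s.cos_theta == pytest.approx(-1.0) for s in steps)

    def test_uncorrelated_walk_has_zero_mean_persistence(self, scenario_table):
        table = scenario_table("BLS", seed=9, n_immune=60, n_targets=0,
                               n_steps=300, field_size=20000.0,
                               kappa_range=(0.0, 0.0))
        from chemodetect import build_trajectories
        cs = [s.cos_theta for tr in build_trajectories(table)
              for s in momentary_params(tr, 1.0)]
        assert abs(np.mean(cs)) < 0.02
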