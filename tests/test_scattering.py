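"""Debye curves, Guinier analyses, R factor and the concentration check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import j1

from flexscat import (ScatteringCurve, build_sphere_model,
                      concentration_series_check, cross_section_fit,
                      debye_curve, guinier_fit, r_factor, read_curve,
                      write_curve)
from flexscat.scattering import FitError, average_curves
from flexscat.spheres import SphereModel

from conftest import random_ball_points


def spheres_from_points(xyz, radius=0.05):
    xyz = np.asarray(xyz, dtype=float)
    vol = len(xyz) * 4 / 3 * np.pi * radius**3
    return SphereModel(centers=xyz, radius=radius, hydrated=False,
                       dry_volume=vol, total_volume=vol, n_dry=len(xyz))


def brute_force_debye(spheres, q):
    """Independent direct double sum (no binning)."""
    n = spheres.n_spheres
    x = q * spheres.radius
    g = np.where(np.abs(x) > 1e-12,
                 (3 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300)**3) ** 2,
                 1.0)
    total = np.zeros_like(q)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.linalg.norm(spheres.centers[i] - spheres.centers[j])
            qr = q * r
            total += np.where(qr > 1e-12, np.sin(qr) / np.maximum(qr, 1e-300), 1.0)
    return g * (1.0 / n + total / n**2)


class TestDebye:
    def test_single_sphere_form_factor_first_zero(self):
        # first zero of the sphere form-factor amplitude at x: tan x = x
        x_zero = brentq(lambda x: np.sin(x) - x * np.cos(x), 4.0, 5.0)
        assert x_zero == pytest.approx(4.4934, abs=1e-3)
        R = 2.0
        sp = spheres_from_points([[0.0, 0.0, 0.0]], radius=R)
        q = np.linspace(x_zero / R - 0.05, x_zero / R + 0.05, 201)
        c = debye_curve(sp, q)
        assert c.q[np.argmin(c.i)] == pytest.approx(x_zero / R, abs=2e-3)

    def test_low_q_normalization(self):
        sp = spheres_from_points(random_ball_points(60, 1.0, seed=2), 0.2)
        c = debye_curve(sp, np.array([1e-4, 0.05, 0.1]))
        assert c.i[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(c.i <= 1.0 + 1e-9)

    def test_binned_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(5)
        sp = spheres_from_points(rng.uniform(0, 4, size=(50, 3)), 0.3)
        q = np.linspace(0.05, 2.0, 40)
        binned = debye_curve(sp, q, bin_width=0.01)
        brute = brute_force_debye(sp, q)
        np.testing.assert_allclose(binned.i, brute, rtol=1e-3)

    def test_errors(self):
        sp = spheres_from_points([[0, 0, 0]])
        with pytest.raises(ValueError):
            debye_curve(sp, np.array([-0.1, 0.5]))


class TestGuinier:
    def test_exact_gaussian_curve(self):
        q = np.linspace(0.02, 1.0, 200)
        c = ScatteringCurve(q=q, i=np.exp(-(q**2) * 9.0 / 3.0))
        g = guinier_fit(c)
        assert g.rg == pytest.approx(3.0, rel=1e-6)
        assert g.i0 == pytest.approx(1.0, rel=1e-6)
        assert g.qrg_range[1] <= 1.3 + 1e-9

    def test_ball_rg_recovered(self):
        R = 3.0
        xyz = random_ball_points(3000, R, seed=9)
        sp = spheres_from_points(xyz, 0.15)
        c = debye_curve(sp, np.linspace(0.02, 2.0, 300))
        g = guinier_fit(c)
        assert g.rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.02)

    def test_rising_curve_rejected(self):
        q = np.linspace(0.02, 1.0, 100)
        with pytest.raises(FitError):
            guinier_fit(ScatteringCurve(q=q, i=np.exp(q**2)))


class TestCrossSection:
    def test_infinite_cylinder_rxs(self):
        # long-cylinder intensity: I(Q) ~ (1/Q) [2 J1(Qa)/(Qa)]^2, R_xs = a/sqrt(2)
        a = 1.0
        q = np.linspace(0.05, 1.2, 200)
        i = (1.0 / q) * (2 * j1(q * a) / (q * a)) ** 2
        res = cross_section_fit(ScatteringCurve(q=q, i=i), window=(0.1, 1.0))
        assert res.rxs == pytest.approx(a / np.sqrt(2), rel=0.03)

    def test_rod_length_relation(self):
        # straight rod: R_g^2 - R_xs^2 = L^2 / 12
        L, a = 12.0, 0.3
        centers = np.column_stack([np.zeros(120), np.zeros(120),
                                   np.linspace(-L / 2, L / 2, 120)])
        sp = spheres_from_points(centers, a)
        c = debye_curve(sp, np.geomspace(0.01, 3.0, 400))
        rg = guinier_fit(c, qrg_limit=1.0).rg
        rxs = cross_section_fit(c, window=(0.7, 2.5)).rxs
        assert rg**2 - rxs**2 == pytest.approx(L**2 / 12, rel=0.05)

    def test_flat_one_over_q_curve_gives_zero(self):
        q = np.linspace(0.2, 1.0, 50)
        res = cross_section_fit(ScatteringCurve(q=q, i=5.0 / q),
                                window=(0.2, 1.0))
        assert res.rxs == 0.0


class TestRFactor:
    def test_identical_curves(self):
        q = np.linspace(0.05, 2.0, 100)
        c = ScatteringCurve(q=q, i=np.exp(-q))
        s = r_factor(c, c)
        assert s.r_factor == pytest.approx(0.0, abs=1e-4)
        assert s.eta == pytest.approx(1.0, rel=1e-3)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-2, max_value=1e2))
    def test_scale_invariance(self, scale):
        q = np.linspace(0.05, 2.0, 80)
        i = 1.0 / (1.0 + q**2) ** 2
        a = ScatteringCurve(q=q, i=i)
        b = ScatteringCurve(q=q, i=scale * i)
        assert r_factor(a, b).r_factor == pytest.approx(0.0, abs=1e-3)

    def test_ranks_correct_shape_lower(self):
        ball = spheres_from_points(random_ball_points(300, 2.0, seed=1), 0.2)
        coil = spheres_from_points(
            np.cumsum(np.random.default_rng(2).normal(0, 0.4, (300, 3)),
                      axis=0), 0.2)
        q = np.linspace(0.05, 2.0, 120)
        target = debye_curve(ball, q)
        target2 = debye_curve(
            spheres_from_points(random_ball_points(280, 2.0, seed=3), 0.2), q)
        r_ball = r_factor(target, target2).r_factor
        r_coil = r_factor(target, debye_curve(coil, q)).r_factor
        assert r_ball < r_coil

    def test_no_overlap_errors(self):
        a = ScatteringCurve(q=np.linspace(0.05, 0.1, 10), i=np.ones(10))
        b = ScatteringCurve(q=np.linspace(1.0, 2.0, 10), i=np.ones(10))
        with pytest.raises(ValueError):
            r_factor(a, b)


class TestCurveIO:
    def test_round_trip_with_units(self, tmp_path):
        q = np.linspace(0.05, 2.0, 30)
        c = ScatteringCurve(q=q, i=np.exp(-q), sigma=0.01 * np.exp(-q))
        p = tmp_path / "c.dat"
        write_curve(c, p)
        c2 = read_curve(p)
        np.testing.assert_allclose(c2.q, c.q, rtol=1e-6)
        np.testing.assert_allclose(c2.i, c.i, rtol=1e-6)
        p2 = tmp_path / "c_angstrom.dat"
        write_curve(c, p2, angstrom_units=True)
        c3 = read_curve(p2, angstrom_units=True)
        np.testing.assert_allclose(c3.q, c.q, rtol=1e-6)


class TestConcentrationSeries:
    @staticmethod
    def _series(i0_trend=0.0):
        q = np.linspace(0.05, 2.0, 100)
        base = np.exp(-(q**2) * 3.6**2 / 3.0) + 1e-3
        out = []
        for conc in (0.25, 0.63, 1.26):
            i0 = conc * (1.0 + i0_trend * conc)
            out.append(ScatteringCurve(q=q, i=i0 * base,
                                       sigma=1e-4 * i0 * base + 1e-9,
                                       concentration=conc))
        return out

    def test_flat_series_not_flagged(self):
        rep = concentration_series_check(self._series(0.0))
        assert not rep.flagged
        assert np.allclose(rep.i0_over_c, rep.i0_over_c[0], rtol=1e-6)

    def test_rising_i0_over_c_flagged(self):
        rep = concentration_series_check(self._series(0.20))
        assert rep.flagged

    def test_missing_labels_error(self):
        curves = self._series()
        curves[0].concentration = None
        with pytest.raises(ValueError):
            concentration_series_check(curves)


def test_average_curves_reduces_noise():
    q = np.linspace(0.05, 2.0, 50)
    rng = np.random.default_rng(0)
    base = np.exp(-q)
    curves = [ScatteringCurve(q=q, i=base + rng.normal(0, 0.05, 50),
                              sigma=np.full(50, 0.05)) for _ in range(16)]
    avg = average_curves(curves)
    assert np.std(avg.i - base) < 0.5 * 0.05
    assert avg.sigma[0] == pytest.approx(0.05 / 4, rel=1e-6)
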