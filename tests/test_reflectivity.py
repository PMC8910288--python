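"""Optical correctness of the reflectivity engine."""

import numpy as np
import pytest

from refmem import components as C
from refmem import reflectivity as R
from refmem import slab as S

from _oracles import fresnel_reflectivity, wave_equation_reflectivity

D2O = C.SolventContrast("D2O", 1.0)
H2O = C.SolventContrast("H2O", 0.0)


def bare_substrate():
    return S.SlabStack(oxide=None, layers=[], backing_roughness=0.0)


def random_stack(rng, n_layers):
    slds = [2.07] + list(rng.uniform(-0.5, 6.5, n_layers)) + [rng.uniform(-0.56, 6.36)]
    thickness = rng.uniform(5.0, 80.0, n_layers)
    return np.array(slds), thickness


class TestAbeles:
    def test_matches_fresnel_closed_form(self):
        q = np.linspace(0.002, 0.3, 400)
        curve = R.abeles(bare_substrate(), q, D2O)
        expected = fresnel_reflectivity(q, C.get_component("silicon").sld(), D2O.sld)
        np.testing.assert_allclose(curve.r, expected, rtol=1e-10)

    def test_total_reflection_below_critical_edge(self):
        # Qc = sqrt(16 pi drho) ~ 0.0147 for Si|D2O
        drho = (D2O.sld - C.get_component("silicon").sld()) * 1e-6
        qc = np.sqrt(16 * np.pi * drho)
        q = np.linspace(0.002, 0.99 * qc, 50)
        curve = R.abeles(bare_substrate(), q, D2O)
        np.testing.assert_allclose(curve.r, 1.0, atol=1e-12)

    def test_kiessig_fringe_spacing(self):
        # single uniform film: fringe minima spaced by ~2 pi / tau at high Q
        tau = 300.0
        film = S.SlabStack(
            oxide=None,
            layers=[S.Layer("film", tau, 0.0, 0.0, sld=3.47)],
            backing_roughness=0.0,
        )
        q = np.linspace(0.05, 0.2, 8000)
        curve = R.abeles(film, q, H2O)
        r = curve.r
        minima = q[1:-1][(r[1:-1] < r[:-2]) & (r[1:-1] < r[2:])]
        spacing = np.diff(minima)
        assert np.median(spacing) == pytest.approx(2 * np.pi / tau, rel=0.02)

    def test_agrees_with_wave_equation_oracle(self):
        # 20 randomized sharp stacks against an independent direct solution
        # of the wave equation
        rng = np.random.default_rng(42)
        q = np.linspace(0.01, 0.3, 60)
        for _ in range(20):
            n = rng.integers(1, 7)
            slds, thickness = random_stack(rng, int(n))
            mine = R.abeles_profile(q, slds, thickness, np.zeros(n + 1))
            ref = wave_equation_reflectivity(q, slds, thickness)
            np.testing.assert_allclose(mine, ref, rtol=1e-6)

    def test_optical_reciprocity(self):
        # reversing the stack preserves |r|^2 at matched wavevectors
        rng = np.random.default_rng(7)
        slds, thickness = random_stack(rng, 4)
        rough = rng.uniform(0.0, 3.0, 5)
        q = np.linspace(0.05, 0.3, 50)
        fwd = R.abeles_profile(q, slds, thickness, rough)
        # matched Q in the reversed fronting medium
        kz = q / 2.0
        kz_rev = np.sqrt(kz**2 - 4 * np.pi * (slds[-1] - slds[0]) * 1e-6)
        rev = R.abeles_profile(
            2 * kz_rev, slds[::-1], thickness[::-1], rough[::-1]
        )
        np.testing.assert_allclose(fwd, rev, rtol=1e-8)

    def test_physical_range(self):
        rng = np.random.default_rng(3)
        q = np.linspace(0.005, 0.3, 200)
        for _ in range(5):
            slds, thickness = random_stack(rng, 5)
            rough = rng.uniform(0.0, 2.0, 6)
            r = R.abeles_profile(q, slds, thickness, rough)
            assert np.all(r > 0) and np.all(r <= 1 + 1e-12)

    def test_nevot_croce_zero_equals_sharp(self):
        rng = np.random.default_rng(11)
        slds, thickness = random_stack(rng, 3)
        q = np.linspace(0.01, 0.3, 100)
        sharp = R.abeles_profile(q, slds, thickness, np.zeros(4))
        nc = R.abeles_profile(q, slds, thickness, np.full(4, 1e-12))
        np.testing.assert_allclose(sharp, nc, rtol=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            R.abeles_profile([0.1], [2.07, 6.36], [-5.0], [0, 0])
        with pytest.raises(ValueError):
            R.abeles_profile([0.1], [2.07, 3.0, 6.36], [10.0], [0, -1, 0])
        with pytest.raises(ValueError):
            R.abeles(bare_substrate(), np.array([-0.1, 0.1]), D2O)

    def test_microslice_warning_and_fallback(self):
        slds = np.array([2.07, 4.0, 6.36])
        with pytest.warns(UserWarning, match="roughness exceeds"):
            R.abeles_profile(np.linspace(0.01, 0.2, 50), slds, [6.0], [1.0, 5.0])
        q = np.linspace(0.01, 0.1, 50)
        nc = R.abeles_profile(q, slds, [30.0], [4.0, 4.0], microslice=False)
        sliced = R.abeles_profile(q, slds, [30.0], [4.0, 4.0], microslice=True)
        # the two roughness treatments agree at moderate sigma/Q
        np.testing.assert_allclose(nc, sliced, rtol=0.05)


class TestSmearing:
    def setup_method(self):
        stack = S.SlabStack(
            oxide=None,
            layers=[S.Layer("film", 120.0, 2.0, 0.0, sld=4.0)],
        )
        slds, thick, rough = stack.profile(D2O)
        self.model = lambda q: R.abeles_profile(q, slds, thick, rough)

    def test_vanishing_resolution_is_identity(self):
        q = np.linspace(0.02, 0.2, 100)
        smeared = R.smear(self.model, q, dq_over_q=1e-7)
        np.testing.assert_allclose(smeared.r, self.model(q), rtol=1e-8)

    def test_constant_model_unchanged(self):
        q = np.linspace(0.02, 0.2, 50)
        smeared = R.smear(lambda qq: np.full_like(qq, 0.123), q, dq_over_q=0.1)
        np.testing.assert_allclose(smeared.r, 0.123, rtol=1e-12)

    def test_against_dense_grid_convolution(self):
        # brute-force numerical convolution on a fine grid as oracle
        q = np.linspace(0.03, 0.18, 40)
        dqq = 0.05
        smeared = R.smear(self.model, q, dq_over_q=dqq)
        fwhm = 2 * np.sqrt(2 * np.log(2))
        expected = np.empty_like(q)
        for i, q0 in enumerate(q):
            sig = dqq * q0 / fwhm
            grid = np.linspace(q0 - 5 * sig, q0 + 5 * sig, 4001)
            w = np.exp(-0.5 * ((grid - q0) / sig) ** 2)
            expected[i] = np.trapezoid(w * self.model(grid), grid) / np.trapezoid(
                w, grid
            )
        np.testing.assert_allclose(smeared.r, expected, rtol=5e-3)

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            R.smear(self.model, np.array([0.1]), dq_over_q=-0.1)

    def test_curve_input_interpolation(self):
        q = np.linspace(0.02, 0.2, 400)
        curve = R.ReflectivityCurve(q, self.model(q))
        a = R.smear(curve, instrument=R.InstrumentModel(dq_over_q=0.03))
        b = R.smear(self.model, q, dq_over_q=0.03)
        inner = (q > 0.03) & (q < 0.18)
        np.testing.assert_allclose(a.r[inner], b.r[inner], rtol=1e-2)


class TestScaleBackground:
    def test_identity_and_constant(self):
        q = np.linspace(0.01, 0.1, 10)
        curve = R.ReflectivityCurve(q, np.linspace(1, 0.1, 10))
        same = R.apply_scale_background(curve, 1.0, 0.0)
        np.testing.assert_array_equal(same.r, curve.r)
        zero = R.ReflectivityCurve(q, np.zeros(10))
        np.testing.assert_allclose(
            R.apply_scale_background(zero, 2.0, 1e-5).r, 1e-5
        )

    def test_invertible(self):
        q = np.linspace(0.01, 0.1, 10)
        curve = R.ReflectivityCurve(q, np.linspace(1, 0.1, 10))
        out = R.apply_scale_background(curve, 0.9, 1e-6)
        np.testing.assert_allclose((out.r - 1e-6) / 0.9, curve.r, rtol=1e-12)

    def test_scale_must_be_positive(self):
        curve = R.ReflectivityCurve(np.array([0.1]), np.array([0.5]))
        with pytest.raises(ValueError):
            R.apply_scale_background(curve, 0.0, 0.0)


def test_instrument_validation():
    with pytest.raises(ValueError):
        R.InstrumentModel(dq_over_q=0.0)
    with pytest.raises(ValueError):
        R.InstrumentModel(scale=-1.0)
    with pytest.raises(ValueError):
        R.InstrumentModel(background=-1e-6)


def test_curve_validation():
    with pytest.raises(ValueError):
        R.ReflectivityCurve(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
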