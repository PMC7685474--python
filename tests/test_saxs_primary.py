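"""SAXS primary analysis against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from af4saxs.saxs_primary import (ScatteringCurve, chi2, dmax_scan,
                                  guinier_fit, mw_from_excluded_volume,
                                  mw_from_standard, pddf_ift, porod_volume,
                                  round_half_away, round_sig,
                                  select_and_average_frames, shape_factor)
from af4saxs.synthetic_data import SAXSSimSpec, simulate_saxs_curve


def sphere_curve(radius=3.0, noise=0.01, floor=1e-4, seed=0,
                 q_max=6.0, n_q=400):
    return simulate_saxs_curve(SAXSSimSpec(
        model="sphere", radius_nm=radius, noise_relative=noise,
        noise_floor=floor, seed=seed, q_nm=np.linspace(0.05, q_max, n_q)))


def sphere_pddf_closed_form(r, radius):
    """p(r) of a homogeneous sphere, unnormalised; zero beyond the diameter."""
    x = np.asarray(r, float)
    p = x ** 2 * (1 - 3 * x / (4 * radius) + x ** 3 / (16 * radius ** 3))
    p[x > 2 * radius] = 0.0
    return p


class TestChi2:
    def test_self_fit_is_zero(self):
        c = sphere_curve()
        fq = chi2(c, c.intensity)
        assert fq.chi2 == pytest.approx(0.0, abs=1e-20)
        assert fq.scale_c == pytest.approx(1.0)

    def test_alternating_residuals(self):
        n = 100
        q = np.linspace(0.1, 2.0, n)
        i = np.ones(n)
        s = np.full(n, 0.1)
        model = i + s * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        fq = chi2(ScatteringCurve(q=q, intensity=i, sigma=s), model,
                  optimize_scale=False)
        assert fq.chi2 == pytest.approx(n / (n - 1))

    @settings(deadline=None, max_examples=30)
    @given(k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, k):
        c = sphere_curve(seed=1)
        fq = chi2(c, k * c.intensity, optimize_scale=True)
        assert fq.chi2 == pytest.approx(0.0, abs=1e-12)
        assert fq.scale_c == pytest.approx(1.0 / k, rel=1e-9)

    def test_too_few_points_rejected(self):
        c = ScatteringCurve(q=np.array([0.1]), intensity=np.array([1.0]),
                            sigma=np.array([0.1]))
        with pytest.raises(ValueError):
            chi2(c, np.array([1.0]))


class TestFrameSelection:
    def test_identical_noiseless_frames(self):
        base = sphere_curve(noise=0.0, floor=0.0)
        base.sigma = np.full_like(base.q, 0.01)
        frames = [ScatteringCurve(q=base.q, intensity=base.intensity.copy(),
                                  sigma=base.sigma.copy()) for _ in range(5)]
        avg, kept = select_and_average_frames(frames)
        assert kept == [0, 1, 2, 3, 4]
        np.testing.assert_allclose(avg.intensity, base.intensity)

    def test_outlier_frames_excluded(self):
        frames = [sphere_curve(radius=3.0, seed=i) for i in range(10)]
        frames += [sphere_curve(radius=6.0, seed=100 + i) for i in range(2)]
        _, kept = select_and_average_frames(frames)
        assert kept == list(range(10))

    def test_noise_chi2_statistics(self):
        """Pairwise reduced chi2 of pure-noise frames is ~1 on average."""
        chis = []
        for seed in range(50):
            rng1 = np.random.default_rng(seed)
            rng2 = np.random.default_rng(1000 + seed)
            q = np.linspace(0.1, 3.0, 200)
            s = np.full(200, 0.05)
            i1 = 1.0 + rng1.normal(0, 0.05, 200)
            i2 = 1.0 + rng2.normal(0, 0.05, 200)
            pair_sigma = s * math.sqrt(2)     # variance of a difference
            chis.append(chi2(ScatteringCurve(q=q, intensity=i1,
                                             sigma=pair_sigma),
                             i2, optimize_scale=False).chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.2)


class TestGuinier:
    def test_noiseless_sphere(self):
        c = sphere_curve(noise=0.0, floor=0.0)
        c.sigma = np.maximum(0.01 * np.abs(c.intensity), 1e-12)
        g = guinier_fit(c)
        assert g.radius_gyration_nm == pytest.approx(math.sqrt(3 / 5) * 3.0,
                                                     rel=5e-3)
        assert g.i_zero == pytest.approx(1.0, rel=5e-3)
        assert g.q_max_times_rg <= 1.3

    def test_noisy_round_trip(self):
        radius = 2.81 / math.sqrt(3 / 5)
        c = sphere_curve(radius=radius, noise=0.01, seed=7, q_max=5.0,
                         n_q=350)
        g = guinier_fit(c)
        assert g.radius_gyration_nm == pytest.approx(2.81, rel=0.03)

    def test_aggregation_upturn_flagged(self):
        clean = sphere_curve(noise=0.0, floor=0.0, q_max=5.0, n_q=350)
        i = clean.intensity + 0.002 * clean.q ** -2.5
        c = ScatteringCurve(q=clean.q, intensity=i,
                            sigma=0.01 * np.abs(i) + 1e-6)
        assert not guinier_fit(c).linearity_flag

    def test_clean_noisy_curve_flagged_linear(self):
        c = sphere_curve(seed=3)
        assert guinier_fit(c).linearity_flag


class TestPDDF:
    def test_sphere_closed_form(self):
        c = sphere_curve(seed=1)
        pddf = pddf_ift(c, 6.0)
        p_true = sphere_pddf_closed_form(pddf.r, 3.0)
        p_true /= np.trapezoid(p_true, pddf.r)
        p_fit = pddf.p_of_r / np.trapezoid(pddf.p_of_r, pddf.r)
        rms = np.sqrt(np.mean((p_fit - p_true) ** 2)) / p_true.max()
        assert rms < 0.02
        assert pddf.rg_real_nm == pytest.approx(math.sqrt(3 / 5) * 3.0,
                                                rel=0.01)

    def test_endpoints_and_nonnegativity(self):
        pddf = pddf_ift(sphere_curve(seed=2), 6.0)
        assert pddf.p_of_r[0] == 0.0
        assert pddf.p_of_r[-1] == 0.0
        assert np.all(pddf.p_of_r >= 0.0)

    def test_guinier_consistency(self):
        """Real-space and reciprocal-space Rg and I(0) agree on clean data."""
        c = sphere_curve(noise=0.002, floor=1e-5, seed=4)
        g = guinier_fit(c)
        pddf = pddf_ift(c, 6.0)
        assert abs(g.radius_gyration_nm - pddf.rg_real_nm) \
            / g.radius_gyration_nm < 0.03
        assert abs(g.i_zero - pddf.i_zero_real) / g.i_zero < 0.03

    def test_dumbbell_support(self):
        """A two-sphere dumbbell has maximum dimension 2R + d; p(r) mass
        beyond it should be negligible."""
        spec = SAXSSimSpec(model="dumbbell", radius_nm=1.5, separation_nm=4.0,
                           noise_relative=0.005, noise_floor=1e-5, seed=5,
                           q_nm=np.linspace(0.05, 6.0, 400))
        c = simulate_saxs_curve(spec)
        pddf = pddf_ift(c, 10.0)
        dmax_true = 2 * 1.5 + 4.0
        beyond = pddf.p_of_r[pddf.r > dmax_true + 2 * (pddf.r[1] - pddf.r[0])]
        assert beyond.max() < 0.05 * pddf.p_of_r.max()

    def test_ift_residuals_statistically_consistent(self):
        """Median reduced chi2 of the reconstruction is <= 1.5 when the data
        really carry the stated errors."""
        chis = [pddf_ift(sphere_curve(seed=s, n_q=200), 6.0).reduced_chi2
                for s in range(50)]
        assert np.median(chis) <= 1.5

    def test_dmax_recovery(self):
        """d_max scan on data generated with D_max = 12 nm lands within 1 nm."""
        c = sphere_curve(radius=6.0, q_max=4.0, n_q=300, seed=3)
        dmax, _ = dmax_scan(c, np.arange(8.0, 16.5, 1.0))
        assert abs(dmax - 12.0) <= 1.0


class TestPorod:
    @pytest.mark.parametrize("radius", [2.0, 3.0, 4.5, 6.0])
    def test_sphere_volume(self, radius):
        c = sphere_curve(radius=radius, noise=0.0, floor=0.0, q_max=10.0,
                         n_q=800)
        c.sigma = np.maximum(0.01 * np.abs(c.intensity), 1e-12)
        res = porod_volume(c, i_zero=1.0, rg_nm=math.sqrt(3 / 5) * radius)
        v_true = 4 / 3 * math.pi * radius ** 3
        assert res.porod_volume_nm3 == pytest.approx(v_true, rel=0.10)

    def test_table_values(self):
        assert round_half_away(100 / 1.6) == 63
        assert round_half_away(213 / 1.6) == 133

    def test_oversubtracted_background_rejected(self):
        c0 = sphere_curve(noise=0.0, floor=0.0, q_max=8.0, n_q=500)
        i = c0.intensity - 2e-4          # background over-subtraction
        c = ScatteringCurve(q=c0.q, intensity=i, sigma=np.full_like(i, 1e-4))
        with pytest.raises(ValueError, match="Porod"):
            porod_volume(c, i_zero=1.0, rg_nm=2.32)


class TestMwEstimators:
    def test_excluded_volume_rule(self):
        assert mw_from_excluded_volume(46.0) == 23.0
        assert mw_from_excluded_volume(0.0) == 0.0
        assert mw_from_excluded_volume(2 * 46.0) == 2 * 23.0

    def test_standard_identity(self):
        assert mw_from_standard(2.0, 1.0, 2.0, 1.0, 66.0) == pytest.approx(66.0)

    def test_standard_scale_invariance(self):
        a = mw_from_standard(2.0, 1.0, 3.0, 2.0, 66.0)
        b = mw_from_standard(4.0, 2.0, 3.0, 2.0, 66.0)
        assert a == pytest.approx(b)

    def test_standard_round_trip_from_simulation(self):
        """I(0) scales with MW at fixed mass concentration, so a 25 kDa sample
        against a 66 kDa reference is recovered."""
        ref = simulate_saxs_curve(SAXSSimSpec(
            model="sphere", radius_nm=3.0, i_zero=66.0, noise_relative=0.0,
            noise_floor=0.0))
        ref.sigma = np.maximum(0.005 * ref.intensity, 1e-12)
        sam = simulate_saxs_curve(SAXSSimSpec(
            model="sphere", radius_nm=2.2, i_zero=25.0, noise_relative=0.0,
            noise_floor=0.0))
        sam.sigma = np.maximum(0.005 * sam.intensity, 1e-12)
        i0_ref = guinier_fit(ref).i_zero
        i0_sam = guinier_fit(sam).i_zero
        mw = mw_from_standard(i0_sam, 1.0, i0_ref, 1.0, 66.0)
        assert mw == pytest.approx(25.0, rel=0.01)


class TestShapeFactor:
    def test_solid_sphere(self):
        r = 3.0
        rho = shape_factor(math.sqrt(3 / 5) * r, r).rho
        assert round_sig(rho, 2) == 0.77

    def test_identity(self):
        assert shape_factor(2.5, 2.5).rho == 1.0

    def test_published_ratios(self):
        assert round_sig(shape_factor(2.81, 3.3).rho, 2) == 0.85
        assert round_sig(shape_factor(3.18, 3.9).rho, 2) == 0.82
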