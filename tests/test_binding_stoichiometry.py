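"""Deconvolution, peak areas and the bound-ratio arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from af4saxs.binding_stoichiometry import (DeconvolutionResult, GaussianPeak,
                                           area_under_peak, binding_ratios,
                                           fit_baseline_and_deconvolve,
                                           konv_from_pure_injection,
                                           mixing_molar_ratio,
                                           monomer_dimer_content)


def gaussian(t, area, center, sigma):
    return area / (sigma * math.sqrt(2 * math.pi)) \
        * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def deconv_from_areas(free=0.0, monomer=0.0, dimer=0.0):
    peaks = []
    for label, area, center in [("free_gaz", free, 4.0),
                                ("monomer", monomer, 4.8),
                                ("dimer", dimer, 6.5)]:
        amp = area / (0.2 * math.sqrt(2 * math.pi))
        peaks.append(GaussianPeak(center, 0.2, amp, label))
    return DeconvolutionResult(peaks=peaks, residual_rms=0.0,
                               baseline=(0.0, 0.0))


class TestDeconvolution:
    def test_single_noiseless_gaussian_exact(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 4.5, 0.3)
        res = fit_baseline_and_deconvolve(t, y, [(3.5, 5.5)], ["peak"])
        pk = res.peaks[0]
        assert pk.center_min == pytest.approx(4.5, abs=1e-6)
        assert pk.sigma_min == pytest.approx(0.3, abs=1e-6)
        assert pk.area == pytest.approx(1.0, rel=1e-6)

    def test_overlapping_pair_with_noise(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 4.5, 0.4) + gaussian(t, 0.6, 5.3, 0.4)
        y = y + rng.normal(0.0, 0.01 * y.max(), t.size)
        res = fit_baseline_and_deconvolve(t, y, [(3.5, 4.9), (5.0, 6.5)],
                                          ["a", "b"])
        assert res.area("a") == pytest.approx(1.0, rel=0.02)
        assert res.area("b") == pytest.approx(0.6, rel=0.02)

    def test_flat_zero_signal_flagged_empty(self):
        t = np.arange(0.0, 10.0, 0.01)
        res = fit_baseline_and_deconvolve(t, np.zeros_like(t), [(3.0, 5.0)],
                                          ["peak"])
        assert res.empty
        assert res.peaks[0].area == 0.0

    def test_overlapping_windows_rejected(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.raises(ValueError, match="disjoint"):
            fit_baseline_and_deconvolve(t, np.ones_like(t),
                                        [(3.0, 5.0), (4.5, 6.0)], ["a", "b"])


class TestAreaUnderPeak:
    def test_rectangle(self):
        t = np.arange(0.0, 10.0, 0.001)
        y = np.where((t >= 4.0) & (t <= 6.0), 1.0, 0.0)
        assert area_under_peak(t, y, (3.0, 7.0)) == pytest.approx(2.0,
                                                                  abs=2e-3)

    def test_gaussian_vs_closed_form(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 5.0, 0.4)
        area = area_under_peak(t, y, (3.0, 7.0))     # +/- 5 sigma
        assert area == pytest.approx(1.0, rel=1e-4)

    def test_baseline_window_near_zero(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 5.0, 0.2)
        assert abs(area_under_peak(t, y, (8.0, 9.0))) < 1e-12

    def test_empty_window_warns(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.warns(UserWarning):
            assert area_under_peak(t, t, (20.0, 21.0)) == 0.0


class TestMonomerDimerContent:
    def test_equal_areas(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 4.5, 0.2) + gaussian(t, 1.0, 6.5, 0.2)
        fm, fd = monomer_dimer_content(t, y, (3.5, 5.5), (5.6, 7.5))
        assert fm == pytest.approx(0.5, abs=1e-6)
        assert fm + fd == pytest.approx(1.0, abs=1e-12)

    def test_no_dimer(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = gaussian(t, 1.0, 4.5, 0.2)
        fm, fd = monomer_dimer_content(t, y, (3.5, 5.5), (5.6, 7.5))
        assert fm == pytest.approx(1.0, abs=1e-7)   # Gaussian tail beyond 5 sigma

    def test_zero_total_rejected(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.raises(ValueError):
            monomer_dimer_content(t, np.zeros_like(t), (3.5, 5.5), (5.6, 7.5))


class TestKonv:
    def test_definition(self):
        # 2 mg/mL of an 11.5 kDa protein = 2/11500 mol/L over area 10
        konv = konv_from_pure_injection(10.0, 2.0, 11.5)
        assert konv == pytest.approx((2.0 / 11500.0) / 10.0, rel=1e-12)

    def test_inverse_in_area(self):
        assert konv_from_pure_injection(20.0, 2.0, 11.5) == pytest.approx(
            0.5 * konv_from_pure_injection(10.0, 2.0, 11.5), rel=1e-12)

    def test_round_trip(self):
        konv = konv_from_pure_injection(7.3, 1.4, 11.5)
        assert 7.3 * konv == pytest.approx(1.4 / 11500.0, rel=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            konv_from_pure_injection(0.0, 2.0, 11.5)


class TestBindingRatios:
    HSA_TOT = 1.0 / 66500.0

    def test_no_ligand_added(self):
        mix = deconv_from_areas(free=0.0, monomer=5.0, dimer=1.0)
        pure = deconv_from_areas(monomer=5.0, dimer=1.0)
        res = binding_ratios(mix, pure, 1e-6, self.HSA_TOT, 0.93, 0.0)
        assert res.overall_gaz_per_hsa == 0.0
        assert res.free_gaz_per_hsa_tot == 0.0
        assert res.gaz_per_hsa_dimer == 0.0

    def test_mixture_identical_to_pure(self):
        mix = deconv_from_areas(free=0.0, monomer=5.0, dimer=1.0)
        pure = deconv_from_areas(monomer=5.0, dimer=1.0)
        res = binding_ratios(mix, pure, 1e-6, self.HSA_TOT, 0.93, 0.0)
        assert res.gaz_per_hsa_dimer == 0.0
        assert res.gaz_per_hsa_monomer == 0.0

    def test_known_partition_recovered(self):
        konv = 1e-6
        added = 1.5 * self.HSA_TOT
        free = 0.2 * self.HSA_TOT
        in_dim = 0.2 * self.HSA_TOT
        mix = deconv_from_areas(free=free / konv, monomer=5.0,
                                dimer=1.0 + in_dim / konv)
        pure = deconv_from_areas(monomer=5.0, dimer=1.0)
        res = binding_ratios(mix, pure, konv, self.HSA_TOT, 0.93, added)
        assert res.c_gaz_free == pytest.approx(free, rel=1e-9)
        assert res.c_gaz_in_dimer == pytest.approx(in_dim, rel=1e-9)
        expected_mono = (added - free - in_dim) / (0.93 * self.HSA_TOT)
        assert res.gaz_per_hsa_monomer == pytest.approx(expected_mono,
                                                        rel=1e-9)

    def test_uv_gain_invariance(self):
        """Rescaling every UV area by a common gain, with Konv re-derived from
        the rescaled pure injection, leaves all ratios unchanged."""
        added = 1.5 * self.HSA_TOT
        for gain in (1.0, 13.0):
            konv = konv_from_pure_injection(10.0 * gain,
                                            added * 11500.0, 11.5)
            mix = deconv_from_areas(free=2.0 * gain, monomer=5.0 * gain,
                                    dimer=(1.0 + 3.0) * gain)
            pure = deconv_from_areas(monomer=5.0 * gain, dimer=1.0 * gain)
            res = binding_ratios(mix, pure, konv, self.HSA_TOT, 0.93, added)
            if gain == 1.0:
                baseline = res
        assert res.overall_gaz_per_hsa == pytest.approx(
            baseline.overall_gaz_per_hsa, rel=1e-12)
        assert res.gaz_per_hsa_dimer == pytest.approx(
            baseline.gaz_per_hsa_dimer, rel=1e-12)

    def test_excess_dimer_subtraction_clipped(self):
        mix = deconv_from_areas(free=0.0, monomer=5.0, dimer=0.5)
        pure = deconv_from_areas(monomer=5.0, dimer=1.0)
        with pytest.warns(UserWarning):
            res = binding_ratios(mix, pure, 1e-6, self.HSA_TOT, 0.93,
                                 0.1 * self.HSA_TOT)
        assert res.clipped
        assert res.gaz_per_hsa_dimer == 0.0

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @settings(deadline=None, max_examples=50)
    @given(free=st.floats(0.0, 5.0), in_dim=st.floats(0.0, 5.0),
           added_extra=st.floats(0.0, 5.0))
    def test_mass_balance_property(self, free, in_dim, added_extra):
        """free + bound(dimer) + bound(monomer) = added, exactly."""
        konv = 1e-6
        added = (free + in_dim + added_extra) * konv
        mix = deconv_from_areas(free=free, monomer=5.0, dimer=1.0 + in_dim)
        pure = deconv_from_areas(monomer=5.0, dimer=1.0)
        res = binding_ratios(mix, pure, konv, self.HSA_TOT, 0.93, added)
        lhs = res.c_gaz_free + res.c_gaz_in_dimer \
            + res.gaz_per_hsa_monomer * res.c_hsa_monomer
        assert lhs == pytest.approx(added, rel=1e-9, abs=1e-18)


class TestMixingMolarRatio:
    def test_lowest_titration_point(self):
        assert mixing_molar_ratio(0.01, 2.0) == pytest.approx(0.029, abs=2e-3)

    def test_equal_mass_equal_mw(self):
        assert mixing_molar_ratio(2.0, 2.0, 50.0, 50.0) == pytest.approx(1.0)

    def test_highest_titration_point_nominal_mws(self):
        # nominal 66.5/11.5 gives 5.78 (the published series prints 5.66)
        assert mixing_molar_ratio(2.0, 2.0) == pytest.approx(5.783, abs=5e-3)

    def test_zero_hsa_rejected(self):
        with pytest.raises(ValueError):
            mixing_molar_ratio(1.0, 0.0)


def test_isotherm_monotone_in_added_ligand(calibrated_geometry, flows):
    """With fixed Kd the recovered overall bound ratio never decreases as
    more ligand is added."""
    from af4saxs.synthetic_data import (FractogramSimSpec,
                                        simulate_titration_series)
    spec = FractogramSimSpec(species_mix=[], geometry=calibrated_geometry,
                             flows=flows, noise_relative=0.0, seed=2)
    pts = simulate_titration_series(2.0, [0.1, 0.3, 0.5, 1.0, 2.0],
                                    kd_mol_l=1e-6, gaz_dimer_fraction=0.3,
                                    spec=spec)
    trues = [p.overall_ratio_true for p in pts]
    assert all(b >= a - 1e-12 for a, b in zip(trues, trues[1:]))
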