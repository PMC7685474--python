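"""Binding stoichiometry from deconvoluted UV fractograms.

A mixture fractogram of an albumin-binding fusion protein (GA-Z) titrated
into human serum albumin (HSA) is decomposed into three elution regions:
free GA-Z, the HSA-monomer complex and the HSA-dimer complex.  Peak areas,
converted to molar concentrations through a conversion factor Konv obtained
from a pure GA-Z injection, give the bound ratios:

    per dimer   = (AUC_dimer(mix) - AUC_dimer(pure HSA)) * Konv / C(dimer)
    free / HSA  =  AUC_free(mix) * Konv / C(HSA_tot)
    per monomer = (C_added - C_free - C_in_dimer) / C(monomer)

with the working assumption that binding does not shift the HSA
monomer-dimer ratio, so the monomer/dimer concentrations in the mixture are
those measured on pure HSA.  The per-monomer ratio is defined by mass
balance, which therefore holds exactly.  C(dimer) counts dimer particles
(half the molar HSA content in dimers), so "per dimer" counts ligands per
dimer particle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Species",
    "GaussianPeak",
    "DeconvolutionResult",
    "BindingResult",
    "DEFAULT_WINDOWS",
    "HSA_MONOMER", "HSA_DIMER", "GAZ_MONOMER", "GAZ_DIMER",
    "fit_baseline_and_deconvolve",
    "area_under_peak",
    "monomer_dimer_content",
    "konv_from_pure_injection",
    "binding_ratios",
    "mixing_molar_ratio",
]

# elution windows (min): free ligand, HSA monomer region, HSA dimer region
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "free_gaz": (3.0, 5.0),
    "monomer": (3.8, 5.6),
    "dimer": (5.8, 7.5),
}


@dataclass(frozen=True)
class Species:
    """A molecular component as seen by the detectors."""

    name: str
    molar_mass_kda: float
    hydrodynamic_radius_nm: float
    dn_dc_ml_g: float = 0.185
    extinction_280: float = 1.0      # AU mL / (mg cm)
    stock_concentration_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.molar_mass_kda <= 0:
            raise ValueError("molar mass must be positive")
        if self.extinction_280 < 0:
            raise ValueError("extinction coefficient must be non-negative")


# Nominal species used throughout: 66.5 kDa HSA (Rh 3.3 nm) with a 7% dimer
# population (133 kDa, Rh 4.8 nm); 11.5 kDa GA-Z (Rh ~2.8 nm) in fast
# monomer-dimer exchange with its 23 kDa dimer.
HSA_MONOMER = Species("HSA monomer", 66.5, 3.3, dn_dc_ml_g=0.185,
                      extinction_280=0.531)
HSA_DIMER = Species("HSA dimer", 133.0, 4.8, dn_dc_ml_g=0.185,
                    extinction_280=0.531)
GAZ_MONOMER = Species("GA-Z monomer", 11.5, 2.8, dn_dc_ml_g=0.196,
                      extinction_280=0.32)
GAZ_DIMER = Species("GA-Z dimer", 23.0, 2.8, dn_dc_ml_g=0.196,
                    extinction_280=0.32)


@dataclass(frozen=True)
class GaussianPeak:
    center_min: float
    sigma_min: float
    amplitude: float
    label: str = ""

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma_min * math.sqrt(2.0 * math.pi)


@dataclass
class DeconvolutionResult:
    peaks: list[GaussianPeak]
    residual_rms: float
    baseline: tuple[float, float]     # intercept, slope
    empty: bool = False

    def area(self, label: str) -> float:
        return sum(p.area for p in self.peaks if p.label == label)


@dataclass
class BindingResult:
    gaz_per_hsa_dimer: float
    free_gaz_per_hsa_tot: float
    gaz_per_hsa_monomer: float | None
    overall_gaz_per_hsa: float
    c_hsa_monomer: float
    c_hsa_dimer: float
    c_hsa_tot: float
    c_gaz_added: float
    c_gaz_free: float
    c_gaz_in_dimer: float
    clipped: bool = False


def _gaussians_plus_baseline(t, *params):
    n = (len(params) - 2) // 3
    out = params[-2] + params[-1] * t
    for k in range(n):
        a, mu, sig = params[3 * k:3 * k + 3]
        out = out + a * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def fit_baseline_and_deconvolve(time_min: np.ndarray,
                                signal: np.ndarray,
                                init_windows: list[tuple[float, float]],
                                labels: list[str] | None = None,
                                ) -> DeconvolutionResult:
    """Fit a linear baseline plus one Gaussian per window.

    Initial centers/amplitudes come from the window maxima; centers are bounded
    to their windows and sigmas to (0, window width].  Windows must be
    disjoint.  A flat zero signal returns zero-area peaks flagged ``empty``.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    n_comp = len(init_windows)
    if labels is None:
        labels = [f"peak{k}" for k in range(n_comp)]
    if len(labels) != n_comp:
        raise ValueError("one label per window required")
    for (a0, b0), (a1, b1) in zip(sorted(init_windows), sorted(init_windows)[1:]):
        if b0 > a1:
            raise ValueError("init windows must be disjoint")
    if t.size < 10 * (3 * n_comp + 2):
        raise ValueError("signal too short for the requested number of components")

    peak_scale = float(np.max(np.abs(y)))
    if peak_scale == 0.0:
        peaks = [GaussianPeak((w[0] + w[1]) / 2, (w[1] - w[0]) / 4, 0.0, lab)
                 for w, lab in zip(init_windows, labels)]
        return DeconvolutionResult(peaks, 0.0, (0.0, 0.0), empty=True)

    p0, lo, hi = [], [], []
    for (w0, w1) in init_windows:
        m = (t >= w0) & (t <= w1)
        if not np.any(m):
            raise ValueError(f"window ({w0}, {w1}) outside the time grid")
        i = np.argmax(y[m])
        width = w1 - w0
        p0 += [max(float(y[m][i]), 1e-12 * peak_scale),
               float(t[m][i]), width / 6.0]
        lo += [0.0, w0, 1e-4 * width]
        hi += [np.inf, w1, width]
    p0 += [0.0, 0.0]
    lo += [-np.inf, -np.inf]
    hi += [np.inf, np.inf]

    try:
        popt, _ = curve_fit(_gaussians_plus_baseline, t, y, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"deconvolution did not converge: {exc}") from exc

    resid = y - _gaussians_plus_baseline(t, *popt)
    peaks = [GaussianPeak(center_min=float(popt[3 * k + 1]),
                          sigma_min=float(popt[3 * k + 2]),
                          amplitude=float(popt[3 * k]),
                          label=labels[k])
             for k in range(n_comp)]
    peaks.sort(key=lambda p: p.center_min)
    return DeconvolutionResult(peaks=peaks,
                               residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                               baseline=(float(popt[-2]), float(popt[-1])))


def area_under_peak(time_min: np.ndarray, signal: np.ndarray,
                    window: tuple[float, float],
                    baseline: tuple[float, float] = (0.0, 0.0)) -> float:
    """Trapezoidal area of the baseline-subtracted signal over a time window."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    m = (t >= window[0]) & (t <= window[1])
    if np.count_nonzero(m) < 2:
        warnings.warn(f"window {window} contains <2 samples; area 0", stacklevel=2)
        return 0.0
    yb = y[m] - (baseline[0] + baseline[1] * t[m])
    return float(np.trapezoid(yb, t[m]))


def monomer_dimer_content(time_min: np.ndarray, uv_signal: np.ndarray,
                          monomer_window: tuple[float, float],
                          dimer_window: tuple[float, float],
                          baseline: tuple[float, float] = (0.0, 0.0),
                          ) -> tuple[float, float]:
    """Monomer/dimer mass fractions of a pure-protein fractogram from UV areas."""
    a_mono = area_under_peak(time_min, uv_signal, monomer_window, baseline)
    a_dim = area_under_peak(time_min, uv_signal, dimer_window, baseline)
    total = a_mono + a_dim
    if total <= 0:
        raise ValueError("total UV area is zero; cannot form content fractions")
    return a_mono / total, a_dim / total


def konv_from_pure_injection(pure_area: float,
                             injected_concentration_mg_ml: float,
                             molar_mass_kda: float) -> float:
    """Area-to-concentration conversion factor Konv, (mol/L) per (signal*min).

    Defined from a pure injection of known concentration: the molar
    concentration of the injected sample divided by its total UV area, under
    the assumption of a linear UV response.  Injections being compared must
    use the same injected volume.
    """
    if pure_area <= 0:
        raise ValueError("pure-injection area must be positive")
    # mg/mL == g/L, so c / (MW in g/mol) is mol/L
    molar = injected_concentration_mg_ml / (molar_mass_kda * 1000.0)
    return molar / pure_area


def binding_ratios(mixture_deconv: DeconvolutionResult,
                   pure_hsa_deconv: DeconvolutionResult,
                   konv: float,
                   hsa_total_mol_l: float,
                   monomer_fraction: float,
                   gaz_added_mol_l: float,
                   noise_tolerance: float = 0.0) -> BindingResult:
    """Bound ratios for one titration point.

    ``mixture_deconv``/``pure_hsa_deconv`` must carry peaks labelled
    ``free_gaz``/``monomer``/``dimer``; the free-ligand and dimer areas of the
    mixture, after subtracting the pure-HSA dimer area, are converted with
    ``konv`` and divided by the relevant HSA pools.  Negative subtraction
    results within ``2 * noise_tolerance`` are clipped to zero; larger
    negatives raise a data-inconsistency warning (and are still clipped).
    """
    if not 0.0 <= monomer_fraction <= 1.0:
        raise ValueError("monomer fraction must lie in [0, 1]")
    if hsa_total_mol_l <= 0:
        raise ValueError("total HSA concentration must be positive")

    c_mono = monomer_fraction * hsa_total_mol_l
    c_dim = (1.0 - monomer_fraction) * hsa_total_mol_l / 2.0   # dimer particles

    auc_dimer_mix = mixture_deconv.area("dimer")
    auc_dimer_hsa = pure_hsa_deconv.area("dimer")
    auc_free = mixture_deconv.area("free_gaz")

    clipped = False

    c_in_dimer = (auc_dimer_mix - auc_dimer_hsa) * konv
    if c_in_dimer < 0:
        if c_in_dimer < -2.0 * noise_tolerance:
            warnings.warn("dimer-region area of mixture below pure HSA by more "
                          "than noise allows; clipping to zero", stacklevel=2)
        c_in_dimer = 0.0
        clipped = True

    c_free = auc_free * konv
    if c_free < 0:
        c_free = 0.0
        clipped = True
    c_free = min(c_free, gaz_added_mol_l) if gaz_added_mol_l >= 0 else c_free

    per_dimer = c_in_dimer / c_dim if c_dim > 0 else 0.0
    free_per_tot = c_free / hsa_total_mol_l

    c_in_monomer = gaz_added_mol_l - c_free - c_in_dimer
    if c_in_monomer < 0:
        if c_in_monomer < -2.0 * noise_tolerance:
            warnings.warn("negative monomer-bound concentration beyond noise; "
                          "clipping to zero", stacklevel=2)
        c_in_monomer = 0.0
        clipped = True
        # keep the mass balance exact by assigning the deficit to free ligand
        c_free = max(gaz_added_mol_l - c_in_dimer, 0.0)
        free_per_tot = c_free / hsa_total_mol_l

    per_monomer = c_in_monomer / c_mono if c_mono > 0 else None
    overall = (gaz_added_mol_l - c_free) / hsa_total_mol_l

    return BindingResult(
        gaz_per_hsa_dimer=per_dimer,
        free_gaz_per_hsa_tot=free_per_tot,
        gaz_per_hsa_monomer=per_monomer,
        overall_gaz_per_hsa=overall,
        c_hsa_monomer=c_mono,
        c_hsa_dimer=c_dim,
        c_hsa_tot=hsa_total_mol_l,
        c_gaz_added=gaz_added_mol_l,
        c_gaz_free=c_free,
        c_gaz_in_dimer=c_in_dimer,
        clipped=clipped,
    )


def mixing_molar_ratio(gaz_stock_mg_ml: float,
                       hsa_stock_mg_ml: float,
                       gaz_molar_mass_kda: float = 11.5,
                       hsa_molar_mass_kda: float = 66.5,
                       mix_ratio_v_v: float = 1.0) -> float:
    """Molar ratio ligand:albumin after volumetric mixing of two stocks.

    For 1:1 (v/v) mixing the volumes cancel and the ratio is simply
    (c_gaz/MW_gaz)/(c_hsa/MW_hsa).
    """
    if hsa_stock_mg_ml <= 0:
        raise ValueError("HSA stock concentration must be positive")
    if gaz_stock_mg_ml < 0 or mix_ratio_v_v <= 0:
        raise ValueError("non-physical mixing inputs")
    gaz_molar = gaz_stock_mg_ml / gaz_molar_mass_kda * mix_ratio_v_v
    hsa_molar = hsa_stock_mg_ml / hsa_molar_mass_kda
    return gaz_molar / hsa_molar
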