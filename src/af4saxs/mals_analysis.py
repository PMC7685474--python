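"""Multi-angle light scattering: molar mass and size by the Berry formalism.

Per elution slice the excess Rayleigh ratio R_theta at a set of detector
angles, together with the dRI-derived concentration, yields the weight-average
molar mass through

    sqrt(K* c / R_theta) ~ (1/sqrt(M)) * (1 + q^2 Rg^2 / 6),

the square-root (Berry) linearisation of the Zimm relation, fitted as a
polynomial of degree 1 or 2 in sin^2(theta/2).  Angle-subset fits (the low- vs
high-angle split) serve as a co-elution diagnostic: for an ideal dilute
monodisperse scatterer with Rg << 1/q they must agree, so a systematic
disagreement flags mixed or noisy slices.  The second virial coefficient is
taken as zero (dilute regime) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fff_retention import SolventConditions

__all__ = [
    "DEFAULT_ANGLES_DEG",
    "LOW_ANGLE_MAX_DEG",
    "HIGH_ANGLE_MIN_DEG",
    "SliceScattering",
    "OpticalConstants",
    "BerryFit",
    "PeakMassProfile",
    "LowSignalError",
    "k_star",
    "scattering_vector",
    "berry_fit",
    "peak_mass_profile",
    "dn_dc_from_batch",
]

AVOGADRO = 6.02214076e23

# 14-angle HELEOS-like detector set, 32-147 degrees.  The low/high split at
# 81/90 degrees gives 6 low-angle and 8 high-angle detectors.
DEFAULT_ANGLES_DEG: tuple[float, ...] = (
    32.0, 41.0, 50.0, 60.0, 70.0, 81.0,
    90.0, 99.0, 108.0, 117.0, 126.0, 134.0, 141.0, 147.0)
LOW_ANGLE_MAX_DEG = 81.0
HIGH_ANGLE_MIN_DEG = 90.0


class LowSignalError(ValueError):
    """Concentration too low for a meaningful fit ('n.d.' in reports)."""


@dataclass(frozen=True)
class OpticalConstants:
    """dn/dc and the derived MALS optical constant K*.

    K* = 4 pi^2 n0^2 (dn/dc)^2 / (N_A lambda0^4) with the vacuum wavelength,
    in units such that R_theta/(K* c) is g/mol for c in g/mL and R_theta in
    1/cm.
    """

    dn_dc_ml_g: float
    k_star: float

    @classmethod
    def from_solvent(cls, solvent: SolventConditions,
                     dn_dc_ml_g: float) -> "OpticalConstants":
        return cls(dn_dc_ml_g=dn_dc_ml_g,
                   k_star=k_star(solvent, dn_dc_ml_g))


def k_star(solvent: SolventConditions, dn_dc_ml_g: float) -> float:
    """MALS optical constant K* in mol cm^2 / g^2."""
    if dn_dc_ml_g <= 0:
        raise ValueError("dn/dc must be positive")
    lambda_cm = solvent.laser_wavelength_nm * 1e-7
    n0 = solvent.refractive_index
    return 4.0 * math.pi ** 2 * n0 ** 2 * dn_dc_ml_g ** 2 \
        / (AVOGADRO * lambda_cm ** 4)


def scattering_vector(angles_deg: np.ndarray,
                      solvent: SolventConditions) -> np.ndarray:
    """Light-scattering momentum transfer q = 4 pi n0 sin(theta/2)/lambda0, 1/nm."""
    half = np.deg2rad(np.asarray(angles_deg, dtype=float)) / 2.0
    return 4.0 * math.pi * solvent.refractive_index * np.sin(half) \
        / solvent.laser_wavelength_nm


@dataclass(frozen=True)
class SliceScattering:
    """One elution slice: concentration plus per-angle excess Rayleigh ratios."""

    concentration_g_ml: float
    rayleigh_ratio: np.ndarray       # 1/cm, one per angle
    angles_deg: np.ndarray
    noise_sd: np.ndarray | None = None   # per-detector baseline SD, 1/cm

    def __post_init__(self) -> None:
        object.__setattr__(self, "rayleigh_ratio",
                           np.asarray(self.rayleigh_ratio, dtype=float))
        object.__setattr__(self, "angles_deg",
                           np.asarray(self.angles_deg, dtype=float))
        if self.noise_sd is not None:
            object.__setattr__(self, "noise_sd",
                               np.asarray(self.noise_sd, dtype=float))
        if self.concentration_g_ml < 0:
            raise ValueError("concentration must be non-negative")
        if self.rayleigh_ratio.shape != self.angles_deg.shape:
            raise ValueError("rayleigh_ratio and angles must have equal length")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.rayleigh_ratio)):
            raise ValueError("rayleigh_ratio must be finite")


@dataclass(frozen=True)
class BerryFit:
    molar_mass_kda: float
    radius_gyration_nm: float | None
    fit_order: int
    angle_subset: str
    subset_indices: tuple[int, ...]
    mass_uncertainty_kda: float
    intercept: float
    slope: float


def _subset_indices(angles: np.ndarray, subset: str) -> np.ndarray:
    if subset == "all":
        return np.arange(angles.size)
    if subset == "low":
        return np.flatnonzero(angles <= LOW_ANGLE_MAX_DEG)
    if subset == "high":
        return np.flatnonzero(angles >= HIGH_ANGLE_MIN_DEG)
    raise ValueError(f"unknown angle subset {subset!r}")


def berry_fit(slice_: SliceScattering,
              optical: OpticalConstants,
              solvent: SolventConditions,
              order: int = 1,
              angle_subset: str = "all",
              concentration_threshold_g_ml: float = 0.0) -> BerryFit:
    """Weighted Berry fit of one slice.

    Fits sqrt(K* c / R_theta) as a degree-``order`` polynomial in
    sin^2(theta/2); the intercept gives 1/sqrt(M) and the slope gives Rg.
    Weights are propagated from per-detector baseline SDs when available.
    """
    if order not in (1, 2):
        raise ValueError("fit order must be 1 or 2")
    if slice_.concentration_g_ml <= concentration_threshold_g_ml:
        raise LowSignalError("concentration below detection threshold (n.d.)")
    idx = _subset_indices(slice_.angles_deg, angle_subset)
    if idx.size < order + 2:
        raise ValueError(f"need at least {order + 2} angles for an order-{order} fit")

    angles = slice_.angles_deg[idx]
    r_theta = slice_.rayleigh_ratio[idx]
    if np.any(r_theta <= 0):
        raise LowSignalError("non-positive Rayleigh ratio in fit subset")

    c = slice_.concentration_g_ml
    y = np.sqrt(optical.k_star * c / r_theta)
    x = np.sin(np.deg2rad(angles) / 2.0) ** 2

    if slice_.noise_sd is not None:
        sd_r = slice_.noise_sd[idx]
        sigma_y = np.where(sd_r > 0, y / (2.0 * r_theta) * sd_r, np.inf)
        if not np.any(np.isfinite(sigma_y)):
            sigma_y = np.ones_like(y)
        else:
            sigma_y = np.where(np.isfinite(sigma_y), sigma_y,
                               np.nanmax(sigma_y[np.isfinite(sigma_y)]))
        weights = 1.0 / sigma_y
    else:
        weights = np.ones_like(y)

    # weighted polynomial LSQ in Berry coordinates
    design = np.vander(x, order + 1, increasing=True)
    wa = design * weights[:, None]
    wy = y * weights
    coef, _, _, _ = np.linalg.lstsq(wa, wy, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if intercept <= 0:
        raise RuntimeError("Berry fit failed: non-positive intercept")

    molar_mass_g_mol = 1.0 / intercept ** 2

    # covariance of coefficients for the mass uncertainty
    dof = max(idx.size - (order + 1), 1)
    resid = wy - wa @ coef
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(wa.T @ wa) * s2
        sd_intercept = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        sd_intercept = float("nan")
    # M = a0^-2  =>  sd_M = 2 M / a0 * sd_a0
    sd_mass_g_mol = 2.0 * molar_mass_g_mol / intercept * sd_intercept

    # Rg from the slope: y ~ a0 (1 + q^2 Rg^2/6), q^2 = (4 pi n0/lambda)^2 x
    q_unit = (4.0 * math.pi * solvent.refractive_index
              / solvent.laser_wavelength_nm) ** 2  # q^2 per unit x, 1/nm^2
    rg_nm: float | None = None
    if slope > 0:
        rg2 = 6.0 * slope / (intercept * q_unit)
        if rg2 > 0:
            rg_nm = math.sqrt(rg2)

    return BerryFit(
        molar_mass_kda=molar_mass_g_mol / 1000.0,
        radius_gyration_nm=rg_nm,
        fit_order=order,
        angle_subset=angle_subset,
        subset_indices=tuple(int(i) for i in idx),
        mass_uncertainty_kda=sd_mass_g_mol / 1000.0,
        intercept=intercept,
        slope=slope,
    )


@dataclass
class PeakMassProfile:
    """Per-slice Berry masses over a peak window plus the weight average."""

    times_min: np.ndarray
    molar_mass_kda: np.ndarray           # NaN where low-signal
    concentrations_g_ml: np.ndarray
    weight_average_kda: float | None     # None => 'n.d.'
    n_slices: int = 0
    determined: bool = True

    def __post_init__(self) -> None:
        self.n_slices = int(np.sum(np.isfinite(self.molar_mass_kda)))
        self.determined = self.weight_average_kda is not None


def peak_mass_profile(fractogram,
                      peak_window: tuple[float, float],
                      optical: OpticalConstants,
                      solvent: SolventConditions,
                      order: int = 1,
                      angle_subset: str = "all",
                      signal_to_noise: float = 5.0) -> PeakMassProfile:
    """Slice-wise Berry masses across an elution window.

    Baseline noise per detector is estimated from the first and last 10% of
    the run (the quieter end), slices whose dRI-derived concentration falls
    below ``signal_to_noise`` times the baseline SD are excluded, and the
    weight-average mass sum(c M)/sum(c) is computed over the kept slices.
    ``fractogram`` is a :class:`af4saxs.workbench_io.Fractogram`.
    """
    t = fractogram.time_min
    lo, hi = peak_window
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError(f"empty peak window {peak_window}")

    dri = fractogram.dri_riu
    ls = fractogram.ls_matrix          # (n_times, n_angles)
    angles = fractogram.ls_angles_deg
    if ls is None or dri is None:
        raise ValueError("fractogram must carry dRI and LS signals")

    n = t.size
    edge = max(int(0.1 * n), 3)
    def _edge_sd(y: np.ndarray) -> float:
        return float(min(np.std(y[:edge]), np.std(y[-edge:])))
    dri_sd = _edge_sd(dri)
    ls_sd = np.array([_edge_sd(ls[:, j]) for j in range(ls.shape[1])])

    conc = dri / optical.dn_dc_ml_g          # g/mL
    conc_floor = signal_to_noise * dri_sd / optical.dn_dc_ml_g

    times, masses, concs = [], [], []
    for i in np.flatnonzero(mask):
        c_i = conc[i]
        if c_i <= conc_floor or c_i <= 0:
            times.append(t[i]); masses.append(np.nan); concs.append(max(c_i, 0.0))
            continue
        sl = SliceScattering(concentration_g_ml=c_i,
                             rayleigh_ratio=np.clip(ls[i], 1e-30, None),
                             angles_deg=angles,
                             noise_sd=ls_sd if np.any(ls_sd > 0) else None)
        try:
            fit = berry_fit(sl, optical, solvent, order=order,
                            angle_subset=angle_subset)
            masses.append(fit.molar_mass_kda)
        except (LowSignalError, RuntimeError):
            masses.append(np.nan)
        times.append(t[i]); concs.append(c_i)

    times = np.asarray(times); masses = np.asarray(masses); concs = np.asarray(concs)
    ok = np.isfinite(masses)
    if not np.any(ok):
        return PeakMassProfile(times, masses, concs, weight_average_kda=None)
    w_avg = float(np.sum(concs[ok] * masses[ok]) / np.sum(concs[ok]))
    return PeakMassProfile(times, masses, concs, weight_average_kda=w_avg)


def dn_dc_from_batch(concentrations_g_ml: np.ndarray,
                     dri_signals_riu: np.ndarray) -> tuple[float, float, float]:
    """Batch-mode dn/dc: OLS slope of delta-n versus concentration.

    Returns ``(dn_dc_ml_g, standard_error, intercept)``.  The intercept should
    be close to zero for a well-zeroed detector; a zero slope is returned
    as-is (non-physical, caller should flag).
    """
    c = np.asarray(concentrations_g_ml, dtype=float)
    dn = np.asarray(dri_signals_riu, dtype=float)
    if c.size != dn.size:
        raise ValueError("concentration and signal arrays must match")
    if np.unique(c).size < 2:
        raise ValueError("need at least two distinct concentration levels")
    design = np.column_stack([np.ones_like(c), c])
    coef, _, _, _ = np.linalg.lstsq(design, dn, rcond=None)
    resid = dn - design @ coef
    dof = max(c.size - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = np.linalg.inv(design.T @ design) * s2
    slope_se = math.sqrt(max(cov[1, 1], 0.0))
    return float(coef[1]), slope_se, float(coef[0])
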