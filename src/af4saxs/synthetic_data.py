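"""Synthetic fractograms and SAXS curves with known ground truth.

The generator stands in for the AF4-UV-MALS-dRI instrument train and the
SAXS beamline: every analysis stage in this package is exercised closed-loop
against data whose true radii, masses, contents and binding ratios are known.

Fractograms: each species elutes as a Gaussian band centred at the retention
time predicted by the channel model (sigma = t_r / sqrt(plate_number)), and
the detectors respond linearly -- UV_280 = sum(c_i eps_i), dRI = sum(c_i
(dn/dc)_i), LS R_theta = K*_i c_i M_i P_i(theta).  Fast monomer-dimer
exchange produces a single skew-normal band at the population-averaged
position whose apparent mass is the weight average.  Titrations solve a
single-site equilibrium per point, with dimeric ligand contributing two
ligand masses per occupied site.

SAXS: analytic sphere / ellipsoid / two-sphere-dumbbell form factors with
Gaussian noise sigma(q) = rel * I(q) + floor.  All outputs are deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skewnorm

from .binding_stoichiometry import (GAZ_DIMER, GAZ_MONOMER, HSA_DIMER,
                                    HSA_MONOMER, Species)
from .fff_retention import (ChannelGeometry, FlowConditions, SolventConditions,
                            calibrate_thickness, time_from_radius)
from .mals_analysis import DEFAULT_ANGLES_DEG, k_star, scattering_vector
from .workbench_io import Fractogram

__all__ = [
    "FractogramSimSpec",
    "SAXSSimSpec",
    "TitrationPoint",
    "complex_radius",
    "default_calibrated_geometry",
    "simulate_fractogram",
    "simulate_fast_exchange_peak",
    "simulate_titration_series",
    "dimer_fraction_for_plateau",
    "sphere_intensity",
    "ellipsoid_intensity",
    "dumbbell_intensity",
    "simulate_saxs_curve",
]

# ratio Rg/Rh used for the (tiny) angular dependence of the LS response
_RG_OVER_RH = 0.775


def complex_radius(radii_nm: list[float]) -> float:
    """Hydrodynamic radius of a complex by hydrodynamic volume additivity."""
    return float(sum(r ** 3 for r in radii_nm) ** (1.0 / 3.0))


def default_calibrated_geometry(flows: FlowConditions | None = None,
                                solvent: SolventConditions | None = None,
                                ) -> ChannelGeometry:
    """Nominal channel calibrated so HSA monomer (3.3 nm) elutes at 4.5 min."""
    flows = flows or FlowConditions()
    solvent = solvent or SolventConditions()
    return calibrate_thickness(HSA_MONOMER.hydrodynamic_radius_nm, 4.5,
                               ChannelGeometry(), flows, solvent)


@dataclass
class FractogramSimSpec:
    """Conditions of one simulated AF4 run.

    ``species_mix`` is a list of (species, injected concentration mg/mL)
    pairs; the injected volume converts concentration into eluted mass.
    ``noise_relative`` is the additive Gaussian noise SD per detector as a
    fraction of that detector's peak signal.
    """

    species_mix: list[tuple[Species, float]]
    geometry: ChannelGeometry
    flows: FlowConditions = field(default_factory=FlowConditions)
    solvent: SolventConditions = field(default_factory=SolventConditions)
    plate_number: float = 2500.0
    sampling_dt_min: float = 0.01
    injection_volume_ml: float = 0.075
    noise_relative: float = 0.005
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_number <= 0:
            raise ValueError("plate number must be positive")
        if any(c < 0 for _, c in self.species_mix):
            raise ValueError("concentrations must be non-negative")


def _band_profile(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian band, 1/min."""
    return np.exp(-0.5 * ((t - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def _detector_responses(spec: FractogramSimSpec,
                        contributions: list[tuple[Species, float, np.ndarray]],
                        ) -> Fractogram:
    """Assemble UV/dRI/LS signals from (species, mass mg, unit-area profile)."""
    t = np.arange(0.0, spec.flows.elution_duration_min + spec.sampling_dt_min / 2,
                  spec.sampling_dt_min)
    n_ang = len(spec.angles_deg)
    uv = np.zeros_like(t)
    dri = np.zeros_like(t)
    ls = np.zeros((t.size, n_ang))
    q = scattering_vector(np.asarray(spec.angles_deg), spec.solvent)  # 1/nm

    for sp, mass_mg, profile in contributions:
        # c(t) in mg/mL such that integral(c F dt) = eluted mass
        c_mg_ml = mass_mg / spec.flows.detector_flow_ml_min * profile
        c_g_ml = c_mg_ml * 1e-3
        uv += c_mg_ml * sp.extinction_280
        dri += c_g_ml * sp.dn_dc_ml_g
        ks = k_star(spec.solvent, sp.dn_dc_ml_g)
        rg = _RG_OVER_RH * sp.hydrodynamic_radius_nm
        p_theta = np.clip(1.0 - (q * rg) ** 2 / 3.0, 0.0, None)
        ls += np.outer(c_g_ml, ks * sp.molar_mass_kda * 1000.0 * p_theta)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_relative > 0:
        for arr in (uv, dri):
            peak = float(np.max(np.abs(arr)))
            arr += rng.normal(0.0, spec.noise_relative * peak, arr.shape) \
                if peak > 0 else 0.0
        peak = float(np.max(np.abs(ls)))
        if peak > 0:
            ls += rng.normal(0.0, spec.noise_relative * peak, ls.shape)

    return Fractogram.from_arrays(t, uv_au=uv, dri_riu=dri, ls_matrix=ls,
                                  ls_angles_deg=np.asarray(spec.angles_deg))


def simulate_fractogram(spec: FractogramSimSpec) -> Fractogram:
    """Simulate one AF4 run: Gaussian band per species, linear detectors."""
    contributions = []
    for sp, conc in spec.species_mix:
        if conc == 0:
            continue
        t_r = time_from_radius(sp.hydrodynamic_radius_nm, spec.geometry,
                               spec.flows, spec.solvent)
        if t_r > spec.flows.elution_duration_min:
            import warnings
            warnings.warn(f"{sp.name}: retention time {t_r:.1f} min beyond the "
                          "elution window; band truncated", stacklevel=2)
        sigma = t_r / math.sqrt(spec.plate_number)
        t = np.arange(0.0, spec.flows.elution_duration_min
                      + spec.sampling_dt_min / 2, spec.sampling_dt_min)
        profile = _band_profile(t, t_r, sigma)
        mass_mg = conc * spec.injection_volume_ml
        contributions.append((sp, mass_mg, profile))
    return _detector_responses(spec, contributions)


def simulate_fast_exchange_peak(monomer: Species, dimer: Species,
                                fraction_dimer: float,
                                concentration_mg_ml: float,
                                spec: FractogramSimSpec) -> Fractogram:
    """Single co-eluting band for species in fast monomer-dimer exchange.

    The band sits at the mass-fraction-weighted retention position with a
    skew-normal shape (skew vanishes for pure populations) and scatters with
    the weight-average molar mass, so the apparent slice mass is flat across
    the peak -- the experimental fast-exchange diagnostic.
    """
    if not 0.0 <= fraction_dimer <= 1.0:
        raise ValueError("fraction_dimer must lie in [0, 1]")
    f = fraction_dimer
    t_m = time_from_radius(monomer.hydrodynamic_radius_nm, spec.geometry,
                           spec.flows, spec.solvent)
    t_d = time_from_radius(dimer.hydrodynamic_radius_nm, spec.geometry,
                           spec.flows, spec.solvent)
    center = (1.0 - f) * t_m + f * t_d
    sigma = center / math.sqrt(spec.plate_number)
    skew = 4.0 * f * (1.0 - f) * math.copysign(1.0, t_d - t_m)

    t = np.arange(0.0, spec.flows.elution_duration_min + spec.sampling_dt_min / 2,
                  spec.sampling_dt_min)
    profile = skewnorm.pdf(t, skew, loc=center, scale=sigma)

    mw_avg = (1.0 - f) * monomer.molar_mass_kda + f * dimer.molar_mass_kda
    rh_avg = (1.0 - f) * monomer.hydrodynamic_radius_nm \
        + f * dimer.hydrodynamic_radius_nm
    pop = Species(name=f"{monomer.name} (fast exchange)",
                  molar_mass_kda=mw_avg, hydrodynamic_radius_nm=rh_avg,
                  dn_dc_ml_g=monomer.dn_dc_ml_g,
                  extinction_280=monomer.extinction_280)
    mass_mg = concentration_mg_ml * spec.injection_volume_ml
    return _detector_responses(spec, [(pop, mass_mg, profile)])


def dimer_fraction_for_plateau(plateau: float) -> float:
    """Molecule-fraction of dimeric ligand giving a saturation ratio ``plateau``.

    With one site per albumin unit and a bound dimer delivering two ligand
    masses, the saturated overall ratio is 1 + g_d where g_d is the dimer
    fraction among binding *entities*; inverting gives the molecule fraction.
    """
    if not 1.0 <= plateau < 2.0:
        raise ValueError("plateau must lie in [1, 2) for a single-site model")
    g_d = plateau - 1.0
    return 2.0 * g_d / (1.0 + g_d)


@dataclass
class TitrationPoint:
    molar_ratio_added: float
    gaz_added_mol_l: float
    gaz_free_mol_l: float
    gaz_in_monomer_mol_l: float
    gaz_in_dimer_mol_l: float
    overall_ratio_true: float
    mixture: Fractogram
    pure_hsa: Fractogram
    pure_gaz: Fractogram | None


def simulate_titration_series(hsa_stock_mg_ml: float,
                              gaz_stock_concentrations_mg_ml: list[float],
                              kd_mol_l: float,
                              gaz_dimer_fraction: float,
                              spec: FractogramSimSpec,
                              hsa_monomer_fraction: float = 0.93,
                              ) -> list[TitrationPoint]:
    """Simulate a 1:1 (v/v) titration of ligand stock into albumin stock.

    Per point the single-site equilibrium (one site per albumin unit, shared
    Kd for monomeric and dimeric ligand entities) is solved, bound ligand is
    distributed over the monomer and dimer pools in proportion to their
    sites, and mixture plus matching pure-reference fractograms are emitted.
    """
    if kd_mol_l <= 0:
        raise ValueError("Kd must be positive")
    f_d = gaz_dimer_fraction
    if not 0.0 <= f_d <= 1.0:
        raise ValueError("dimer fraction must lie in [0, 1]")

    c_hsa = hsa_stock_mg_ml / 2.0                   # after 1:1 mixing, mg/mL
    h_tot = c_hsa / (HSA_MONOMER.molar_mass_kda * 1000.0)  # mol/L albumin units
    f_m = hsa_monomer_fraction
    # entity bookkeeping: a dimer of ligand is one binding entity of 2 masses
    g_d = (f_d / 2.0) / ((1.0 - f_d) + f_d / 2.0) if f_d > 0 else 0.0
    masses_per_entity = 1.0 + g_d

    def hsa_mix(conc_mg_ml: float) -> list[tuple[Species, float]]:
        return [(HSA_MONOMER, f_m * conc_mg_ml),
                (HSA_DIMER, (1.0 - f_m) * conc_mg_ml)]

    points: list[TitrationPoint] = []
    base_seed = spec.seed
    for k, gaz_stock in enumerate(gaz_stock_concentrations_mg_ml):
        c_gaz = gaz_stock / 2.0                     # after mixing, mg/mL
        gaz_molar = c_gaz / (GAZ_MONOMER.molar_mass_kda * 1000.0)
        l_entities = gaz_molar * ((1.0 - f_d) + f_d / 2.0)
        s_tot = h_tot                                # one site per albumin unit

        # free-entity concentration from L + S L/(Kd+L) = L_tot
        b = kd_mol_l + s_tot - l_entities
        l_free = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd_mol_l * l_entities))
        occupied = s_tot * l_free / (kd_mol_l + l_free)

        gaz_free = l_free * masses_per_entity
        gaz_bound = occupied * masses_per_entity
        gaz_in_mono = gaz_bound * f_m
        gaz_in_dim = gaz_bound * (1.0 - f_m)

        occ_frac = occupied / s_tot if s_tot > 0 else 0.0

        # complex species: albumin plus average bound ligand load
        mono_complex = Species(
            "HSA monomer complex",
            molar_mass_kda=HSA_MONOMER.molar_mass_kda,
            hydrodynamic_radius_nm=complex_radius(
                [HSA_MONOMER.hydrodynamic_radius_nm]
                + [GAZ_MONOMER.hydrodynamic_radius_nm * occ_frac ** (1 / 3)]
                if occ_frac > 0 else [HSA_MONOMER.hydrodynamic_radius_nm]),
            dn_dc_ml_g=HSA_MONOMER.dn_dc_ml_g,
            extinction_280=HSA_MONOMER.extinction_280)
        dim_complex = Species(
            "HSA dimer complex",
            molar_mass_kda=HSA_DIMER.molar_mass_kda,
            hydrodynamic_radius_nm=complex_radius(
                [HSA_DIMER.hydrodynamic_radius_nm]
                + [GAZ_MONOMER.hydrodynamic_radius_nm * occ_frac ** (1 / 3)]
                if occ_frac > 0 else [HSA_DIMER.hydrodynamic_radius_nm]),
            dn_dc_ml_g=HSA_DIMER.dn_dc_ml_g,
            extinction_280=HSA_DIMER.extinction_280)
        # bound ligand mass rides on the complex peaks (mg/mL equivalents)
        bound_mono_mg_ml = gaz_in_mono * GAZ_MONOMER.molar_mass_kda * 1000.0
        bound_dim_mg_ml = gaz_in_dim * GAZ_MONOMER.molar_mass_kda * 1000.0
        gaz_on_mono = Species("GA-Z on monomer", GAZ_MONOMER.molar_mass_kda,
                              mono_complex.hydrodynamic_radius_nm,
                              GAZ_MONOMER.dn_dc_ml_g, GAZ_MONOMER.extinction_280)
        gaz_on_dim = Species("GA-Z on dimer", GAZ_MONOMER.molar_mass_kda,
                             dim_complex.hydrodynamic_radius_nm,
                             GAZ_MONOMER.dn_dc_ml_g, GAZ_MONOMER.extinction_280)
        free_gaz_mg_ml = gaz_free * GAZ_MONOMER.molar_mass_kda * 1000.0

        from dataclasses import replace as _replace
        mix_spec = _replace(spec, seed=base_seed + 3 * k,
                            species_mix=[
                                (GAZ_MONOMER, free_gaz_mg_ml),
                                (mono_complex, f_m * c_hsa),
                                (gaz_on_mono, bound_mono_mg_ml),
                                (dim_complex, (1.0 - f_m) * c_hsa),
                                (gaz_on_dim, bound_dim_mg_ml),
                            ])
        hsa_spec = _replace(spec, seed=base_seed + 3 * k + 1,
                            species_mix=hsa_mix(c_hsa))
        gaz_spec = _replace(spec, seed=base_seed + 3 * k + 2,
                            species_mix=[(GAZ_MONOMER, c_gaz)])

        points.append(TitrationPoint(
            molar_ratio_added=gaz_molar / h_tot if h_tot > 0 else math.inf,
            gaz_added_mol_l=gaz_molar,
            gaz_free_mol_l=gaz_free,
            gaz_in_monomer_mol_l=gaz_in_mono,
            gaz_in_dimer_mol_l=gaz_in_dim,
            overall_ratio_true=(gaz_molar - gaz_free) / h_tot,
            mixture=simulate_fractogram(mix_spec),
            pure_hsa=simulate_fractogram(hsa_spec),
            pure_gaz=simulate_fractogram(gaz_spec) if c_gaz > 0 else None,
        ))
    return points


# ---------------------------------------------------------------------------
# SAXS curve generation
# ---------------------------------------------------------------------------

def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalised sphere form-factor amplitude 3(sin x - x cos x)/x^3."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return np.where(small, 1.0 - x ** 2 / 10.0, amp)


def sphere_intensity(q: np.ndarray, radius_nm: float) -> np.ndarray:
    """I(q)/I(0) of a homogeneous sphere."""
    return _sphere_amplitude(q * radius_nm) ** 2


def ellipsoid_intensity(q: np.ndarray, semi_axes_nm: tuple[float, float, float],
                        n_quad: int = 64) -> np.ndarray:
    """Orientation-averaged I(q)/I(0) of a homogeneous triaxial ellipsoid."""
    a, b, c = semi_axes_nm
    q = np.asarray(q, dtype=float)
    u, wu = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (u + 1.0)          # cos(beta) in [0, 1]
    wu = 0.5 * wu
    if math.isclose(a, b):
        r_eff = np.sqrt(a * a * (1.0 - u ** 2) + c * c * u ** 2)
        amp2 = _sphere_amplitude(np.outer(q, r_eff)) ** 2
        return amp2 @ wu / np.sum(wu)
    phi, wp = np.polynomial.legendre.leggauss(32)
    phi = 0.25 * math.pi * (phi + 1.0)
    wp = 0.25 * math.pi * wp
    total = np.zeros_like(q)
    for uu, wuu in zip(u, wu):
        r_eff = np.sqrt((a * a * np.cos(phi) ** 2 + b * b * np.sin(phi) ** 2)
                        * (1.0 - uu ** 2) + c * c * uu ** 2)
        amp2 = _sphere_amplitude(np.outer(q, r_eff)) ** 2
        total += wuu * (amp2 @ wp)
    return total / (np.sum(wu) * np.sum(wp))


def dumbbell_intensity(q: np.ndarray, radius_nm: float,
                       separation_nm: float) -> np.ndarray:
    """Two identical coherent spheres at centre separation d (Debye cross term).

    Normalised so a *single* sphere would give I(0) = 1; the dumbbell then has
    I(0) = 4 (coherent addition), collapsing to one doubled-volume coherent
    pair at d = 0.
    """
    q = np.asarray(q, dtype=float)
    amp2 = _sphere_amplitude(q * radius_nm) ** 2
    qd = q * separation_nm
    sinc = np.sinc(qd / math.pi)
    return 2.0 * amp2 * (1.0 + sinc)


@dataclass
class SAXSSimSpec:
    """One simulated SAXS measurement.

    ``i_zero`` scales the normalised single-particle intensity (for the
    dumbbell it is the forward intensity of one constituent sphere).  The
    noise model is sigma(q) = noise_relative * I(q) + noise_floor.
    """

    model: str = "sphere"
    radius_nm: float = 3.0
    semi_axes_nm: tuple[float, float, float] = (4.0, 4.0, 1.5)
    separation_nm: float = 0.0
    components: list[tuple["SAXSSimSpec", float]] | None = None
    i_zero: float = 1.0
    q_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 6.0, 400))
    noise_relative: float = 0.01
    noise_floor: float = 1e-4
    seed: int = 0
    concentration_mg_ml: float | None = None
    label: str = ""


def _model_intensity(spec: SAXSSimSpec, q: np.ndarray) -> np.ndarray:
    if spec.model == "sphere":
        return spec.i_zero * sphere_intensity(q, spec.radius_nm)
    if spec.model == "ellipsoid":
        return spec.i_zero * ellipsoid_intensity(q, spec.semi_axes_nm)
    if spec.model == "dumbbell":
        return spec.i_zero * dumbbell_intensity(q, spec.radius_nm,
                                                spec.separation_nm)
    if spec.model == "mixture":
        if not spec.components:
            raise ValueError("mixture model requires components")
        weights = np.array([w for _, w in spec.components], dtype=float)
        if np.any(weights < 0) or not math.isclose(float(weights.sum()), 1.0,
                                                   rel_tol=1e-9):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        return sum(w * _model_intensity(c, q) for c, w in spec.components)
    raise ValueError(f"unknown SAXS model {spec.model!r}")


def simulate_saxs_curve(spec: SAXSSimSpec):
    """Noisy ScatteringCurve from an analytic form-factor model."""
    from .saxs_primary import ScatteringCurve

    q = np.asarray(spec.q_nm, dtype=float)
    i_model = _model_intensity(spec, q)
    sigma = spec.noise_relative * np.abs(i_model) + spec.noise_floor
    sigma = np.clip(sigma, 1e-12, None)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, sigma) if (spec.noise_relative > 0
                                       or spec.noise_floor > 0) else 0.0
    return ScatteringCurve(q=q, intensity=i_model + noise, sigma=sigma,
                           label=spec.label or spec.model,
                           concentration_mg_ml=spec.concentration_mg_ml)
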