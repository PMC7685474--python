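"""AF4 retention theory: elution time <-> hydrodynamic radius.

In normal-mode asymmetrical flow field-flow fractionation (AF4) a cross-flow
pushes analytes toward the accumulation wall of a thin channel while diffusion
relaxes them away from it, producing an exponential concentration layer of
relative thickness ``lambda = l/w``.  The retention ratio

    R = t0/tr = 6*lambda*(coth(1/(2*lambda)) - 2*lambda)

links the observed retention time to the diffusion coefficient and hence, via
Stokes-Einstein, to the hydrodynamic radius.  Because the effective channel
height differs from the nominal spacer thickness (membrane swelling and
compression), a dimensionless ``thickness_scale`` can be calibrated against a
reference species of known radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "ChannelGeometry",
    "FlowConditions",
    "SolventConditions",
    "RetentionResult",
    "UnretainedSpeciesError",
    "channel_void_volume",
    "void_volume_downstream_of_focus",
    "void_time",
    "retention_ratio_from_lambda",
    "lambda_from_retention_ratio",
    "radius_from_retention_time",
    "time_from_radius",
    "calibrate_thickness",
]

BOLTZMANN_J_PER_K = 1.380649e-23


class UnretainedSpeciesError(ValueError):
    """Retention time at or below the void time: retention theory inapplicable."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Trapezoidal AF4 channel plan plus effective thickness.

    Defaults follow a standard trapezoidal channel: 26.5 cm tip-to-tip,
    inlet/outlet breadths 2.2/0.6 cm, 350 um spacer.  ``thickness_scale``
    multiplies the nominal spacer thickness to give the effective channel
    height w; it is the single calibration degree of freedom.
    """

    tip_to_tip_length_cm: float = 26.5
    inlet_width_cm: float = 2.2
    outlet_width_cm: float = 0.6
    nominal_thickness_um: float = 350.0
    thickness_scale: float = 1.0
    focus_position_cm: float = 2.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if min(self.tip_to_tip_length_cm, self.inlet_width_cm,
               self.outlet_width_cm, self.nominal_thickness_um) <= 0:
            raise ValueError("all channel dimensions must be positive")
        if self.thickness_scale <= 0:
            raise ValueError("thickness_scale must be positive")
        if self.outlet_width_cm > self.inlet_width_cm:
            raise ValueError("outlet width must not exceed inlet width")
        if not 0 <= self.focus_position_cm < self.tip_to_tip_length_cm:
            raise ValueError("focus position must lie within the channel")

    @property
    def thickness_cm(self) -> float:
        """Effective channel height w in cm."""
        return self.nominal_thickness_um * 1e-4 * self.thickness_scale


@dataclass(frozen=True)
class FlowConditions:
    detector_flow_ml_min: float = 1.0
    cross_flow_ml_min: float = 4.5
    elution_duration_min: float = 30.0

    def __post_init__(self) -> None:
        if self.detector_flow_ml_min <= 0:
            raise ValueError("detector flow must be positive")
        if self.cross_flow_ml_min < 0:
            raise ValueError("cross flow must be non-negative")


@dataclass(frozen=True)
class SolventConditions:
    """Carrier-liquid physical properties (room-temperature aqueous defaults)."""

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4
    refractive_index: float = 1.331
    laser_wavelength_nm: float = 658.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0 or self.viscosity_Pa_s <= 0:
            raise ValueError("temperature and viscosity must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class RetentionResult:
    retention_time_min: float
    void_time_min: float
    retention_ratio: float
    lambda_parameter: float
    diffusion_coefficient_cm2_s: float
    hydrodynamic_radius_nm: float


def channel_void_volume(geometry: ChannelGeometry) -> float:
    """Geometric channel volume in mL: trapezoid plan area x effective height."""
    area_cm2 = 0.5 * (geometry.inlet_width_cm + geometry.outlet_width_cm) \
        * geometry.tip_to_tip_length_cm
    return area_cm2 * geometry.thickness_cm


def void_volume_downstream_of_focus(geometry: ChannelGeometry) -> float:
    """Channel volume (mL) between the focus position and the outlet.

    The sample band starts its migration at the focus line, so only this
    downstream volume contributes to the void time.
    """
    L = geometry.tip_to_tip_length_cm
    b_in = geometry.inlet_width_cm
    b_out = geometry.outlet_width_cm
    z = geometry.focus_position_cm
    # integral of the linearly tapering breadth b(z') from z to L
    slope = (b_out - b_in) / L
    area = b_in * (L - z) + 0.5 * slope * (L * L - z * z)
    return area * geometry.thickness_cm


def void_time(geometry: ChannelGeometry, flows: FlowConditions) -> float:
    """Void time t0 in minutes."""
    return void_volume_downstream_of_focus(geometry) / flows.detector_flow_ml_min


def retention_ratio_from_lambda(lam: float) -> float:
    """Classical FFF retention equation R(lambda) = 6l(coth(1/2l) - 2l).

    Uses the large-lambda series 1 - 1/(60 l^2) + 1/(2520 l^4) above lambda = 2
    to avoid catastrophic cancellation, and clamps coth to 1 deep in the
    high-retention regime.  Strictly increasing on (0, inf) with range (0, 1).
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if lam > 2.0:
        return 1.0 - 1.0 / (60.0 * lam * lam) + 1.0 / (2520.0 * lam ** 4)
    x = 1.0 / (2.0 * lam)
    coth = 1.0 if x > 30 else math.cosh(x) / math.sinh(x)
    return 6.0 * lam * (coth - 2.0 * lam)


def lambda_from_retention_ratio(ratio: float) -> float:
    """Invert R(lambda) by bracketed root finding (relative tolerance 1e-10)."""
    if not 0 < ratio < 1:
        raise ValueError(f"retention ratio must lie in (0, 1), got {ratio}")
    lo, hi = 1e-12, 1e6
    return brentq(lambda l: retention_ratio_from_lambda(l) - ratio,
                  lo, hi, rtol=1e-12, maxiter=200)


def _diffusion_from_lambda(lam: float, geometry: ChannelGeometry,
                           flows: FlowConditions) -> float:
    """D in cm^2/s from lambda = D*V0/(Vc*w^2)."""
    v0_ml = channel_void_volume(geometry)
    vc_cm3_s = flows.cross_flow_ml_min / 60.0
    w = geometry.thickness_cm
    return lam * vc_cm3_s * w * w / v0_ml


def _lambda_from_diffusion(d_cm2_s: float, geometry: ChannelGeometry,
                           flows: FlowConditions) -> float:
    v0_ml = channel_void_volume(geometry)
    vc_cm3_s = flows.cross_flow_ml_min / 60.0
    w = geometry.thickness_cm
    return d_cm2_s * v0_ml / (vc_cm3_s * w * w)


def _stokes_einstein_radius_nm(d_cm2_s: float, solvent: SolventConditions) -> float:
    d_m2_s = d_cm2_s * 1e-4
    r_m = BOLTZMANN_J_PER_K * solvent.temperature_K / \
        (6.0 * math.pi * solvent.viscosity_Pa_s * d_m2_s)
    return r_m * 1e9


def _stokes_einstein_diffusion_cm2_s(radius_nm: float,
                                     solvent: SolventConditions) -> float:
    r_m = radius_nm * 1e-9
    d_m2_s = BOLTZMANN_J_PER_K * solvent.temperature_K / \
        (6.0 * math.pi * solvent.viscosity_Pa_s * r_m)
    return d_m2_s * 1e4


def radius_from_retention_time(t_r_min: float,
                               geometry: ChannelGeometry,
                               flows: FlowConditions,
                               solvent: SolventConditions | None = None,
                               ) -> RetentionResult:
    """Hydrodynamic radius from an observed retention time.

    Solves R(lambda) = t0/tr for lambda, converts to a diffusion coefficient
    through the channel model, and applies Stokes-Einstein.  Raises
    :class:`UnretainedSpeciesError` for t_r <= t0.
    """
    solvent = solvent or SolventConditions()
    t0 = void_time(geometry, flows)
    if t_r_min <= t0:
        raise UnretainedSpeciesError(
            f"retention time {t_r_min:g} min is not past the void time {t0:g} min")
    if not geometry.calibrated:
        warnings.warn("channel thickness not calibrated; radii use the nominal "
                      "spacer thickness and may be biased", stacklevel=2)
    ratio = t0 / t_r_min
    lam = lambda_from_retention_ratio(ratio)
    d = _diffusion_from_lambda(lam, geometry, flows)
    r_h = _stokes_einstein_radius_nm(d, solvent)
    return RetentionResult(
        retention_time_min=t_r_min, void_time_min=t0, retention_ratio=ratio,
        lambda_parameter=lam, diffusion_coefficient_cm2_s=d,
        hydrodynamic_radius_nm=r_h)


def time_from_radius(radius_nm: float,
                     geometry: ChannelGeometry,
                     flows: FlowConditions,
                     solvent: SolventConditions | None = None) -> float:
    """Forward retention model: predicted retention time (min) for a radius."""
    if radius_nm <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    solvent = solvent or SolventConditions()
    t0 = void_time(geometry, flows)
    if flows.cross_flow_ml_min == 0:
        warnings.warn("zero cross flow: species is unretained, eluting at t0",
                      stacklevel=2)
        return t0
    d = _stokes_einstein_diffusion_cm2_s(radius_nm, solvent)
    lam = _lambda_from_diffusion(d, geometry, flows)
    return t0 / retention_ratio_from_lambda(lam)


def calibrate_thickness(reference_radius_nm: float,
                        reference_tr_min: float,
                        geometry: ChannelGeometry,
                        flows: FlowConditions,
                        solvent: SolventConditions | None = None,
                        scale_range: tuple[float, float] = (0.2, 2.0),
                        ) -> ChannelGeometry:
    """Calibrate the effective channel thickness against a reference species.

    Finds the ``thickness_scale`` for which the forward model maps the
    reference radius onto the observed reference retention time (relative
    tolerance 1e-6); raises if no scale in ``scale_range`` achieves this.
    """
    solvent = solvent or SolventConditions()
    t0_nominal = void_time(geometry, flows)
    if reference_tr_min <= t0_nominal * scale_range[0]:
        raise UnretainedSpeciesError(
            "reference retention time precedes any achievable void time")

    def mismatch(scale: float) -> float:
        g = replace(geometry, thickness_scale=scale)
        return time_from_radius(reference_radius_nm, g, flows, solvent) \
            - reference_tr_min

    lo, hi = scale_range
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "calibration failure: no thickness scale in "
            f"[{lo}, {hi}] reproduces t_r = {reference_tr_min:g} min "
            f"(mismatch {f_lo:+.3g} .. {f_hi:+.3g} min)")
    scale = brentq(mismatch, lo, hi, rtol=1e-9, maxiter=200)
    return replace(geometry, thickness_scale=scale, calibrated=True)
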