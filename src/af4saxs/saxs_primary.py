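"""Model-free SAXS primary analysis.

Covers the standard first-pass chain for a 1-D solution scattering curve
I(q) +/- sigma(q):

* reduced chi^2 comparison of two curves with an analytically optimal scale,
* similarity-based frame selection and error-weighted averaging,
* Guinier fit (ln I = ln I0 - q^2 Rg^2 / 3) with a self-consistent automatic
  low-q range and a runs-test linearity flag,
* regularized indirect Fourier transform to the pair-distance distribution
  p(r) with p(0) = p(Dmax) = 0 and optional non-negativity,
* Porod invariant and volume with Guinier/Porod tail extrapolations,
* three molecular-weight estimators (Porod volume / 1.6, ab initio excluded
  volume / 2, and a concentration-normalised I(0) standard), and
* the dimensionless shape factor rho = Rg/Rh.

q is handled internally in 1/nm; an input curve whose maximum q is below 1
is assumed to be in 1/A and converted by the reader in workbench_io.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import norm

__all__ = [
    "ScatteringCurve",
    "GuinierResult",
    "PDDF",
    "PorodResult",
    "FitQuality",
    "ShapeFactorResult",
    "chi2",
    "select_and_average_frames",
    "guinier_fit",
    "pddf_ift",
    "dmax_scan",
    "porod_volume",
    "mw_from_porod_volume",
    "mw_from_excluded_volume",
    "mw_from_standard",
    "shape_factor",
    "round_half_away",
    "round_sig",
]


def round_half_away(x: float) -> int:
    """Round to integer with ties away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class ScatteringCurve:
    """1-D SAXS profile: q (1/nm), I(q), sigma(q), plus sample metadata."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""
    concentration_mg_ml: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.size == self.intensity.size == self.sigma.size):
            raise ValueError("q, I and sigma must have equal length")
        if self.q.size and (np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0)):
            raise ValueError("q must be positive and strictly increasing")
        if self.q.size and np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class FitQuality:
    chi2: float
    n_points: int
    scale_c: float


@dataclass(frozen=True)
class GuinierResult:
    radius_gyration_nm: float
    i_zero: float
    q_range: tuple[float, float]
    q_max_times_rg: float
    fit_r2: float
    linearity_flag: bool
    n_points: int


@dataclass
class PDDF:
    r: np.ndarray
    p_of_r: np.ndarray
    d_max: float
    alpha: float
    rg_real_nm: float
    i_zero_real: float
    reduced_chi2: float
    dmax_flagged: bool = False


@dataclass(frozen=True)
class PorodResult:
    invariant_q: float
    porod_volume_nm3: float
    mw_porod_kda: float       # full precision; round_half_away for reports


@dataclass(frozen=True)
class ShapeFactorResult:
    rho: float
    rg_source: str = "SAXS"
    rh_source: str = "AF4-MALS"


def chi2(experimental: ScatteringCurve,
         calculated_intensity: np.ndarray,
         optimize_scale: bool = True) -> FitQuality:
    """Reduced chi^2 between an experimental curve and a model intensity.

    With ``optimize_scale`` the scale c minimising the weighted residual is
    used: c = sum(I_exp I_calc / s^2) / sum(I_calc^2 / s^2); otherwise c = 1.
    chi2 = 1/(N-1) * sum(((I_exp - c I_calc)/sigma)^2).
    """
    i_exp = experimental.intensity
    i_cal = np.asarray(calculated_intensity, dtype=float)
    s = experimental.sigma
    n = i_exp.size
    if i_cal.size != n:
        raise ValueError("model intensity must match the experimental grid")
    if n < 2:
        raise ValueError("need at least two points for a chi2")
    if optimize_scale:
        denom = float(np.sum(i_cal ** 2 / s ** 2))
        c = float(np.sum(i_exp * i_cal / s ** 2)) / denom if denom > 0 else 1.0
    else:
        c = 1.0
    value = float(np.sum(((i_exp - c * i_cal) / s) ** 2)) / (n - 1)
    return FitQuality(chi2=value, n_points=n, scale_c=c)


def select_and_average_frames(frames: list[ScatteringCurve],
                              threshold: float = 1.5,
                              ) -> tuple[ScatteringCurve, list[int]]:
    """Similarity-select frames and form their error-weighted average.

    The reference is the point-wise median across frames; frames whose
    reduced chi^2 against the reference (no rescaling) is at most
    ``threshold`` are kept.  The average is inverse-variance weighted with
    sigma_avg = sqrt(1 / sum(sigma^-2)).  If nothing passes, the single
    closest frame is returned with a warning.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    q = frames[0].q
    for f in frames[1:]:
        if f.q.size != q.size or not np.allclose(f.q, q):
            raise ValueError("frames must share a common q grid")

    stack = np.stack([f.intensity for f in frames])
    ref = np.median(stack, axis=0)
    scores = [chi2(f, ref, optimize_scale=False).chi2 for f in frames]
    kept = [i for i, s in enumerate(scores) if s <= threshold]
    if not kept:
        best = int(np.argmin(scores))
        warnings.warn("no frame within the similarity threshold; returning "
                      "the closest single frame", stacklevel=2)
        kept = [best]

    w = np.stack([1.0 / frames[i].sigma ** 2 for i in kept])
    i_avg = np.sum(w * stack[kept], axis=0) / np.sum(w, axis=0)
    s_avg = np.sqrt(1.0 / np.sum(w, axis=0))
    avg = ScatteringCurve(q=q.copy(), intensity=i_avg, sigma=s_avg,
                          label=frames[0].label + " (averaged)",
                          concentration_mg_ml=frames[0].concentration_mg_ml)
    return avg, kept


def _runs_test_ok(residuals: np.ndarray, alpha: float = 0.05) -> bool:
    """Wald-Wolfowitz runs test on residual signs; True = no curvature seen."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = signs.size
    if n < 8:
        return True
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return False
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return True
    z = (runs - mu) / math.sqrt(var)
    return abs(z) < norm.ppf(1.0 - alpha / 2.0)


def guinier_fit(curve: ScatteringCurve,
                q_rg_limit: float = 1.3,
                min_points: int = 10,
                skip_points: int = 2) -> GuinierResult:
    """Guinier fit with a self-consistent automatic low-q range.

    Starting from the ``skip_points``-th usable point, candidate windows grow
    while the self-consistency condition q_max * Rg <= ``q_rg_limit`` holds
    for the Rg fitted on each window; among the self-consistent windows the
    one with the smallest reduced chi^2 (sigma-weighted, in log space) is
    returned, which keeps the fit inside the region where the quadratic
    approximation actually holds.  A runs test on the residuals sets
    ``linearity_flag`` False when systematic curvature (aggregation or
    interparticle interference) is detected.
    """
    usable = np.flatnonzero(curve.intensity > 0)
    if usable.size < min_points + skip_points:
        raise ValueError("too few positive-intensity points for a Guinier fit")

    q2 = curve.q ** 2
    ln_i = np.full_like(curve.q, np.nan)
    ln_i[usable] = np.log(curve.intensity[usable])
    w_full = np.zeros_like(curve.q)
    w_full[usable] = curve.intensity[usable] / curve.sigma[usable]

    def scan(idx_all: np.ndarray) -> list[tuple]:
        """All self-consistent candidate windows starting at idx_all[0]."""
        found = []
        for stop in range(min_points, idx_all.size + 1):
            idx = idx_all[:stop]
            x, y, w = q2[idx], ln_i[idx], w_full[idx]
            design = np.column_stack([np.ones_like(x), x])
            coef, _, _, _ = np.linalg.lstsq(design * w[:, None], y * w,
                                            rcond=None)
            b0, b1 = coef
            if b1 >= 0:
                break
            rg = math.sqrt(-3.0 * b1)
            q_max_rg = curve.q[idx[-1]] * rg
            if q_max_rg > q_rg_limit:
                break
            resid_w = w * (y - (b0 + b1 * x))
            score = float(resid_w @ resid_w) / max(idx.size - 2, 1)
            found.append((score, idx, b0, b1, rg, q_max_rg))
        return found

    # slide the start point forward past any low-q upturn (aggregation)
    aggregated = False
    candidates: list[tuple] = []
    for extra_skip in range(0, usable.size - min_points - skip_points + 1):
        idx_all = usable[skip_points + extra_skip:]
        candidates = scan(idx_all)
        if candidates:
            aggregated = extra_skip > 0
            break
    if not candidates:
        raise ValueError("no valid Guinier window: curve has no self-consistent "
                         "low-q region with negative slope")
    # widest window whose chi2 is statistically comparable to the best one
    best_score = min(c[0] for c in candidates)
    ok = [c for c in candidates if c[0] <= 1.5 * best_score + 1e-12]
    _, idx, b0, b1, rg, q_max_rg = max(ok, key=lambda c: c[1].size)
    x, y, w = q2[idx], ln_i[idx], w_full[idx]
    fit = b0 + b1 * x
    resid = y - fit
    ss_res = float(np.sum((w * resid) ** 2))
    ss_tot = float(np.sum((w * (y - np.average(y, weights=w))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(
        radius_gyration_nm=rg,
        i_zero=math.exp(b0),
        q_range=(float(curve.q[idx[0]]), float(curve.q[idx[-1]])),
        q_max_times_rg=q_max_rg,
        fit_r2=r2,
        linearity_flag=_runs_test_ok(resid) and not aggregated,
        n_points=int(idx.size),
    )


def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Kernel A[j, k] so that I(q_j) = sum_k A[j, k] p(r_k) (trapezoid rule)."""
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    kernel = 4.0 * math.pi * np.sinc(qr / math.pi)    # 4 pi sin(qr)/(qr)
    wts = np.full(r.size, dr)
    wts[0] = wts[-1] = dr / 2.0
    return kernel * wts[None, :]


def pddf_ift(curve: ScatteringCurve,
             d_max: float,
             alpha: float | str = "auto",
             n_r: int = 101,
             nonnegative: bool = True) -> PDDF:
    """Regularized indirect Fourier transform to the pair-distance distribution.

    Solves I(q) = 4 pi int_0^Dmax p(r) sin(qr)/(qr) dr on an ``n_r``-point r
    grid with fixed endpoint zeros, a second-difference smoothness penalty of
    weight ``alpha``, inverse-variance data weighting, and (by default) a
    non-negativity constraint solved via NNLS.  ``alpha='auto'`` picks the
    corner of the (log residual, log penalty) L-curve.  A reduced chi^2 much
    greater than 1 flags a too-small ``d_max``.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    q, i_exp, s = curve.q, curve.intensity, curve.sigma
    if q[-1] * d_max < math.pi:
        warnings.warn("curve barely resolves d_max (q_max * d_max < pi)",
                      stacklevel=2)
    r = np.linspace(0.0, d_max, n_r)
    a_full = _ift_design(q, r)
    a = a_full[:, 1:-1]                    # p(0) = p(Dmax) = 0 built in
    aw = a / s[:, None]
    yw = i_exp / s

    m = a.shape[1]
    d2 = np.zeros((m - 2, m))
    for k in range(m - 2):
        d2[k, k:k + 3] = (1.0, -2.0, 1.0)
    # scale regularisation so alpha is dimensionless across problems
    d2 *= np.linalg.norm(aw) / max(np.linalg.norm(d2), 1e-300)

    def solve(al: float) -> np.ndarray:
        stacked = np.vstack([aw, math.sqrt(al) * d2])
        rhs = np.concatenate([yw, np.zeros(m - 2)])
        if nonnegative:
            sol, _ = nnls(stacked, rhs, maxiter=10 * m)
        else:
            sol, _, _, _ = np.linalg.lstsq(stacked, rhs, rcond=None)
        return sol

    if alpha == "auto":
        alphas = np.logspace(-6, 2, 15)
        pts = []
        for al in alphas:
            p_try = solve(al)
            res = float(np.sum((aw @ p_try - yw) ** 2))
            pen = float(np.sum((d2 @ p_try) ** 2))
            pts.append((math.log(max(res, 1e-300)), math.log(max(pen, 1e-300))))
        # maximum-curvature corner of the discrete L-curve
        best_k, best_c = 1, -np.inf
        for k in range(1, len(alphas) - 1):
            x0, y0 = pts[k - 1]; x1, y1 = pts[k]; x2, y2 = pts[k + 1]
            cross = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
            d01 = math.hypot(x1 - x0, y1 - y0)
            d12 = math.hypot(x2 - x1, y2 - y1)
            d02 = math.hypot(x2 - x0, y2 - y0)
            denom = d01 * d12 * d02
            curv = abs(cross) / denom if denom > 0 else 0.0
            if curv > best_c:
                best_c, best_k = curv, k
        alpha_val = float(alphas[best_k])
    else:
        alpha_val = float(alpha)

    p_inner = solve(alpha_val)
    if not np.all(np.isfinite(p_inner)):
        raise RuntimeError("IFT ill-conditioned; supply a larger alpha")
    p = np.zeros(n_r)
    p[1:-1] = p_inner

    i_fit = a @ p_inner
    # effective parameter count of the regularised (linear) estimator:
    # df = tr[Aw (Aw'Aw + a D'D)^-1 Aw']  -- the hat-matrix trace
    gram = aw.T @ aw
    try:
        df_eff = float(np.trace(np.linalg.solve(
            gram + alpha_val * (d2.T @ d2), gram)))
    except np.linalg.LinAlgError:
        df_eff = float(m)
    dof = max(q.size - df_eff, 1.0)
    red_chi2 = float(np.sum(((i_exp - i_fit) / s) ** 2)) / dof

    total = float(np.trapezoid(p, r))
    if total > 0:
        rg2 = float(np.trapezoid(r ** 2 * p, r)) / (2.0 * total)
        rg_real = math.sqrt(max(rg2, 0.0))
        i0_real = 4.0 * math.pi * total
    else:
        rg_real, i0_real = 0.0, 0.0

    return PDDF(r=r, p_of_r=p, d_max=d_max, alpha=alpha_val,
                rg_real_nm=rg_real, i_zero_real=i0_real,
                reduced_chi2=red_chi2,
                dmax_flagged=red_chi2 > 10.0)


def dmax_scan(curve: ScatteringCurve,
              dmax_grid: np.ndarray,
              alpha: float | str = "auto",
              n_r: int = 61,
              rel_tol: float = 0.10) -> tuple[float, np.ndarray]:
    """Choose D_max as the smallest trial value whose IFT fit is near-optimal.

    Runs ``pddf_ift`` for each candidate and returns the smallest d_max whose
    reduced chi^2 is within ``rel_tol`` of the best across the grid (fits stop
    improving once d_max reaches the true maximum particle dimension).
    """
    dmax_grid = np.asarray(dmax_grid, dtype=float)
    scores = np.array([pddf_ift(curve, d, alpha=alpha, n_r=n_r).reduced_chi2
                       for d in dmax_grid])
    best = float(np.min(scores))
    cutoff = best * (1.0 + rel_tol) + 1e-12
    chosen = float(dmax_grid[np.flatnonzero(scores <= cutoff)[0]])
    return chosen, scores


def porod_volume(curve: ScatteringCurve, i_zero: float,
                 rg_nm: float | None = None) -> PorodResult:
    """Porod invariant, Porod volume and the V_p/1.6 mass estimate.

    Q = int q^2 I dq over the measured range, extended to q = 0 with a Guinier
    extrapolation (when ``rg_nm`` is given) and to infinity with a Porod
    K/q^4 tail fitted on the last decade of q.  V_p = 2 pi^2 I(0) / Q and
    MW_p = V_p / 1.6 under the standard nm^3-to-kDa protein conversion.
    """
    q, i = curve.q, curve.intensity
    if i_zero <= 0:
        raise ValueError("I(0) must be positive")
    q_core = float(np.trapezoid(q ** 2 * i, q))

    # low-q tail from Guinier extrapolation to q = 0
    if rg_nm is not None and rg_nm > 0:
        q_lo = np.linspace(0.0, q[0], 50)
        i_lo = i_zero * np.exp(-q_lo ** 2 * rg_nm ** 2 / 3.0)
        q_low = float(np.trapezoid(q_lo ** 2 * i_lo, q_lo))
    else:
        q_low = float(q[0] ** 3 / 3.0 * i_zero)   # flat extrapolation

    # high-q tail: Porod constant K = q^4 I averaged over the last decade
    tail = q >= q[-1] / 10.0 ** 0.5
    if np.count_nonzero(tail) < 3:
        tail = q >= q[-1] / 2.0
    k_porod = float(np.mean(q[tail] ** 4 * i[tail]))
    if k_porod <= 0:
        raise ValueError("negative Porod constant: check background subtraction")
    q_high = k_porod / q[-1]

    invariant = q_core + q_low + q_high
    v_p = 2.0 * math.pi ** 2 * i_zero / invariant
    return PorodResult(invariant_q=invariant, porod_volume_nm3=v_p,
                       mw_porod_kda=mw_from_porod_volume(v_p))


def mw_from_porod_volume(v_p_nm3: float) -> float:
    """MW estimate (kDa) from the hydrated-particle Porod volume: V_p / 1.6."""
    if v_p_nm3 < 0:
        raise ValueError("Porod volume must be non-negative")
    return v_p_nm3 / 1.6


def mw_from_excluded_volume(v_a_nm3: float) -> float:
    """MW estimate (kDa) from an ab initio model's excluded volume: V_a / 2."""
    if v_a_nm3 < 0:
        raise ValueError("excluded volume must be non-negative")
    return v_a_nm3 / 2.0


def mw_from_standard(i_zero: float, concentration_mg_ml: float,
                     ref_i_zero: float, ref_concentration_mg_ml: float,
                     ref_mw_kda: float) -> float:
    """MW from I(0)/c against a reference standard measured identically."""
    if min(i_zero, concentration_mg_ml, ref_i_zero,
           ref_concentration_mg_ml, ref_mw_kda) <= 0:
        raise ValueError("all intensities, concentrations and the reference "
                         "mass must be positive")
    return ref_mw_kda * (i_zero / concentration_mg_ml) \
        / (ref_i_zero / ref_concentration_mg_ml)


def shape_factor(rg_nm: float, rh_nm: float,
                 rg_source: str = "SAXS",
                 rh_source: str = "AF4-MALS") -> ShapeFactorResult:
    """Dimensionless ratio rho = Rg/Rh (0.77 for a homogeneous solid sphere)."""
    if rg_nm <= 0 or rh_nm <= 0:
        raise ValueError("radii must be positive")
    return ShapeFactorResult(rho=rg_nm / rh_nm,
                             rg_source=rg_source, rh_source=rh_source)
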