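# Methods

## AF4 retention model

The channel is trapezoidal (tip-to-tip length L = 26.5 cm, breadths
2.2 → 0.6 cm, nominal spacer 350 µm) with constant detector flow
1.0 mL/min and cross-flow 4.5 mL/min. The geometric volume is the plan
area times the effective height w, and the void time uses only the volume
downstream of the focus line (default 2 cm from the inlet), since the
sample band starts migrating there: t₀ = V_downstream/V_out.

Retention follows the classical normal-mode equation
R = 6λ[coth(1/(2λ)) − 2λ] with λ = D·V₀/(V_c·w²); the diffusion
coefficient maps to a hydrodynamic radius through Stokes–Einstein at
298.15 K and η = 8.9×10⁻⁴ Pa·s (room-temperature water; neither is a
sensitive choice at the ±2 K level). The equation is inverted by bracketed
root finding; above λ = 2 a series expansion replaces the coth difference
to avoid catastrophic cancellation. Steric and non-equilibrium corrections
are omitted: all species here are below 10 nm, far from steric inversion.

Because membrane swelling and compression make the effective channel
height differ substantially from the nominal spacer, absolute radii from
nominal geometry are biased (uncalibrated use emits a warning). The
supported workflow calibrates a dimensionless `thickness_scale`
(search range 0.2–2.0) against one reference species; calibrating the
albumin monomer peak (3.2–3.3 nm at 4.5 min) places the dimer peak at
6.45–6.5 min, matching the observed 6.5 min within a fraction of a
percent. Note a genuine property of the theory: at fixed t_r the inferred
radius *increases* when the cross-flow decreases, since λ is pinned by
R = t₀/t_r and D ∝ V_c.

## MALS Berry fitting

The optical constant is K* = 4π²n₀²(dn/dc)²/(N_A λ₀⁴) (n₀ = 1.331,
λ₀ = 658 nm; dn/dc 0.185 mL/g for albumin, 0.196 mL/g for the fusion
protein). Berry coordinates √(K*c/R_θ) are fitted against sin²(θ/2) by
weighted polynomial least squares of degree 1 or 2; the intercept gives
M = a₀⁻², the slope gives R_g² = 6a₁/(a₀·(4πn₀/λ₀)²). The exact 14-angle
detector set is configurable; the default spans 32–147° with the subset
split at ≤81° (6 angles, "low") / ≥90° (8 angles, "high"). For visible
light and R_g ≤ 5 nm the form factor varies by <1% across this range, so
subset disagreement on real data diagnoses noise or co-elution, not shape.

Per-detector noise is estimated from the quieter of the first/last 10% of
the run; weights propagate σ_R into Berry coordinates
(σ_y = y·σ_R/(2R_θ)). Slices whose dRI-derived concentration is below 5×
the baseline SD are reported "n.d."; the peak mass is the weight average
Σc·M/Σc over the remaining slices. The second virial coefficient is fixed
at zero (dilute regime; concentrations ≤2 mg/mL). Batch dn/dc is an OLS
slope of Δn against concentration.

## Peak deconvolution and bound ratios

Fractograms are fitted as a linear baseline plus one Gaussian per
initialisation window (windows must be disjoint; centers bounded to their
windows, σ ∈ (0, window width]); areas follow analytically as
amplitude·σ·√2π. Peak areas are converted to molarity with
Konv = C_molar(pure injection)/area(pure injection), which assumes a
linear UV response and equal injection volumes and makes all ratios
invariant to the UV gain.

With the working assumption that ligand binding leaves the albumin
monomer–dimer ratio unchanged, the monomer and dimer pools in a mixture
equal those measured on pure albumin; dimer concentration is expressed in
dimer *particles* (half the molar albumin content in dimers), so "ligand
per dimer" counts ligands per particle. The three ratios are

* per dimer: (AUC_dimer(mix) − AUC_dimer(pure))·Konv / C_dimer,
* free per albumin: AUC_free(mix)·Konv / C_total,
* per monomer: (C_added − C_free − C_in-dimer) / C_monomer,

the last defined by mass balance, which therefore holds exactly. Negative
subtraction results within twice the propagated noise are clipped to zero;
larger negatives additionally raise a data-inconsistency warning. K_d
estimation is deliberately out of scope — the experiment reports bound
ratios, not an isotherm fit.

## SAXS primary analysis

*χ² metric.* Reduced χ² = (N−1)⁻¹ Σ[(I_exp − c·I_calc)/σ]² with the
analytically optimal scale c = Σ(I_exp I_calc/σ²)/Σ(I_calc²/σ²) when
requested.

*Frame averaging.* The reference is the point-wise median frame; frames
with χ² ≤ 1.5 (no rescaling) against it are kept and averaged with
inverse-variance weights, σ_avg = (Σσ⁻²)^(−1/2).

*Guinier.* Weighted fit of ln I vs q², windows grown from the 3rd usable
point under the self-consistency constraint q_max·R_g ≤ 1.3; among the
self-consistent windows the widest whose weighted residual χ² is within
50% of the best is chosen, which keeps the fit inside the genuinely
quadratic region on clean data while using the full window on noisy data.
A q_min·R_g lower bound is not enforced (small proteins). A
Wald–Wolfowitz runs test on the residuals (5% level), or any forced
skipping of upturned low-q points, clears the linearity flag — the
aggregation diagnostic.

*IFT.* I(q) = 4π∫p(r)·sinc(qr)dr is discretised by the trapezoid rule on
an n_r-point grid with p(0) = p(D_max) = 0 eliminated, weighted by 1/σ,
and solved with a second-difference smoothness penalty; non-negativity
(default on, appropriate for compact particles) makes the solver NNLS.
α = "auto" picks the maximum-curvature corner of the discrete
(log residual, log penalty) L-curve over 15 values in 10⁻⁶–10². The
reduced χ² uses the effective parameter count tr[A(AᵀA + αDᵀD)⁻¹Aᵀ]
rather than the raw grid size. D_max scans choose the smallest trial
value whose χ² is within 10% of the grid optimum — the fit stops
improving once D_max reaches the true maximum dimension.

*Porod.* Q = ∫q²I dq over the data, extended to q = 0 by Guinier
extrapolation and to infinity by a K/q⁴ tail with K averaged over the
last half-decade of q; V_p = 2π²I(0)/Q. Mass estimators: V_p/1.6 (hydrated
Porod volume, nm³ → kDa), V_a/2 (ab initio model excluded volume), and
I(0)/c ratioed to a reference standard. Reported masses round half away
from zero to integer kDa; shape factors ρ = R_g/R_h report to two
significant figures (√(3/5) ≈ 0.77 for a solid sphere).

## Synthetic-data generator

The generator emulates the study conditions: albumin at 2 mg/mL with a
93:7 monomer:dimer content (66.5/133 kDa, R_h 3.3/4.8 nm), an 11.5 kDa
ligand (R_h ≈ 2.8 nm) in fast monomer–dimer exchange with its 23 kDa
dimer, 1:1 (v/v) titrations of 0.01–2 mg/mL ligand stock into 2 mg/mL
albumin, and SAXS particles including an oblate 4×4×1.5 nm
albumin-like ellipsoid. Elution bands are Gaussian with
σ = t_r/√N at plate number N = 2500 (chromatographic efficiency typical
of a well-behaved AF4 channel and consistent with near-baseline-separated
albumin peaks); fast exchange produces a single skew-normal band at the
population-weighted position whose light scattering carries the
weight-average mass, so slice masses are flat across the peak. Detectors
respond linearly (UV = Σcᵢεᵢ, dRI = Σcᵢ(dn/dc)ᵢ, R_θ = K*cᵢMᵢP(θ)) with
additive Gaussian noise, default SD 0.5% of each detector's peak.
Titrations solve a single-site equilibrium with one site per albumin unit
(a dimer particle carries two); a dimeric ligand entity occupies one site
but delivers two ligand masses, so the saturated overall ratio is 1 + g_d
with g_d the dimer fraction among binding entities — a molecule dimer
fraction of 0.46 yields the observed plateau of 1.3. Complex radii follow
hydrodynamic volume additivity, R_h³ = ΣR_h,ᵢ³, a simple defensible rule
in the absence of structural information.

SAXS curves use analytic form factors (sphere; orientation-averaged
ellipsoid by 64-point Gauss–Legendre quadrature; two-sphere dumbbell with
Debye cross term) with σ(q) = 0.01·I(q) + 10⁻⁴·I(0) by default.

What the generator does **not** emulate — and what passing closed-loop
tests therefore cannot show about real data: inter-detector band
broadening and delay volumes, baseline drift beyond linear, detector
saturation, membrane adsorption, radiation damage, and concentration-
dependent structure factors. Recovery tolerances on synthetic data are
lower bounds on real-world uncertainty.

## Problem sizes in tests

Closed-loop suites use 12-minute elution windows sampled at 0.01 min with
14 LS angles, 50-seed replicates for noisy-recovery statistics, SAXS
curves of 200–800 points, and IFT grids of 61–101 r-points — sizes chosen
so each recovery statistic is well-resolved while the whole suite runs in
seconds.

## Known limitations

* Retention theory is normal-mode only; no programmed cross-flow decay,
  focusing hydrodynamics or steric effects.
* The Guinier range heuristic can return short windows on very noisy
  curves; inspect `n_points` and `fit_r2`.
* The L-curve corner criterion is a pragmatic stand-in for perceptual
  regularisation criteria; α is always reported for reproducibility.
* Konv-based concentration conversion assumes strictly linear UV response
  and identical injection volumes between the pure reference and mixture
  runs.
* The monomer/dimer windows overlap in principle; the deconvolution
  resolves overlap by simultaneous fitting, but severely fused peaks
  (plate numbers ≪ 1000) will inflate area uncertainties.
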