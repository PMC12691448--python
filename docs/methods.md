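# Methods

## Model structure and assumptions

The framework couples exponential tumor growth with mass-action T-cell
killing, saturating (Michaelis–Menten) drug effects, and first-order drug
clearance. Two therapeutic agents enter: Avelumab (A₁), an anti-PD-L1
antibody that blocks PD-1/PD-L1 complex formation by the fraction
φ(A₁) = c₁A₁/(c₁A₁+K_A1), and NHS-muIL12 (A₂), an immunocytokine that
stimulates T-cell proliferation through a saturating term proportional to
T. Immunosuppression acts through the complex abundance
Q = q₀·T·(T+εV)·(1−φ): PD-1 sits on T-cells, PD-L1 on both T-cells and
(scaled by the expression propensity ε) tumor cells, and the factor
1/(1+Q/K_TQ) throttles all T-cell production. The three complex
coefficients σ, ρ_P, ρ_L appear only as a product and are lumped into a
single configurable q₀; they are not separately identifiable.

ε is dimensionless and is interpreted as the tumor's *functional*
immunosuppressive strength rather than a molecular PD-L1 count. In the
base model it is a constant; in the refined model it is a state variable
driven by basal production saturating in tumor volume (half-saturation
K_V), NHS-muIL12-induced upregulation (the adaptive-resistance term,
rate α_A2, sharing the drug saturation of the T-cell stimulation term),
Avelumab-mediated suppression (rate α_A1·φ), and natural decay (d_ε).
An explicit IFN-γ compartment is deliberately omitted — linking
upregulation directly to A₂ avoids additional identifiability problems.

Dosing is impulsive: injections on named days are instantaneous jumps in
the drug compartments (left-limit convention — the jump happens at the
dose time and integration restarts from the post-jump state). No
subcutaneous absorption phase is modeled for NHS-muIL12. ε(0) is the
drug-free quasi-steady state (k_basal/d_ε)·V₀/(K_V+V₀), computed before
any day-0 bolus. T(0) defaults to the drug-free basal balance δ/d_T
because no T-cell initial condition is observable; it is overridable.

## Parameters

Units are days, mm³ and μg throughout; c₁/c₂ absorb the conversion from
administered μg to the effective-concentration scale of K_A1/K_A2.

Fixed from murine literature or the companion modeling work:

| parameter | value | meaning |
|---|---|---|
| λ_T | 4.15 day⁻¹ | max CD8⁺ stimulation rate by IL-12 |
| K_A1 | 1×10⁻¹³ | Avelumab half-saturation |
| K_A2 | 7×10⁻¹⁴ | NHS-muIL12 half-saturation |
| d_A1 | ln2/1.86 ≈ 0.3726 day⁻¹ | Avelumab clearance (44.6 h half-life) |
| d_A2 | ln2/9.5 ≈ 0.0730 day⁻¹ | NHS-muIL12 clearance |

Dynamic-ε constants (the globally fitted EMT6 values, used as defaults
and as synthetic ground truth): k_basal = 30.5441 day⁻¹, K_V = 50 mm³,
α_A1 = 38.2653 day⁻¹, α_A2 = 643.6397 day⁻¹, d_ε = 0.4409 day⁻¹. An MC38
variant (`EpsilonParams.mc38()`) carries the values refitted to the
400 μg-Avelumab study: k_basal = 12.64, K_V = 462.70, α_A1 = 3.72,
α_A2 = 1990.17, d_ε = 0.10.

The remaining base-system constants (r, η, δ, d_T, c₁, c₂, K_TQ, q₀) come
from an appendix table that is not available to this implementation, so
the package ships its own defaults: r = 0.17, η = 0.03, δ = 1.2,
d_T = 0.35, c₁ = 1×10⁻¹⁵, c₂ = 4×10⁻¹⁵, K_TQ = 3×10⁴, q₀ = 1. They were
chosen once, by forward simulation, to satisfy two design constraints and
then frozen: (i) the six EMT6 arms reproduce the study's qualitative
regimes — untreated growth from 100 to ≈1750 mm³ by day 25,
dose-dependent partial efficacy of NHS-muIL12 monotherapy that ultimately
fails through ε upregulation, modest slowing under Avelumab alone,
non-monotone rise-then-regression in the low-dose combination, and rapid
elimination in the high-dose combination; (ii) every ε-equation constant
has a nonzero local effect on the observed volumes (Q/K_TQ of order one
in the untreated state, so changes in ε move T and hence V). All values
are overridable through a flat JSON/YAML config whose keys are the field
names of `BaseParams`/`EpsilonParams`.

## Numerical choices

* Integration: LSODA (stiff-capable, adaptive) with rtol 1e-8 /
  atol 1e-10, restarted at every dose day; rate constants span several
  orders of magnitude across arms. Output on a dense 0.1-day grid by
  default, or exactly at observation days during fitting.
* Negative excursions below 1e-8 in absolute value are clipped to zero
  (solver-tolerance headroom above atol); anything larger raises, because
  positivity is a model property and larger violations indicate a
  tolerance failure.
* Fitting: bounded trust-region least squares (`scipy.optimize.
  least_squares`, trf) on log10-transformed parameters, with bounds
  [1e-4, 1e4] × nominal scale. Multistart uses the geometric center of
  the bounds box plus seeded log-uniform Latin-hypercube points
  (default 20 starts). SSE is unweighted — experimental standard errors
  are not used. If the integrator fails at an extreme trial point the
  residual is replaced by a large finite penalty (1e8) so the trust
  region backs off instead of aborting the start.
* The elimination threshold for outcome classification is 1 mm³ (strict
  inequality at the horizon t_end = 25 days); both are configurable.
* AIC = n·ln(RSS/n) + 2k. Per-arm rows use n = 6 with k = 1 (constant ε)
  and k = 5 (dynamic ε, all global parameters charged to each arm).
  Global totals are computed from the RSS summed over all 36 points
  (k = 6 constant, k = 5 dynamic); this — not the sum of per-arm AICs —
  is the aggregation that reproduces the published totals, and both
  quantities are exposed (`ComparisonTable.constant_aic_sum` vs
  `constant_total_aic`) because the two conventions genuinely differ
  (242.78 vs 259.84 on the published constant-ε numbers).
* The dynamic fit defaults to five free parameters; a `fit_KV=False`
  mode fixes K_V and fits four (k = 4), matching the alternative
  convention in which the volume half-saturation is held at its nominal
  value.

## The synthetic-data generator

The original tumor-volume observations were digitized from published
figures and are not printed anywhere, so every downstream stage is
exercised on synthetic studies that copy the experimental design: six
arms (isotype control; NHS-muIL12 2 μg or 10 μg on day 0; Avelumab
200 μg on days 0/3/6; both combinations — 400 μg Avelumab for the MC38
layout), V(0) = 100 mm³, and six observation days per arm (default 0, 5,
10, 15, 20, 25; the real observation days are unrecoverable from the
text). Volumes are simulated under the dynamic-ε model at known truth
parameters and perturbed by multiplicative lognormal noise (σ = 0.1 by
default — tumor-volume measurement error scales with size; no noise
model is stated in the source material). What the generator does *not*
emulate: between-mouse heterogeneity, the bimodal responder/non-responder
split of the high-dose arm, measurement-day jitter, or censoring by
humane endpoints. Tests passing on this generator therefore demonstrate
correctness of the pipeline under the model's own assumptions, not
fidelity to real murine data.

## Identifiability of the ε-equation constants

Noise-free self-consistency is exact: a six-arm study generated at the
truth and refit with 20 multistarts returns every parameter to machine
precision (refit RSS ≈ 1e-22). With 10% lognormal observation noise the
picture changes qualitatively: the five constants are *practically
non-identifiable* at this sample size. The fitted optimum routinely sits
at 30–50% of the RSS attained by the truth while lying far away in
parameter space (median relative errors of roughly 90–340% per
parameter, with strong pairwise compensation among k_basal, K_V and
α_A2, and between α_A1 and d_ε). The cause is structural: ε influences
the observable V only through the single scalar pathway
ε → Q → F → T → V, so the Fisher information matrix is near-singular and
the likelihood has long curved valleys — classic sloppy-model geometry.
Neither more multistarts (which find *deeper* noise-fitting optima), a
purely local refit from the truth-scale start, nor fixing K_V (the
four-parameter mode) restores 25%-level recovery; three structurally
different base parameterizations were examined with the same result. The
recovery experiment reports this honestly (per-parameter bias, median
absolute relative error and RMSE, plus non-converged counts) rather than
hiding it; point estimates of these constants from a single 36-point
study should be read as one point on a ridge of near-equivalent fits,
and the ratio k_basal/d_ε (which sets ε's equilibrium scale) is far
better determined than either factor.

## Sensitivity analysis

The local sweep perturbs the nine constants not refit from tumor-growth
data (the five ε constants, K_A1, K_A2, d_A1, d_A2) one at a time by
±25% and re-simulates all six arms (108 runs). "Most sensitive arm" is
quantified as the largest absolute relative change in final tumor
volume across all perturbations of that arm — the ranking statistic is a
package choice, as only the qualitative conclusion is inherited from the
source analysis. The focused Mode-6 (high-dose combination) time-course
analysis varies α_A2, α_A1, K_A1 and d_A1 and verifies that tumor
elimination — and the eventual decay of ε to zero once the tumor is
eradicated — survives every ±25% perturbation.

## Known limitations

* The base-system defaults are this package's own calibration, not the
  source appendix values; absolute simulated volumes should not be read
  as predictions for EMT6 mice.
* No T-cell exhaustion, clonal-selection structure, delay terms, or
  stochastic/agent-based dynamics; no stability or bifurcation analysis.
* Residuals are computed on V only (the single observed state), so the
  T-cell trajectory is entirely model-imputed.
* AIC totals across independently fitted arms and a single joint fit are
  not strictly comparable; both are reported under documented
  conventions.
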