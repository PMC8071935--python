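# Methods

## Signal model

The package models diffusion-weighted signal decay in perfused tissue as two
exponential pools,

S_b/S_0 = f·exp(−b·D\*) + (1 − f)·exp(−b·D),

with the diffusion coefficient D and pseudo-diffusion coefficient D\* stored
internally in mm²/s and converted to the conventional display units
(10⁻³ mm²/s for D, 10⁻² mm²/s for D\*) only at the reporting layer; keeping a
single canonical unit avoids scale bugs. Signals are normalized at ingestion
(S_0 = 1): raw `(b, intensity)` input is divided by its b = 0 entry, and
simulated ROI curves are renormalized the same way after noise averaging.
The default acquisition scheme is the clinical 10-b-value design
(0–1000 s/mm² with excitation counts 2,2,2,2,2,2,2,4,6,8); any strictly
increasing scheme starting at b = 0 can be configured.

The model is symmetric under exchanging the two pools (D ↔ D\*, f ↔ 1 − f);
the package fixes labels by the convention D ≤ D\* (the slow pool is
"diffusion") and flags fits where the optimizer lands on the mirrored
labeling.

## Fitting

**Segmented ("mono") fit.** The b range is split at a threshold (default
200 s/mm²; b = 200 is assigned to the low set, so the high set is the strict
inequality b > 200 and keeps 4 of the 10 default points). Ordinary least
squares of log-signal against b over the high-b set gives D = −slope and,
extrapolated to b = 0, an intercept; f = 1 − intercept. D\* is then the
bounded one-dimensional least-squares minimizer of the full bi-exponential
residual with D and f held fixed, over all b values by default
(`dstar_b_range: low` restricts to the low-b subset). When the estimated
f ≤ 0.005 the perfusion pool carries too little signal for D\* to be
identifiable; D\* is reported at its lower bound with a
`D_star_nonidentifiable` flag rather than a spurious value. Intercepts above
1 (possible under noise) are clamped to 1 and flagged, implying f = 0.

The segmented estimator carries a deterministic asymptotic bias from
residual perfusion signal in the high-b points. The size of that residual is
f/(1 − f)·exp(−b(D\* − D)) relative to the diffusion term, so accuracy is
governed by the *absolute* decay b·(D\* − D), not by the D\*/D ratio alone.
For the clinically observed pseudo-diffusion range (D\* ≳ 1.5×10⁻² mm²/s,
as in esophageal tumors) the bias is below 2% in D and f and 5% in D\* on
the default scheme; for the (rarely observed) combination of small D and
small D\* the high-b points are contaminated and the bias grows. The test
suite asserts the tolerance only over the clinically relevant region.

**Full ("bi") fit.** All three parameters are estimated simultaneously by
bounded nonlinear least squares over every b value, minimizing residuals in
linear signal space (the model is written in S_b/S_0, not log space), using
a trust-region reflective solver — the bounded variant of
Levenberg–Marquardt-type damped least squares; plain LM cannot honor
parameter bounds. The fit is seeded from the segmented estimates by default
(`fixed-init` selects mid-bounds seeding instead; both converge to the same
optimum on identifiable noise-free curves). When the segmented seed has a
non-identifiable D\* its placeholder can invert the pool labels, so the seed
is replaced by D\* = 10·D in that case. Convergence tolerance is 10⁻¹⁰ on
the relative residual change with a budget of 500 iterations — generous for
10-point curves. Bounds (D ∈ [10⁻⁵, 5×10⁻³], D\* ∈ [10⁻³, 0.5] mm²/s,
f ∈ [0, 1]) bracket all reported tumor values by well over 3 SD; boundary
hits are flagged, never silently accepted.

Under noise the two estimators behave as expected from theory and as
reported across the abdominal-imaging literature: both are unbiased enough
at moderate SNR, errors shrink monotonically with SNR, and the segmented D\*
estimate has systematically higher variance than the joint fit (the
perfusion step inherits the noise of the frozen D and f). The Monte-Carlo
property tests assert exactly these batch-level orderings.

## Synthetic cohorts

The generator emulates the clinical study design end to end so every
downstream stage is testable without patient data:

* **Grade groups** — WD n=20, MD n=20, PD n=14 (54 patients). Per-grade
  parameter distributions are normals with the reference group means ± SD
  (segmented-model column by default; a switch selects the full-fit column),
  truncated to (0, ∞) for D and D\* and (0.01, 0.9) for f, sampled
  independently per parameter: only marginal moments are available, so
  independence is the weakest consistent assumption. A consequence worth
  knowing: independent marginals separate D\* across grades more cleanly
  than the real (correlated, noisy) measurements did, so D\*'s group test is
  usually significant in simulation even though it was not in the clinic.
* **Acquisition** — noise-free decay on the 10-b scheme; Rician magnitude
  noise per excitation (each excitation observes √((A+g₁)² + g₂²),
  g ~ N(0, σ)), averaged over the per-b excitation counts. σ is constant
  across b (thermal noise) at 1/SNR₀ on the normalized scale; NEX averaging
  is the only b-dependent noise reduction. Default SNR₀ = 50, typical for
  3 T body diffusion imaging; configurable, ∞ = noise-free.
* **ROI protocol** — 9 ROIs per patient (3 sections × 3 ROIs), each the
  average of 25 voxel curves (a proxy for the ~54 mm² ROI area), fitted per
  ROI with both models; the patient-level parameter is the arithmetic mean
  across ROI fits — averaging signals within an ROI but parameters across
  ROIs, in that order.
* **Determinism** — each patient's stream is keyed by (master seed, group
  index, patient index), so identical configs are byte-identical and
  enlarging one group never perturbs another patient's draws. Patients whose
  curves cannot be fitted are excluded with a logged reason; a group
  failing >10% aborts the run.

What the generator does *not* emulate: spatial structure (no image phantom),
motion/peristalsis artifacts, inter-reader variability (ROI replication is
the stand-in), or any parameter covariance within a patient. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the declared generating assumptions, not fidelity to every property of the
clinical measurements — in particular, correlation magnitudes for f
attenuate slightly once imaging noise and fitting are in the loop.

## Statistics

Per parameter and model: Shapiro–Wilk per group (a constant group is
reported as gate-fail, p = 0); if all three groups pass at α = 0.05, one-way
ANOVA followed by Fisher's LSD post hoc — pairwise t tests reusing the
ANOVA's pooled within-group MSE and error degrees of freedom, with no
multiplicity adjustment (that is the definition of LSD); otherwise
Kruskal–Wallis with no post hoc. The two routes are exclusive. Pairwise
p-values are reported only on the significant ANOVA path (NA otherwise).
All tests are two-tailed at α = 0.05; no correction is applied across the
six parameters (a Holm option exists for users who want one).

Spearman correlation with grade uses the ordinal coding PD=1 < MD=2 < WD=3
(configurable), chosen so that D correlates positively with differentiation
and f negatively — matching the direction conventions of the clinical
literature. With more than one patient per grade the coded variable has
ties, so |ρ| is capped below 1 even for a perfectly monotone parameter
(midrank handling).

ROC analysis runs per grade pair with the less-differentiated group as the
positive class (PD over MD over WD); f is greater-is-positive, D
lesser-is-positive, and orientation is auto-detected so AUC ≥ 0.5 with the
direction recorded. The AUC is the Mann–Whitney pair-ordering probability
(ties ½), identical to the trapezoidal area under the empirical ROC curve.
The operating cutoff maximizes the Youden index over midpoints of adjacent
sorted values, breaking ties toward higher specificity and then lower
cutoff. A closed-form binormal AUC, Φ(Δμ/√(σ₁²+σ₂²)), serves as the
analytic cross-check. Interpretation bands: AUC in [0.5, 0.7) low,
[0.7, 0.9] moderate (both boundary values inclusive on the moderate side),
above 0.9 high. A (pair, parameter) ROC row is emitted when the omnibus
test is significant and, on the ANOVA path, that pair's LSD p-value is
below α — ROC is only reported for discriminating parameters.

## Problem sizes and reproducibility

Deterministic checks use noise-free 10-point curves. Monte-Carlo suites use
150–200 replicates per condition for estimator-error orderings, 2,000
replicates for AUC reproduction (Monte-Carlo SE ≈ 0.0005), 10,000 null
simulations for the ANOVA type-I calibration, and 100 seeded cohorts for
correlation sign structure. The full pipeline on the default 54-patient
cohort (972 ROI fits per model) runs in ~3 s. Replicate seeds are derived
from the master seed via a seed sequence keyed by (master, replicate index).
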