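# ivim-grade

Intravoxel incoherent motion (IVIM) diffusion-MRI modelling, fitting and
tumor-grade discrimination analysis.

## The problem

Diffusion-weighted MRI signal in perfused tissue decays bi-exponentially with
the diffusion weighting *b*:

```
S_b / S_0 = f · exp(−b·D*) + (1 − f) · exp(−b·D)
```

where *D* (mm²/s) is the true tissue diffusion coefficient, *D\** (mm²/s) the
pseudo-diffusion coefficient of the capillary (perfusion) pool — typically an
order of magnitude larger than *D* — and *f* the perfusion fraction, the
fast pool's share of the b = 0 signal. In esophageal squamous cell carcinoma
(ESCC), *f* rises and *D* falls as tumors dedifferentiate, so these
parameters can grade tumors (well / moderately / poorly differentiated: WD /
MD / PD) non-invasively.

Two competing estimation strategies exist, and their relative merit matters
clinically:

* **Segmented ("mono") fit** — above a b threshold (default 200 s/mm²) the
  perfusion pool has decayed and `S_b/S_0 ≈ (1 − f)·exp(−b·D)`; a log-linear
  fit of the high-b points gives *D*, the extrapolated b = 0 intercept gives
  *f* = 1 − intercept, and *D\** is then fitted alone with *D*, *f* fixed.
* **Full ("bi") fit** — simultaneous bounded nonlinear least squares of all
  three parameters over every b value.

This package implements both strategies, a synthetic cohort generator that
emulates the clinical study design (three grade groups of 20/20/14 patients,
a 10-b-value scheme `0, 30, 50, 80, 150, 200, 400, 600, 800, 1000 s/mm²`
with excitation counts `2,2,2,2,2,2,2,4,6,8`, Rician magnitude noise, 9 ROIs
per patient with parameter averaging), and the downstream statistics:
Shapiro–Wilk-gated one-way ANOVA with Fisher's LSD post hoc (or
Kruskal–Wallis), Spearman correlation with ordinal grade, and pairwise ROC
analysis with Youden-index cutoffs.

## Worked example

```python
from ivim_grade import *

truth = IVIMParams(D=1.05e-3, D_star=1.25e-2, f=0.32)   # poorly differentiated tumor
curve = ivim_signal_curve(truth, BValueScheme())

seg = fit_mono_segmented(curve)
full = fit_bi_full(curve)
print(f"segmented: D={seg.params.D:.3e}  D*={seg.params.D_star:.3e}  f={seg.params.f:.3f}")
print(f"full fit:  D={full.params.D:.3e}  D*={full.params.D_star:.3e}  f={full.params.f:.3f}")
```

```
segmented: D=1.057e-03  D*=1.276e-02  f=0.316
full fit:  D=1.050e-03  D*=1.250e-02  f=0.320
```

On a noise-free curve the full fit recovers the generating parameters to
optimizer precision, while the segmented fit carries a small, well-understood
asymptotic bias (here +0.7% in *D*, −0.004 in *f*) from residual perfusion
signal in the high-b points.

A full in-silico study — cohort simulation, per-ROI fitting with both models,
group comparison, correlation, ROC — is one call (or `ivim-grade reproduce`
on the command line):

```python
report = run_reproduction(RunConfig().with_seed(1))
```

Its report tables (means ± SD are on display scale, D in 10⁻³ mm²/s):

```
f_mono: WD 0.18+/-0.04  MD 0.22+/-0.09  PD 0.33+/-0.06  p=1.72e-07
PD vs WD, f_mono: cutoff=0.233  AUC=0.982  sens=0.93  spec=0.95  (high)
```

i.e. the perfusion fraction separates the grade groups strongly and
discriminates poorly from well differentiated tumors with high diagnostic
value — the qualitative clinical finding the simulation emulates.

### Command line

```
ivim-grade simulate  --config study.yaml --seed 17 --outdir runs/sim1
ivim-grade fit       --model both --b-threshold 200 --input curves.csv --output params.csv
ivim-grade analyze   --cohort runs/sim1/cohort.csv --outdir runs/sim1
ivim-grade reproduce --seed 1 --outdir runs/full
ivim-grade replicate --seed 1 --n 50 --outdir runs/mc
```

`fit` accepts external decay curves as CSV (`roi_id,b,signal`; raw
intensities are normalized by the b = 0 entry), so real measurements can be
analyzed alongside simulations.

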