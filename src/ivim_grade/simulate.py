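"""Synthetic esophageal-tumor cohorts with the study's statistical structure.

The generator emulates the data-generating process the grading analysis
assumes: three differentiation-grade groups (well / moderately / poorly
differentiated, WD n=20, MD n=20, PD n=14) with grade-specific IVIM parameter
distributions, signal decay sampled on the clinical 10-b-value scheme,
magnitude (Rician) noise reduced by per-b excitation averaging, and the
9-ROI-per-patient protocol (3 sections x 3 ROIs) in which voxel signals are
averaged into ROI curves, each ROI curve is fitted with both models, and the
patient-level parameter is the across-ROI mean of the fits.

Grade distributions default to the mono-model column of the reference group
statistics (means +/- SD); a switch selects the bi-model column. Parameters
are drawn independently per patient from normals truncated to their physical
ranges — only marginal moments are available, so independence is the weakest
consistent assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BValueScheme, IVIMParams, SignalCurve, ValidationError, ivim_signal
from .fitting import FitConfig, FitInfeasibleError, fit_bi_full, fit_mono_segmented

__all__ = [
    "GradeSpec",
    "CohortConfig",
    "Patient",
    "Cohort",
    "MONO_GRADE_SPECS",
    "BI_GRADE_SPECS",
    "GRADE_ORDER",
    "cohort_from_frame",
    "sample_truth",
    "add_rician_noise",
    "simulate_patient",
    "simulate_cohort",
]

GRADE_ORDER: tuple[str, ...] = ("WD", "MD", "PD")

_TRUNC_F = (0.01, 0.9)
_MAX_DRAWS = 1000


@dataclass(frozen=True)
class GradeSpec:
    """Group size and IVIM parameter moments for one differentiation grade.

    Means and SDs are (D, D*, f) in internal units (mm^2/s for the rates).
    """

    grade: str
    n: int
    param_means: tuple[float, float, float]
    param_sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("group size must be positive")
        if any(sd <= 0 for sd in self.param_sds):
            raise ValidationError("parameter SDs must be positive")


# Grade-group moments (mean, SD) of the reference cohort; D in mm^2/s.
# Mono-model (segmented-fit) column:
MONO_GRADE_SPECS: tuple[GradeSpec, ...] = (
    GradeSpec("WD", 20, (1.48e-3, 2.65e-2, 0.16), (0.51e-3, 1.96e-2, 0.05)),
    GradeSpec("MD", 20, (1.22e-3, 1.88e-2, 0.23), (0.39e-3, 1.26e-2, 0.08)),
    GradeSpec("PD", 14, (1.05e-3, 1.25e-2, 0.32), (0.44e-3, 0.56e-2, 0.07)),
)
# Bi-model (full-fit) column:
BI_GRADE_SPECS: tuple[GradeSpec, ...] = (
    GradeSpec("WD", 20, (1.33e-3, 2.82e-2, 0.18), (0.54e-3, 1.63e-2, 0.07)),
    GradeSpec("MD", 20, (1.17e-3, 2.21e-2, 0.26), (0.51e-3, 1.41e-2, 0.10)),
    GradeSpec("PD", 14, (0.91e-3, 1.67e-2, 0.35), (0.45e-3, 0.78e-2, 0.08)),
)


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated cohort.

    Attributes
    ----------
    grade_specs
        One GradeSpec per grade group.
    scheme
        Acquisition design (b values + NEX).
    snr0
        Signal-to-noise ratio at b=0 per single excitation; ``math.inf``
        means noise-free. Default 50, typical for 3T body DWI.
    rois_per_patient
        Regions of interest per patient (3 sections x 3 ROIs = 9).
    voxels_per_roi
        Voxel curves averaged into each ROI curve (proxy for the ~54 mm^2
        ROI area).
    param_source
        Which grade-moment column generated the truth ("mono" or "bi");
        informational echo for provenance.
    """

    grade_specs: tuple[GradeSpec, ...] = MONO_GRADE_SPECS
    scheme: BValueScheme = field(default_factory=BValueScheme)
    snr0: float = 50.0
    rois_per_patient: int = 9
    voxels_per_roi: int = 25
    seed: int = 0
    param_source: str = "mono"

    def __post_init__(self) -> None:
        if not self.snr0 > 0:
            raise ValidationError("snr0 must be positive")
        if self.rois_per_patient < 1 or self.voxels_per_roi < 1:
            raise ValidationError("rois_per_patient and voxels_per_roi must be >= 1")

    @property
    def sigma(self) -> float:
        """Per-excitation noise SD on the normalized signal scale."""
        return 0.0 if math.isinf(self.snr0) else 1.0 / self.snr0


@dataclass
class Patient:
    patient_id: str
    grade: str
    true_params: IVIMParams | None
    roi_curves: list[SignalCurve]
    fitted_mono: IVIMParams | None = None
    fitted_bi: IVIMParams | None = None
    roi_fits: list = field(default_factory=list)  # per-ROI FitResult, both models
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class Cohort:
    patients: list[Patient]
    config: CohortConfig
    seed: int

    def by_grade(self, grade: str) -> list[Patient]:
        return [p for p in self.patients if p.grade == grade and not p.excluded]

    def parameter_values(self, parameter: str, model_tag: str, grade: str) -> np.ndarray:
        """Per-patient fitted values of one parameter for one grade group."""
        attr = {"mono": "fitted_mono", "bi": "fitted_bi"}[model_tag]
        vals = [getattr(getattr(p, attr), parameter) for p in self.by_grade(grade)]
        return np.asarray(vals, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per patient per model (fitted parameters)."""
        rows = []
        for p in self.patients:
            if p.excluded:
                continue
            for tag, params in (("mono", p.fitted_mono), ("bi", p.fitted_bi)):
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "grade": p.grade,
                        "model": tag,
                        "D": params.D,
                        "D_star": params.D_star,
                        "f": params.f,
                    }
                )
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "grade": p.grade,
                    "D": p.true_params.D,
                    "D_star": p.true_params.D_star,
                    "f": p.true_params.f,
                }
                for p in self.patients
            ]
        )


def cohort_from_frame(df: pd.DataFrame, config: CohortConfig | None = None) -> Cohort:
    """Rebuild a Cohort from the long ``patient_id,grade,model,D,D_star,f``
    table written by :meth:`Cohort.to_frame` (ground truth not recoverable)."""
    required = {"patient_id", "grade", "model", "D", "D_star", "f"}
    if not required <= set(df.columns):
        raise ValidationError(f"cohort table requires columns {sorted(required)}")
    patients = []
    for pid, g in df.groupby("patient_id", sort=False):
        fitted = {}
        for _, row in g.iterrows():
            fitted[row["model"]] = IVIMParams(
                D=float(row["D"]), D_star=float(row["D_star"]), f=float(row["f"])
            )
        patients.append(
            Patient(
                patient_id=str(pid),
                grade=str(g["grade"].iloc[0]),
                true_params=None,
                roi_curves=[],
                fitted_mono=fitted.get("mono"),
                fitted_bi=fitted.get("bi"),
            )
        )
    return Cohort(patients=patients, config=config or CohortConfig(), seed=-1)


def sample_truth(spec: GradeSpec, rng: np.random.Generator) -> IVIMParams:
    """Draw one patient's true (D, D*, f) from truncated normals.

    D and D* are truncated to (0, inf), f to (0.01, 0.9); draws are rejected
    and resampled until valid, with a hard cap against infeasible specs.
    """
    means = np.asarray(spec.param_means)
    sds = np.asarray(spec.param_sds)
    out = np.full(3, np.nan)
    lo = np.array([0.0, 0.0, _TRUNC_F[0]])
    hi = np.array([np.inf, np.inf, _TRUNC_F[1]])
    for i in range(3):
        for _ in range(_MAX_DRAWS):
            x = rng.normal(means[i], sds[i])
            if lo[i] < x < hi[i]:
                out[i] = x
                break
        else:
            raise ValidationError(
                f"could not sample parameter {i} for grade {spec.grade} "
                f"within {_MAX_DRAWS} attempts"
            )
    return IVIMParams(D=float(out[0]), D_star=float(out[1]), f=float(out[2]))


def add_rician_noise(
    clean_signal, sigma: float, nex, rng: np.random.Generator
) -> np.ndarray | float:
    """Rician magnitude noise with NEX averaging.

    Each excitation observes ``sqrt((A + g1)^2 + g2^2)`` with g1, g2 ~
    N(0, sigma) — complex Gaussian channel noise after magnitude
    reconstruction; nex independent excitations are averaged. sigma is
    1/SNR0 on the normalized signal scale. Rician noise is biased upward
    (Rayleigh mean ``sigma*sqrt(pi/2)`` at zero signal), a real feature of
    magnitude MRI that averaging does not remove.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    A = np.asarray(clean_signal, dtype=float)
    nex_arr = np.asarray(nex, dtype=int)
    if np.any(nex_arr < 1):
        raise ValidationError("nex must be >= 1")
    if sigma == 0:
        return float(A) if A.ndim == 0 else A.copy()
    max_nex = int(nex_arr.max())
    g1 = rng.normal(0.0, sigma, size=(max_nex,) + A.shape)
    g2 = rng.normal(0.0, sigma, size=(max_nex,) + A.shape)
    draws = np.sqrt((A + g1) ** 2 + g2**2)
    # average only the first nex draws at each position
    mask = np.arange(max_nex).reshape((max_nex,) + (1,) * A.ndim) < nex_arr
    out = np.sum(draws * mask, axis=0) / nex_arr
    return float(out) if out.ndim == 0 else out


def _noisy_roi_curve(
    truth: IVIMParams, config: CohortConfig, rng: np.random.Generator
) -> SignalCurve:
    """Average voxel-level noisy decays into one ROI curve, renormalized at b=0."""
    clean = ivim_signal(truth, config.scheme.b_array)
    voxels = np.empty((config.voxels_per_roi, len(config.scheme)))
    for v in range(config.voxels_per_roi):
        voxels[v] = add_rician_noise(clean, config.sigma, config.scheme.nex, rng)
    roi = voxels.mean(axis=0)
    roi = roi / roi[0]
    return SignalCurve(config.scheme, tuple(roi.tolist()))


def _mean_params(results) -> IVIMParams:
    arr = np.array([r.params.as_tuple() for r in results])
    m = arr.mean(axis=0)
    return IVIMParams(D=float(m[0]), D_star=float(m[1]), f=float(m[2]))


def simulate_patient(
    spec: GradeSpec,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "p0",
    fit_config: FitConfig | None = None,
) -> Patient:
    """Simulate one patient: truth draw, ROI curves, both fits, ROI averaging."""
    fit_config = fit_config or FitConfig()
    truth = sample_truth(spec, rng)
    curves = [_noisy_roi_curve(truth, config, rng)
              for _ in range(config.rois_per_patient)]
    patient = Patient(patient_id, spec.grade, truth, curves)
    try:
        mono = [fit_mono_segmented(c, fit_config) for c in curves]
        bi = [fit_bi_full(c, fit_config) for c in curves]
    except FitInfeasibleError as exc:  # mirrors exclusion of unusable images
        patient.excluded = True
        patient.exclusion_reason = str(exc)
        return patient
    patient.fitted_mono = _mean_params(mono)
    patient.fitted_bi = _mean_params(bi)
    patient.roi_fits = mono + bi
    return patient


def simulate_cohort(config: CohortConfig, fit_config: FitConfig | None = None) -> Cohort:
    """Simulate the full cohort, deterministic given ``config.seed``.

    Each patient gets an independent random stream keyed by (seed, group
    index, patient index), so enlarging one group never perturbs the draws
    of any other patient.
    """
    patients: list[Patient] = []
    for gi, spec in enumerate(config.grade_specs):
        failures = 0
        for pi in range(spec.n):
            rng = np.random.default_rng([config.seed, gi, pi])
            pid = f"{spec.grade}-{pi + 1:02d}"
            p = simulate_patient(spec, config, rng, pid, fit_config)
            if p.excluded:
                failures += 1
            patients.append(p)
        if failures > 0.1 * spec.n:
            raise ValidationError(
                f"{failures}/{spec.n} patients failed fitting in group {spec.grade}"
            )
    return Cohort(patients=patients, config=config, seed=config.seed)
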