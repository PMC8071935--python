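import numpy as np
import pytest

from ivim_grade import (
    BValueScheme,
    CohortConfig,
    GradeSpec,
    IVIMParams,
    ivim_signal_curve,
    simulate_cohort,
)

# Reference grade-group mean parameters (D, D*, f in internal mm^2/s units)
WD_MONO = IVIMParams(1.48e-3, 2.65e-2, 0.16)
MD_MONO = IVIMParams(1.22e-3, 1.88e-2, 0.23)
PD_MONO = IVIMParams(1.05e-3, 1.25e-2, 0.32)
WD_BI = IVIMParams(1.33e-3, 2.82e-2, 0.18)
PD_BI = IVIMParams(0.91e-3, 1.67e-2, 0.35)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture(scope="session")
def wd_curve(scheme):
    """Noise-free decay curve at the WD-group segmented-model means."""
    return ivim_signal_curve(WD_MONO, scheme)


@pytest.fixture(scope="session")
def pd_curve(scheme):
    return ivim_signal_curve(PD_MONO, scheme)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A fast miniature cohort for structural / determinism tests."""
    specs = tuple(
        GradeSpec(g.grade, 3, g.param_means, g.param_sds)
        for g in CohortConfig().grade_specs
    )
    return CohortConfig(grade_specs=specs, rois_per_patient=3, voxels_per_roi=5, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort, shared across analysis tests."""
    return simulate_cohort(CohortConfig(seed=0))
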