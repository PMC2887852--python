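import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from perfcmr.curves import MYOCARDIAL_SEGMENT, SignalTimeCurve
from perfcmr.pipeline import PipelineConfig
from perfcmr.simulate import CohortSpec, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_curve(si, times=None, n_baseline=2, roi_id="roi", roi_kind=MYOCARDIAL_SEGMENT):
    """Handy constructor for small literal test curves (1 s spacing default)."""
    si = np.asarray(si, dtype=float)
    if times is None:
        times = np.arange(len(si), dtype=float)
    return SignalTimeCurve(
        roi_id=roi_id, roi_kind=roi_kind, times=np.asarray(times, float),
        si=si, n_baseline=n_baseline,
    )


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 8-patient cohort (6 CABG + 2 no-CAD) reused by pipeline/IO tests."""
    return simulate_cohort(CohortSpec(n_cabg=6, n_no_cad=2), seed=7)
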