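import numpy as np
import pytest

from manodrift import AnalysisParams, PressureStudy
from manodrift.swallow_metrics import Landmarks
from manodrift.synthetic_cohort import DriftModel, simulate_study


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def nem_study():
    """A drift-free normal-motility study (expensive; shared read-only)."""
    return simulate_study("nem", DriftModel.none(), seed=3)


@pytest.fixture(scope="session")
def nem_drift_study():
    """The same anatomy with default heterogeneous drift."""
    return simulate_study("nem", DriftModel(), seed=3)


@pytest.fixture(scope="session")
def toy_landmarks():
    """The simulator's standard geometry, for direct metric unit tests."""
    return Landmarks(
        ues_band=slice(2, 5),
        les_band=slice(29, 32),
        egj_sleeve=slice(29, 32),
        gastric=slice(32, 35),
        body_span=slice(5, 29),
    )


@pytest.fixture
def study_from():
    """Build a validated study around a raw pressure matrix."""

    def _build(P, fs=10.0, t_exit=None, onsets=(20.0,), **kw):
        P = np.asarray(P, dtype=float)
        duration = P.shape[1] / fs
        return PressureStudy(
            pressure=P,
            fs=fs,
            t_exit=duration - 1.0 if t_exit is None else t_exit,
            swallow_onsets=list(onsets),
            **kw,
        )

    return _build
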