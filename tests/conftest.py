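import numpy as np
import pytest

from ctgeval.records import CtgTrace
from ctgeval.synthetic import TraceGenParams, generate_clean_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(fhr, uc=None, delivery_time_s=None, case_id="t", uc_smoothed=False):
    fhr = np.asarray(fhr, dtype=float)
    if uc is None:
        uc = np.full(len(fhr), 20.0)
    if delivery_time_s is None:
        delivery_time_s = len(fhr) / 4
    return CtgTrace(
        case_id=case_id, fhr=fhr, uc=uc,
        delivery_time_s=delivery_time_s, uc_smoothed=uc_smoothed,
    )


@pytest.fixture
def flat_trace():
    """One-hour constant trace at 140 bpm, delivery at the end."""
    return make_trace(np.full(14400, 140.0), delivery_time_s=3600.0)


@pytest.fixture
def synthetic_trace():
    """Default generated trace with its ground-truth event ledger."""
    params = TraceGenParams()
    return generate_clean_trace(params, seed=7)
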