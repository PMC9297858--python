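import numpy as np
import pytest

from ictalscope.traces import DffTrace, TraceMatrix


def make_trace(values, rate=4.0, labels=None, regions=None) -> TraceMatrix:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, m = values.shape
    labels = labels or [f"roi{j}" for j in range(m)]
    return TraceMatrix(
        time=np.arange(n) / rate,
        values=values,
        sampling_rate=rate,
        roi_labels=labels,
        region_of=regions,
    )


def make_dff(values, rate=4.0, labels=None, regions=None) -> DffTrace:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, m = values.shape
    labels = labels or [f"roi{j}" for j in range(m)]
    return DffTrace(
        time=np.arange(n) / rate,
        dff=values,
        baseline=np.ones(m),
        method="whole_trace_percentile",
        sampling_rate=rate,
        roi_labels=labels,
        region_of=regions,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
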