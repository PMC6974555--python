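import numpy as np
import pytest

from cvhrisk.rr_io import BeatSeries


def make_series(
    rr_ms,
    labels=None,
    clock_start=0.0,
    patient_id="test",
    start_offset_s=0.0,
):
    """BeatSeries from a list of RR intervals (beat times = cumulative RR)."""
    rr = np.asarray(rr_ms, dtype=float)
    times = start_offset_s + np.cumsum(rr) / 1000.0
    if labels is None:
        labels = ["N"] * len(rr)
    return BeatSeries(
        patient_id=patient_id,
        clock_start=clock_start,
        beat_times=times,
        rr_ms=rr,
        labels=np.asarray(labels),
    )


@pytest.fixture
def series_factory():
    return make_series
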