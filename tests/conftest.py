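import numpy as np
import pytest

from retinads.tuning import SpikeResponseSet, TuningCurve

DIRECTIONS = tuple(float(d) for d in range(0, 360, 30))


def make_curve(counts, phase="ALL"):
    return TuningCurve(np.array(DIRECTIONS), np.asarray(counts, dtype=float), phase=phase)


def make_response_set(counts_by_dir, contrast=300.0, n_trials=8, spike_time=0.5,
                      trial_duration=3.0, cell_id="c0"):
    """Response set with a fixed total count per direction, spikes at one time.

    Counts are split across trials as evenly as possible.
    """
    rs = SpikeResponseSet(trial_duration)
    for d, total in zip(DIRECTIONS, counts_by_dir):
        per_trial = [total // n_trials + (1 if k < total % n_trials else 0) for k in range(n_trials)]
        rs.add(cell_id, d, contrast, [np.full(m, spike_time) for m in per_trial])
    return rs


@pytest.fixture
def directions():
    return np.array(DIRECTIONS)
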