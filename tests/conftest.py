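import logging

import numpy as np
import pytest

from mbcensor.io_formats import MotionTrace, RunTimeseries
from mbcensor.synth import SimRun, SynthConfig, simulate_dataset

logging.getLogger("mbcensor").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """12-subject, 2-run synthetic cohort with motion-coupled artifact."""
    cfg = SynthConfig(n_subjects=12, runs_per_subject=2, T=300, n_roi=6, seed=9)
    return simulate_dataset(cfg)


def make_toy_run(T=120, n_roi=3, tr=0.72, seed=0):
    """Hand-built run (below the synthetic generator's minimum length)
    for brute-force pipeline oracles."""
    rng = np.random.default_rng(seed)
    mp = MotionTrace(rng.normal(0, 0.02, (T, 6)), tr=tr)
    roi = rng.standard_normal((n_roi, T)).cumsum(axis=1) * 0.1 + rng.standard_normal((n_roi, T))
    ts = RunTimeseries(roi, tr=tr, nuisance={"GS": roi.mean(axis=0)})
    return SimRun(motion=mp, ts=ts)
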