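"""Shared fixtures: small synthetic sessions generated once per test run.

Heavy simulations shorten the inter-trial interval to (2.5, 3.5) s — the
ITI contributes only dead frames to every analysis here, so this scales
runtime without touching any measured quantity. Trial counts, epoch
durations, sampling rate and planted effect sizes keep their defaults.
"""

import numpy as np
import pytest

from popact import preprocess as pp
from popact.synth import SimConfig, generate_session, plant_ground_truth

FAST_ITI = (2.5, 3.5)

ZERO_COHERENCE = {p: 0.0 for p in
                  ("initial-naive", "initial-expert",
                   "reversal-naive", "reversal-expert")}


def fast_config(**kwargs) -> SimConfig:
    kwargs.setdefault("iti_range_s", FAST_ITI)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def task_bundle():
    """One mixed-class expert session used by read-only tests."""
    cfg = fast_config(n_cells=60)
    return cfg, generate_session(cfg, "initial-expert", seed=11)


@pytest.fixture(scope="session")
def conditioned_bundle(task_bundle):
    cfg, (rec, trials, behav, gt) = task_bundle
    traces = pp.preprocess_session(rec)
    return cfg, rec, trials, behav, gt, traces
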