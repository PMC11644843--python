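import numpy as np
import pandas as pd
import pytest

from ethoval import (
    BehaviorStream,
    ChannelConfig,
    DurationDistribution,
    MinuteLabelSeries,
    SimulationConfig,
)
from ethoval.series import DEFAULT_START


@pytest.fixture
def start():
    return DEFAULT_START


@pytest.fixture
def small_sim_config():
    """Short two-channel simulation used where only structure matters."""
    return SimulationConfig(
        duration_s=3600 * 10,
        seed=7,
        channels={
            "lying": ChannelConfig(
                bout_duration_dist=DurationDistribution.lognormal(45.0, 0.5),
                target_prevalence=0.25,
            ),
            "rumination": ChannelConfig(
                bout_duration_dist=DurationDistribution.lognormal(30.0, 0.5),
                target_prevalence=0.12,
                lying_coupling=2.0,
            ),
        },
    )


def make_minutes(labels, channel="rumination", start=DEFAULT_START):
    return MinuteLabelSeries(start, np.asarray(labels, dtype=float), channel)


def make_stream(labels, channel="lying", start=DEFAULT_START):
    return BehaviorStream(start, np.asarray(labels, dtype=float), channel)


@pytest.fixture
def minutes_factory():
    return make_minutes


@pytest.fixture
def stream_factory():
    return make_stream
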