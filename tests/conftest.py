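"""Shared fixtures: small synthetic sessions reused across test modules."""

import pytest

from oddball import (attach_light_schedule, build_oddball_pair,
                     make_scenario, simulate_spike_trains)
from oddball.spikes import count_tone_windows


@pytest.fixture(scope="session")
def oddball_pair():
    """The standard 653-tone, 10%-deviant counterbalanced pair."""
    return build_oddball_pair(653, 0.1, seed=7)


@pytest.fixture(scope="session")
def light(oddball_pair):
    return attach_light_schedule(oddball_pair[0])


@pytest.fixture(scope="session")
def pv_flat_spikes(oddball_pair, light):
    """A 20-neuron PV flat-scenario spike set (fast, reused read-only)."""
    scenario = make_scenario("PV", "flat")
    return simulate_spike_trains(scenario, oddball_pair, light,
                                 n_neurons=20, n_reps=4, seed=11)


@pytest.fixture(scope="session")
def pv_flat_counts(pv_flat_spikes):
    return count_tone_windows(pv_flat_spikes)
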