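"""Scenario rate tables parameterizing the synthetic spike generator.

A scenario encodes, for one experimental group (PV-Cre, SOM-Cre, or control),
the per-tone firing rate of a homogeneous population of putative excitatory
neurons as a function of the tone's probability condition (spontaneous window,
standard, deviant, equal) and the optogenetic light state.  The flat tables
are constructed so that the light-on/light-off percent changes, and the
implied drop in population SSA index, equal the effect sizes the analyses are
expected to recover:

* PV suppression: spontaneous +185%, standard +102%, deviant +56%,
  SSA index change -41%;
* SOM suppression: spontaneous +46%, standard +29%, deviant +0%,
  SSA index change -25%;
* control (reporter only): no light effect anywhere.

Given the deviant rate D and the on/off rate multipliers a (standard) and b
(deviant), the standard/deviant ratio x = S/D that yields a relative SSA
change c solves the quadratic obtained from
``(b - a x)/(b + a x) = (1 + c)(1 - x)/(1 + x)``; for the PV table
(a=2.02, b=1.56, c=-0.41) x = 0.5419 and for the SOM table (a=1.29, b=1.00,
c=-0.25) x = 0.3940, giving the rate tables below with D fixed at 10 Hz.

*Dynamic* mode adds the time-course structure measured within the oddball
sequence: elevated standard responses immediately after each deviant
(+60% at T1, +26% at T2 relative to the steady state T4) and an onset
adaptation in which the standard response decays from twice its steady-state
value over roughly the first 20 standard tones.  Flat mode zeroes both so the
probability-condition effect sizes are exact in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONDITIONS = ("spontaneous", "standard", "deviant", "equal")

#: steady-state Hz, (light-off, light-on); see module docstring for derivation
_FLAT_TABLES = {
    "PV": {
        "spontaneous": (2.00, 5.70),
        "standard": (5.42, 10.95),
        "deviant": (10.00, 15.60),
        "equal": (7.00, 9.87),
    },
    "SOM": {
        "spontaneous": (2.00, 2.92),
        "standard": (3.94, 5.08),
        "deviant": (10.00, 10.00),
        "equal": (6.00, 7.02),
    },
    "control": {
        "spontaneous": (2.00, 2.00),
        "standard": (5.42, 5.42),
        "deviant": (10.00, 10.00),
        "equal": (7.00, 7.00),
    },
}

#: multiplicative gain on the standard rate at positions T1..T4 after a deviant
_POST_DEVIANT_GAIN = {1: 1.60, 2: 1.26, 3: 1.00, 4: 1.00}


@dataclass
class ScenarioRates:
    """Condition x light rate table for one synthetic experimental group.

    Attributes
    ----------
    name : {"PV", "SOM", "control"}
    mode : {"flat", "dynamic"}
        Flat tables have no within-sequence time course; dynamic tables add
        post-deviant elevation of the standard response and onset adaptation.
    table : dict
        ``condition -> (rate_off_hz, rate_on_hz)``.
    post_deviant_gain : dict
        ``position (1..4) -> gain`` on the standard rate (1.0 in flat mode).
    onset_n_to_steady : int
        Number of standards over which the onset elevation decays.
    onset_initial_gain : float
        Standard-rate gain at the very first tone (1.0 in flat mode).
    """

    name: str
    mode: str = "flat"
    table: dict = field(default_factory=dict)
    post_deviant_gain: dict = field(default_factory=dict)
    onset_n_to_steady: int = 20
    onset_initial_gain: float = 1.0
    #: optional per-neuron multiplicative rate jitter SD (0 = homogeneous)
    rate_jitter_sd: float = 0.0

    def rate(self, condition: str, light: bool) -> float:
        off, on = self.table[condition]
        return on if light else off

    def __post_init__(self):
        for cond, (off, on) in self.table.items():
            if off < 0 or on < 0:
                raise ValueError(f"negative rate for {cond}")


def make_scenario(name: str, mode: str = "flat") -> ScenarioRates:
    """Return the canonical rate table for an experimental group.

    Parameters
    ----------
    name : {"PV", "SOM", "control"}
    mode : {"flat", "dynamic"}

    Returns
    -------
    ScenarioRates
    """
    if name not in _FLAT_TABLES:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{sorted(_FLAT_TABLES)}")
    if mode not in ("flat", "dynamic"):
        raise ValueError(f"unknown mode {mode!r}; choose 'flat' or 'dynamic'")
    table = {c: tuple(v) for c, v in _FLAT_TABLES[name].items()}
    if mode == "flat":
        return ScenarioRates(name=name, mode="flat", table=table,
                             post_deviant_gain={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
                             onset_initial_gain=1.0)
    return ScenarioRates(name=name, mode="dynamic", table=table,
                         post_deviant_gain=dict(_POST_DEVIANT_GAIN),
                         onset_n_to_steady=20, onset_initial_gain=2.0)
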