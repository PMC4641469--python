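"""Synthetic electrophysiology: Poisson spike trains and laminar LFP sessions.

The spike generator emulates a homogeneous population of putative excitatory
units recorded during oddball stimulation with interleaved optogenetic light
pulses.  Per tone, the spike count in the 50-ms response window is Poisson
with mean ``rate x 0.05 s``, where the rate comes from a
:class:`~oddball.scenarios.ScenarioRates` table indexed by the tone's
probability condition and light state; spontaneous spikes fill the 50-ms
pre-tone window the same way.  Spike times are uniform within their window
(the downstream analyses consume only counts).  In dynamic mode the standard
rate additionally carries post-deviant elevation and onset adaptation gains.

The LFP generator emulates a laminar probe session: each tone evokes a
voltage profile whose second spatial derivative is a single short-latency
current sink (negative basin) centred on a configurable granular channel
band, with sink amplitude adapting with tone probability
(deviant > standard) plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .scenarios import ScenarioRates
from .stimulus import LightSchedule, ToneSequence

EVOKED_WINDOW_MS = 50
SPONT_WINDOW_MS = 50


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrainSet:
    """Per-neuron, per-repetition spike trains aligned to a stimulus pair.

    ``spike_times[(neuron, seq_idx, rep)]`` is a sorted float array of spike
    times in ms relative to the start of that sequence presentation.
    """

    n_neurons: int
    n_reps: int
    sequences: list[ToneSequence]
    light: LightSchedule
    spike_times: dict = field(default_factory=dict, repr=False)
    scenario_name: str = ""
    seed: int = 0
    layers: list[str] = field(default_factory=list)

    def neurons(self) -> range:
        return range(self.n_neurons)

    def train(self, neuron: int, seq_idx: int, rep: int) -> np.ndarray:
        return self.spike_times[(neuron, seq_idx, rep)]

    def to_frame(self) -> pd.DataFrame:
        """Long event table (neuron, seq, rep, time_ms)."""
        rows = []
        for (neuron, s, rep), t in sorted(self.spike_times.items()):
            rows.append(pd.DataFrame({
                "neuron": neuron, "seq": s, "rep": rep, "time_ms": t}))
        if not rows:
            return pd.DataFrame(columns=["neuron", "seq", "rep", "time_ms"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sequences: list[ToneSequence],
                   light: LightSchedule, n_neurons: int,
                   n_reps: int) -> "SpikeTrainSet":
        sts = cls(n_neurons=n_neurons, n_reps=n_reps, sequences=sequences,
                  light=light)
        grouped = frame.groupby(["neuron", "seq", "rep"])["time_ms"]
        for n in range(n_neurons):
            for s in range(len(sequences)):
                for r in range(n_reps):
                    try:
                        t = np.sort(grouped.get_group((n, s, r)).to_numpy(float))
                    except KeyError:
                        t = np.empty(0)
                    sts.spike_times[(n, s, r)] = t
        return sts


def standard_rate_gains(seq: ToneSequence, scenario: ScenarioRates) -> np.ndarray:
    """Per-tone multiplicative gain on the standard rate (1.0 for non-standards).

    Dynamic mode composes two effects seen within real oddball sequences:

    * post-deviant elevation -- the first standards after each deviant are
      elevated (T1 +60%, T2 +26%, back to steady state by T3/T4);
    * onset adaptation -- the standard response starts at
      ``onset_initial_gain`` times the steady state and decays exponentially
      over the first ``onset_n_to_steady`` standards.
    """
    roles = seq.roles()
    n = len(roles)
    gains = np.ones(n)
    if scenario.mode == "flat":
        return gains
    # position after the most recent deviant (0 at the deviant itself)
    pos_after = np.full(n, np.inf)
    last_dev = None
    std_counter = 0
    tau = scenario.onset_n_to_steady / 3.0  # ~5% residual at n_to_steady
    for i in range(n):
        if roles[i] == "deviant":
            last_dev = i
            continue
        if roles[i] != "standard":
            continue
        g = 1.0
        if last_dev is not None:
            pos = i - last_dev
            pos_after[i] = pos
            g *= scenario.post_deviant_gain.get(pos, 1.0)
        g *= 1.0 + (scenario.onset_initial_gain - 1.0) * np.exp(-std_counter / tau)
        std_counter += 1
        gains[i] = g
    return gains


def tone_rates(seq: ToneSequence, light: LightSchedule,
               scenario: ScenarioRates) -> tuple[np.ndarray, np.ndarray]:
    """Expected (evoked, spontaneous) rate in Hz for every tone of ``seq``.

    The spontaneous window precedes tone onset; because the light pulse
    starts 100 ms before onset, lit tones have light-on spontaneous windows.
    """
    roles = seq.roles()
    lit = light.lit_mask(seq.n_tones)
    gains = standard_rate_gains(seq, scenario)
    evoked = np.array([scenario.rate(role, bool(l))
                       for role, l in zip(roles, lit)]) * gains
    spont = np.array([scenario.rate("spontaneous", bool(l)) for l in lit])
    return evoked, spont


def simulate_spike_trains(scenario: ScenarioRates,
                          sequences: tuple[ToneSequence, ...] | list[ToneSequence],
                          light: LightSchedule, n_neurons: int, n_reps: int = 4,
                          seed: int = 0) -> SpikeTrainSet:
    """Draw Poisson spike trains for a population of synthetic neurons.

    Parameters
    ----------
    scenario : ScenarioRates
        Rate table (see :func:`oddball.scenarios.make_scenario`).
    sequences : sequence of ToneSequence
        Typically the counterbalanced oddball pair; an equal-probability
        sequence may be appended.
    light : LightSchedule
        Shared light schedule (every k-th tone).
    n_neurons, n_reps : int
        Population size and number of interleaved repetitions (4 in the
        emulated protocol).
    seed : int
        Seeds a single generator for the whole set.
    """
    if n_neurons < 1 or n_reps < 1:
        raise ValueError("n_neurons and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    sts = SpikeTrainSet(n_neurons=n_neurons, n_reps=n_reps,
                        sequences=list(sequences), light=light,
                        scenario_name=scenario.name, seed=seed,
                        layers=["unassigned"] * n_neurons)
    jitter = np.ones(n_neurons)
    if scenario.rate_jitter_sd > 0:
        jitter = np.exp(rng.normal(0.0, scenario.rate_jitter_sd, n_neurons))
        jitter /= jitter.mean()
    w = EVOKED_WINDOW_MS / 1000.0
    for s, seq in enumerate(sequences):
        evoked_hz, spont_hz = tone_rates(seq, light, scenario)
        onsets = seq.onsets().astype(float)
        win_starts = np.concatenate([onsets - SPONT_WINDOW_MS, onsets])
        win_rates = np.concatenate([spont_hz, evoked_hz])
        win_len = np.concatenate([np.full(len(onsets), float(SPONT_WINDOW_MS)),
                                  np.full(len(onsets), float(EVOKED_WINDOW_MS))])
        for rep in range(n_reps):
            # counts for all neurons x windows in one draw
            lam = np.outer(jitter, win_rates) * w
            counts = rng.poisson(lam)
            for n in range(n_neurons):
                c = counts[n]
                starts = np.repeat(win_starts, c)
                lens = np.repeat(win_len, c)
                t = starts + rng.random(starts.size) * lens
                sts.spike_times[(n, s, rep)] = np.sort(t)
    return sts


# ---------------------------------------------------------------------------
# laminar LFP sessions
# ---------------------------------------------------------------------------

@dataclass
class LFPSession:
    """Laminar LFP aligned to tone onsets.

    Attributes
    ----------
    voltages : ndarray, shape (n_channels, n_time, n_trials), uV
    channel_depths : ndarray, um, strictly increasing with uniform spacing
    sampling_rate : float, Hz
    times : ndarray, ms relative to tone onset
    trial_condition : ndarray of str, probability role per trial
    trial_light : ndarray of bool
    """

    voltages: np.ndarray
    channel_depths: np.ndarray
    sampling_rate: float
    times: np.ndarray
    trial_condition: np.ndarray
    trial_light: np.ndarray
    granular_band: tuple[int, int] | None = None  # ground truth, CSD indexing

    def __post_init__(self):
        dz = np.diff(self.channel_depths)
        if not (np.all(dz > 0) and np.allclose(dz, dz[0])):
            raise ValueError("channel depths must be strictly increasing "
                             "with uniform spacing")

    @property
    def spacing_um(self) -> float:
        return float(self.channel_depths[1] - self.channel_depths[0])

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("voltages", data=self.voltages)
            f.create_dataset("depths", data=self.channel_depths)
            f.create_dataset("times", data=self.times)
            f.create_dataset("trial_condition",
                             data=np.char.encode(self.trial_condition.astype(str)))
            f.create_dataset("trial_light", data=self.trial_light)
            f.attrs["sampling_rate"] = self.sampling_rate
            if self.granular_band is not None:
                f.attrs["granular_band"] = self.granular_band

    @classmethod
    def load_h5(cls, path) -> "LFPSession":
        with h5py.File(path, "r") as f:
            band = f.attrs.get("granular_band")
            return cls(
                voltages=f["voltages"][:],
                channel_depths=f["depths"][:],
                sampling_rate=float(f.attrs["sampling_rate"]),
                times=f["times"][:],
                trial_condition=np.char.decode(f["trial_condition"][:]),
                trial_light=f["trial_light"][:].astype(bool),
                granular_band=tuple(int(b) for b in band) if band is not None else None,
            )


def _sink_time_course(times_ms: np.ndarray, onset_ms: float = 5.0,
                      tau_rise: float = 3.0, tau_decay: float = 15.0) -> np.ndarray:
    """Unit-peak difference-of-exponentials confined to short latencies."""
    t = times_ms - onset_ms
    h = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    peak = h.max()
    return h / peak if peak > 0 else h


def simulate_lfp_session(scenario: ScenarioRates, seq: ToneSequence,
                         n_channels: int = 32, spacing_um: float = 25.0,
                         seed: int = 0, granular_band: tuple[int, int] = (14, 18),
                         peak_amplitude_uv: float = 30.0,
                         dev_std_amp_ratio: float = 1.5974,
                         noise_sd_uv: float = 1.5,
                         sampling_rate: float = 1000.0) -> LFPSession:
    """Simulate one laminar LFP session driven by a tone sequence.

    Each tone contributes a separable space x time voltage deflection whose
    second spatial derivative is a single negative basin (current sink)
    covering exactly the channels of ``granular_band`` (indices into the CSD
    profile, i.e. LFP channels 1..n-2 after edge-dropping).  The sink
    amplitude for a standard tone is the deviant amplitude divided by
    ``dev_std_amp_ratio``; the default ratio 1.5974 makes the granular CSD
    SSA index (r-1)/(r+1) = 0.23.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    lo, hi = granular_band
    if not (0 <= lo <= hi <= n_channels - 3):
        raise ValueError(f"granular band {granular_band} outside the usable "
                         f"CSD channel range 0..{n_channels - 3}")
    rng = np.random.default_rng(seed)
    depths = np.arange(n_channels) * spacing_um
    times = np.arange(-50.0, 150.0, 1000.0 / sampling_rate)
    # Gaussian depth profile: its second difference is negative for channels
    # within ~one sigma of the centre, so sigma is set between the half-width
    # of the band and the half-width plus one channel.
    # CSD channel j maps to LFP channel j+1 (edge channels are dropped)
    centre_depth = (depths[lo + 1] + depths[hi + 1]) / 2.0
    sigma = ((hi - lo) / 2.0 + 0.5) * spacing_um
    g = np.exp(-0.5 * ((depths - centre_depth) / sigma) ** 2)
    h = _sink_time_course(times)
    amp = {
        "deviant": peak_amplitude_uv,
        "standard": peak_amplitude_uv / dev_std_amp_ratio,
        "equal": 2.0 * peak_amplitude_uv / (1.0 + dev_std_amp_ratio),
    }
    roles = seq.roles()
    n_trials = len(roles)
    # a positive Gaussian bump in depth has a negative second spatial
    # derivative (sink) at its centre and positive flanks (sources)
    kernel = np.outer(g, h)
    trial_amps = np.array([amp[r] for r in roles])
    voltages = kernel[:, :, None] * trial_amps[None, None, :]
    if noise_sd_uv > 0:
        voltages = voltages + rng.normal(0.0, noise_sd_uv, voltages.shape)
    from .stimulus import attach_light_schedule
    lit = attach_light_schedule(seq).lit_mask(seq.n_tones)
    return LFPSession(voltages=voltages, channel_depths=depths,
                      sampling_rate=sampling_rate, times=times,
                      trial_condition=roles, trial_light=lit[:n_trials],
                      granular_band=(lo, hi))
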