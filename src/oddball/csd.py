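"""Current source density analysis of laminar LFP.

The CSD is the second spatial derivative of the LFP along the probe,
computed with the second-order central finite difference; negative values
are current sinks (net inward current).  The short-latency sink marks the
thalamo-recipient granular layer; layers above and below are the
supra-granular and infra-granular layers.  Layer amplitudes are the
per-channel RMS over the first 50 ms after tone onset averaged across the
layer's channels, normalized within a session by the deviant light-off
value, and the SSA index of the granular sink is the usual
(deviant - standard)/(deviant + standard) on those amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spikes import ssa_index
from .synth import LFPSession


@dataclass
class CSDProfile:
    """Second spatial derivative of a laminar LFP session.

    ``values`` has shape (n_channels - 2, n_time, n_trials) in uV per
    ``spacing_um**2``-scaled units (uV/um^2); channel i of the profile is
    interior channel i+1 of the LFP.
    """

    values: np.ndarray
    depths: np.ndarray  # interior channel depths, um
    times: np.ndarray  # ms relative to tone onset
    spacing_um: float
    trial_condition: np.ndarray
    trial_light: np.ndarray

    def condition_mean(self, condition: str,
                       light: bool | None = None) -> np.ndarray:
        """Trial-averaged CSD (channels x time) for one condition."""
        mask = self.trial_condition == condition
        if light is not None:
            mask &= self.trial_light == light
        if not mask.any():
            raise ValueError(f"no trials for condition {condition!r}")
        return self.values[:, :, mask].mean(axis=2)


@dataclass
class LayerAssignment:
    """Partition of usable (interior) channels into cortical layers."""

    granular: tuple[int, int]  # inclusive channel range, CSD indexing
    supragranular: tuple[int, int] | None
    infragranular: tuple[int, int] | None

    def channels(self, layer: str) -> np.ndarray:
        rng = getattr(self, layer)
        if rng is None:
            return np.array([], dtype=int)
        return np.arange(rng[0], rng[1] + 1)


def compute_csd(lfp: LFPSession) -> CSDProfile:
    """Second-order central finite difference across channels.

    ``CSD_i(t) = (V_{i-1} - 2 V_i + V_{i+1}) / dz^2`` for interior channels;
    the two edge channels are dropped rather than padded.
    """
    v = lfp.voltages
    if v.shape[0] < 3:
        raise ValueError("need at least 3 channels for a second difference")
    dz = lfp.spacing_um
    csd = (v[:-2] - 2.0 * v[1:-1] + v[2:]) / dz**2
    return CSDProfile(values=csd, depths=lfp.channel_depths[1:-1],
                      times=lfp.times, spacing_um=dz,
                      trial_condition=lfp.trial_condition,
                      trial_light=lfp.trial_light)


def locate_granular_sink(csd: CSDProfile,
                         latency_window: tuple[float, float] = (0.0, 50.0),
                         threshold_sd: float = 2.0,
                         condition: str = "deviant") -> LayerAssignment:
    """Find the granular layer from the short-latency sink.

    The granular band is the contiguous run of channels around the most
    negative trough of the trial-averaged deviant CSD within the latency
    window, extended while the channel's window-mean CSD stays below
    ``-threshold_sd`` standard errors of the pre-onset baseline.  The
    largest-magnitude trough is used (the "deepest" sink in the sense of
    sink strength); layers above and below become supra-/infra-granular.
    """
    mean_csd = csd.condition_mean(condition)
    in_win = (csd.times >= latency_window[0]) & (csd.times < latency_window[1])
    baseline = (csd.times >= csd.times[0]) & (csd.times < 0)
    if not in_win.any():
        raise ValueError("latency window contains no samples")
    win_mean = mean_csd[:, in_win].mean(axis=1)
    if baseline.any():
        base_sd = mean_csd[:, baseline].std(ddof=0)
        base_se = base_sd / np.sqrt(in_win.sum())
    else:
        base_se = 0.0
    threshold = -threshold_sd * base_se
    trough_ch = int(np.argmin(mean_csd[:, in_win].min(axis=1)))
    if win_mean[trough_ch] >= min(threshold, 0.0) or (
            base_se == 0.0 and win_mean[trough_ch] >= 0.0):
        raise ValueError("no sink: no channel falls below the baseline "
                         "threshold in the latency window")
    lo = trough_ch
    while lo - 1 >= 0 and win_mean[lo - 1] < threshold:
        lo -= 1
    hi = trough_ch
    n_ch = mean_csd.shape[0]
    while hi + 1 < n_ch and win_mean[hi + 1] < threshold:
        hi += 1
    supra = (0, lo - 1) if lo > 0 else None
    infra = (hi + 1, n_ch - 1) if hi < n_ch - 1 else None
    return LayerAssignment(granular=(lo, hi), supragranular=supra,
                           infragranular=infra)


def layer_amplitude(csd: CSDProfile, layers: LayerAssignment,
                    window: tuple[float, float] = (0.0, 50.0),
                    normalize: bool = True,
                    debias: bool = True) -> pd.DataFrame:
    """Per-layer, per-condition CSD amplitude.

    Amplitude is the RMS of each channel's trial-averaged CSD over the
    window, then the mean across the layer's channels.  With ``debias``
    the residual noise power left by trial averaging -- estimated per
    channel from the pre-onset baseline -- is subtracted from the window
    power before the square root, so amplitudes of conditions with very
    different trial counts (deviant vs standard) stay comparable.  With
    ``normalize`` the session's values are divided by the deviant
    light-off amplitude of the same layer.
    """
    in_win = (csd.times >= window[0]) & (csd.times < window[1])
    in_base = csd.times < 0
    conditions = sorted(set(csd.trial_condition))
    rows = []
    for layer in ("supragranular", "granular", "infragranular"):
        ch = layers.channels(layer)
        for cond in conditions:
            for light in (False, True):
                mask = (csd.trial_condition == cond) & (csd.trial_light == light)
                if ch.size == 0 or not mask.any():
                    rows.append({"layer": layer, "condition": cond,
                                 "light": light, "amplitude": np.nan,
                                 "flag": "empty layer" if ch.size == 0
                                         else "no trials"})
                    continue
                m = csd.values[:, :, mask].mean(axis=2)
                power = (m[np.ix_(ch, in_win)] ** 2).mean(axis=1)
                if debias and in_base.any():
                    power = power - (m[np.ix_(ch, in_base)] ** 2).mean(axis=1)
                rms = np.sqrt(np.maximum(power, 0.0))
                rows.append({"layer": layer, "condition": cond, "light": light,
                             "amplitude": float(rms.mean()), "flag": ""})
    df = pd.DataFrame(rows)
    if normalize:
        for layer in df["layer"].unique():
            sel = (df["layer"] == layer)
            ref_row = df[sel & (df["condition"] == "deviant")
                         & (~df["light"])]["amplitude"]
            if len(ref_row) and ref_row.iloc[0] > 0:
                df.loc[sel, "normalized"] = df.loc[sel, "amplitude"] / ref_row.iloc[0]
            else:
                df.loc[sel, "normalized"] = np.nan
    return df


def csd_ssa(amplitudes: pd.DataFrame, layer: str = "granular",
            light: bool = False) -> float:
    """SSA index of a layer's CSD amplitudes (pooled over tones).

    Applies the spiking SSA formula to the deviant and standard amplitudes;
    NaN (flagged undefined) when both are zero.
    """
    sel = amplitudes[(amplitudes["layer"] == layer)
                     & (amplitudes["light"] == light)]
    dev = sel[sel["condition"] == "deviant"]["amplitude"]
    std = sel[sel["condition"] == "standard"]["amplitude"]
    if dev.empty or std.empty:
        raise ValueError(f"missing deviant or standard amplitude for {layer}")
    d, s = float(dev.iloc[0]), float(std.iloc[0])
    if d < 0 or s < 0:
        raise ValueError("amplitudes must be non-negative")
    # pooled over tones: same formula with D_A + D_B replaced by the pooled D
    return ssa_index(d, 0.0, s, 0.0)
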