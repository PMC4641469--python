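"""Spike-train statistics for oddball experiments.

Everything downstream of raw spike times lives here: firing-rate windows,
PSTHs, normalization, the SSA index, inclusion criteria, population
light-effect summaries, post-deviant / post-light time courses, matched
subsets and strong/weak tone pooling.

Conventions
-----------
* All analysis windows are half-open ``[start, start + len)``; a spike
  exactly on a boundary belongs to the later window.
* The evoked window is the 50 ms from tone onset (putative excitatory
  units); identified interneurons use 100 ms, exposed via ``window_ms``
  arguments.  The spontaneous window is the matching span before onset.
* A "tone response" unit is a (neuron, tone-label) pair: the deviant
  response of tone A comes from the sequence where A is rare, the standard
  response from its counterbalanced partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimulus import LightSchedule, ToneSequence
from .synth import SpikeTrainSet

TONE_LABELS = ("A", "B")


# ---------------------------------------------------------------------------
# elementary rate measures
# ---------------------------------------------------------------------------

def evoked_rate(spike_times, window_start: float, window_len: float) -> float:
    """Firing rate (Hz) in the half-open window [start, start+len) ms."""
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    t = np.asarray(spike_times, dtype=float)
    n = int(np.count_nonzero((t >= window_start) & (t < window_start + window_len)))
    return n / (window_len / 1000.0)


def psth(trial_spike_times, bin_ms: float = 5.0,
         t_range: tuple[float, float] = (0.0, 50.0)) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged peri-stimulus time histogram.

    Parameters
    ----------
    trial_spike_times : iterable of arrays
        Spike times per trial, in ms relative to the alignment event.
    bin_ms : float
        Bin width; must divide the range.
    t_range : (start, stop)

    Returns
    -------
    (bin_edges, rates_hz) : rates are per-bin firing rates averaged over
        trials; empty input gives all-zero rates over the requested range.
    """
    start, stop = t_range
    span = stop - start
    n_bins = span / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_ms} does not divide range {span}")
    edges = start + np.arange(round(n_bins) + 1) * bin_ms
    trials = list(trial_spike_times)
    n_trials = len(trials)
    counts = np.zeros(len(edges) - 1)
    for t in trials:
        counts += np.histogram(np.asarray(t, dtype=float), bins=edges)[0]
    denom = max(n_trials, 1) * (bin_ms / 1000.0)
    return edges, counts / denom


def ssa_index(D_A: float, D_B: float, S_A: float, S_B: float) -> float:
    """Stimulus-specific adaptation index.

    ``((D_A + D_B) - (S_A + S_B)) / (D_A + D_B + S_A + S_B)`` where D and S
    are the mean rates evoked by each tone presented as deviant and standard.
    1 means complete adaptation (no standard response), 0 no adaptation.
    Returns NaN (flagged as undefined) when all four rates are zero.
    """
    total = D_A + D_B + S_A + S_B
    if total == 0:
        return float("nan")
    return ((D_A + D_B) - (S_A + S_B)) / total


# ---------------------------------------------------------------------------
# per-tone window counts
# ---------------------------------------------------------------------------

@dataclass
class SeqCounts:
    """Window spike counts for one sequence presentation set.

    ``evoked``/``spont`` have shape (n_neurons, n_reps, n_tones).
    """

    evoked: np.ndarray
    spont: np.ndarray
    roles: np.ndarray
    labels: np.ndarray
    lit: np.ndarray
    seq: ToneSequence


@dataclass
class ToneCounts:
    """Per-tone evoked and spontaneous spike counts for a SpikeTrainSet."""

    seqs: list[SeqCounts]
    n_neurons: int
    n_reps: int
    evoked_window_ms: float
    spont_window_ms: float
    light: LightSchedule

    @property
    def evoked_window_s(self) -> float:
        return self.evoked_window_ms / 1000.0

    @property
    def spont_window_s(self) -> float:
        return self.spont_window_ms / 1000.0


def count_tone_windows(sts: SpikeTrainSet, evoked_window_ms: float = 50.0,
                       spont_window_ms: float = 50.0) -> ToneCounts:
    """Count spikes in the evoked and pre-tone windows of every tone."""
    seqs = []
    for s, seq in enumerate(sts.sequences):
        onsets = seq.onsets().astype(float)
        n_tones = len(onsets)
        evoked = np.zeros((sts.n_neurons, sts.n_reps, n_tones), dtype=np.int32)
        spont = np.zeros_like(evoked)
        for n in range(sts.n_neurons):
            for r in range(sts.n_reps):
                t = sts.train(n, s, r)
                evoked[n, r] = (np.searchsorted(t, onsets + evoked_window_ms)
                                - np.searchsorted(t, onsets))
                spont[n, r] = (np.searchsorted(t, onsets)
                               - np.searchsorted(t, onsets - spont_window_ms))
        seqs.append(SeqCounts(evoked=evoked, spont=spont, roles=seq.roles(),
                              labels=seq.tones(), lit=sts.light.lit_mask(n_tones),
                              seq=seq))
    return ToneCounts(seqs=seqs, n_neurons=sts.n_neurons, n_reps=sts.n_reps,
                      evoked_window_ms=evoked_window_ms,
                      spont_window_ms=spont_window_ms, light=sts.light)


def _tone_mask(sc: SeqCounts, tone: str | None, condition: str | None,
               light: bool | None) -> np.ndarray:
    mask = np.ones(len(sc.roles), dtype=bool)
    if tone is not None:
        mask &= sc.labels == tone
    if condition is not None:
        mask &= sc.roles == condition
    if light is not None:
        mask &= sc.lit == light
    return mask


def trial_counts(tc: ToneCounts, tone: str | None = None,
                 condition: str | None = None, light: bool | None = None,
                 window: str = "evoked") -> np.ndarray:
    """Per-trial spike counts matching the selection, shape (n_neurons, n_trials).

    Trials are tone presentations across sequences and repetitions.
    """
    parts = []
    for sc in tc.seqs:
        mask = _tone_mask(sc, tone, condition, light)
        arr = sc.evoked if window == "evoked" else sc.spont
        parts.append(arr[:, :, mask].reshape(tc.n_neurons, -1))
    return np.concatenate(parts, axis=1)


def mean_rate(tc: ToneCounts, tone: str | None = None,
              condition: str | None = None, light: bool | None = None,
              window: str = "evoked") -> np.ndarray:
    """Per-neuron mean rate (Hz) over the selected trials."""
    counts = trial_counts(tc, tone, condition, light, window)
    w = tc.evoked_window_s if window == "evoked" else tc.spont_window_s
    return counts.mean(axis=1) / w


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

def _signed_rank_one_sided(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p for median(x - y) > 0."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(d, alternative="greater").pvalue)


def apply_inclusion_criteria(tc: ToneCounts, alpha: float = 0.05,
                             min_rate_hz: float = 0.02) -> pd.DataFrame:
    """Decide which (neuron, tone) responses enter the analyses.

    A tone response is kept iff

    (i)   the light-off deviant-evoked count exceeds the paired spontaneous
          count (one-sided Wilcoxon signed-rank, p < ``alpha``);
    (ii)  the neuron's overall rate during each oddball sequence exceeds
          ``min_rate_hz``;
    (iii) the tone passes the tuning test: its evoked counts exceed the
          pooled out-of-band counts (one-sided rank-sum, p < ``alpha``).
          In synthetic sessions out-of-band responses occur at the
          spontaneous rate, so the pooled pre-tone counts serve as the
          out-of-band pool.

    SSA analyses additionally require criterion (i) for *both* tones; this
    is exposed as the ``included_both`` column.

    Returns
    -------
    DataFrame with one row per (neuron, tone): columns ``included``,
    ``included_both`` and a ``reason`` audit string for exclusions.
    """
    rows = []
    dur_s = [sc.seq.duration_ms / 1000.0 for sc in tc.seqs]
    crit_i = {}
    for tone in TONE_LABELS:
        dev_e = trial_counts(tc, tone=tone, condition="deviant", light=False)
        dev_s = trial_counts(tc, tone=tone, condition="deviant", light=False,
                             window="spont")
        tone_e = trial_counts(tc, tone=tone, light=False)
        oob = trial_counts(tc, light=False, window="spont")
        for n in range(tc.n_neurons):
            reasons = []
            if dev_e.shape[1] == 0:
                reasons.append("no deviant trials")
                p_dev = 1.0
            else:
                p_dev = _signed_rank_one_sided(dev_e[n], dev_s[n])
                if p_dev >= alpha:
                    reasons.append("deviant response not above spontaneous")
            # overall rate per oddball sequence (all spikes / duration)
            for k, sc in enumerate(tc.seqs):
                total = sc.evoked[n].sum() + sc.spont[n].sum()
                rate = total / (dur_s[k] * tc.n_reps)
                if rate <= min_rate_hz:
                    reasons.append(f"rate {rate:.3g} Hz <= {min_rate_hz} Hz "
                                   f"in sequence {k}")
                    break
            if tone_e[n].sum() + oob[n].sum() == 0:
                reasons.append("silent")
            else:
                p_tune = float(sps.mannwhitneyu(
                    tone_e[n], oob[n], alternative="greater").pvalue)
                if p_tune >= alpha:
                    reasons.append("not significantly tuned to tone")
            crit_i[(n, tone)] = p_dev < alpha
            rows.append({"neuron": n, "tone": tone,
                         "included": len(reasons) == 0,
                         "reason": "; ".join(reasons)})
    out = pd.DataFrame(rows)
    both = {n: all(crit_i.get((n, t), False) for t in TONE_LABELS)
            for n in range(tc.n_neurons)}
    out["included_both"] = [
        bool(both[r.neuron]) and r.included for r in out.itertuples()]
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalization_reference(sts: SpikeTrainSet, tc: ToneCounts,
                            reference: str = "max_5ms_bin_deviant_off",
                            bin_ms: float = 5.0) -> pd.DataFrame:
    """Per (neuron, tone) normalization reference rate in Hz.

    ``max_5ms_bin_deviant_off`` -- the maximum firing rate across 5-ms PSTH
    bins of the light-off deviant response (the default used for population
    PSTHs); ``mean_deviant_off`` -- the mean light-off deviant-evoked rate
    over the whole evoked window.  Both leave light-on/light-off percent
    changes unchanged (pure per-unit rescaling).
    """
    if reference not in ("max_5ms_bin_deviant_off", "mean_deviant_off"):
        raise ValueError(f"unknown reference {reference!r}")
    rows = []
    for tone in TONE_LABELS:
        if reference == "mean_deviant_off":
            rates = mean_rate(tc, tone=tone, condition="deviant", light=False)
            for n in range(tc.n_neurons):
                rows.append({"neuron": n, "tone": tone,
                             "reference_hz": float(rates[n])})
            continue
        # collect deviant light-off trials per neuron and histogram them
        for n in range(tc.n_neurons):
            trials = []
            for s, sc in enumerate(tc.seqs):
                mask = _tone_mask(sc, tone, "deviant", False)
                onsets = sc.seq.onsets().astype(float)[mask]
                for r in range(tc.n_reps):
                    t = sts.train(n, s, r)
                    for on in onsets:
                        lo = np.searchsorted(t, on)
                        hi = np.searchsorted(t, on + tc.evoked_window_ms)
                        trials.append(t[lo:hi] - on)
            if trials:
                _, rates_hz = psth(trials, bin_ms=bin_ms,
                                   t_range=(0.0, tc.evoked_window_ms))
                ref = float(rates_hz.max())
            else:
                ref = 0.0
            rows.append({"neuron": n, "tone": tone, "reference_hz": ref})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population light-effect summary
# ---------------------------------------------------------------------------

@dataclass
class LightEffectSummary:
    """Population summary of the optogenetic effect per probability condition.

    ``table`` has one row per condition with the population mean normalized
    rate on light-off and light-on trials, their difference, and the percent
    change computed on the population means.
    """

    table: pd.DataFrame
    n_units: int
    excluded: list[str] = field(default_factory=list)


def light_effect_summary(tc: ToneCounts, sts: SpikeTrainSet,
                         included: pd.DataFrame | None = None,
                         reference: str = "max_5ms_bin_deviant_off") -> LightEffectSummary:
    """Population light-on vs light-off effect per condition.

    For every included (neuron, tone) unit, condition rates are divided by
    that unit's normalization reference; condition means are then taken
    across units and the percent change is ``(mean_on - mean_off) /
    mean_off * 100`` on those population means.  The spontaneous condition
    pools the pre-tone windows of all tones (whose light state follows the
    pulse, which begins before onset).
    """
    refs = normalization_reference(sts, tc, reference=reference)
    refs = refs.set_index(["neuron", "tone"])["reference_hz"]
    if included is not None:
        if included.empty:
            raise ValueError("empty population after inclusion criteria")
        keep = included[included["included"].astype(bool)][["neuron", "tone"]]
        units = [tuple(r) for r in keep.to_numpy()]
    else:
        units = [(n, t) for t in TONE_LABELS for n in range(tc.n_neurons)]
    if not units:
        raise ValueError("empty population after inclusion criteria")

    conditions = ["spontaneous", "standard", "deviant"]
    if any((sc.roles == "equal").any() for sc in tc.seqs):
        conditions.append("equal")

    per_cond = {c: {} for c in conditions}
    for light in (False, True):
        for cond in conditions:
            if cond == "spontaneous":
                rates = {t: mean_rate(tc, tone=None, light=light,
                                      window="spont") for t in TONE_LABELS}
            else:
                rates = {t: mean_rate(tc, tone=t, condition=cond, light=light)
                         for t in TONE_LABELS}
            per_cond[cond][light] = rates

    excluded = []
    rows = []
    for cond in conditions:
        vals = {False: [], True: []}
        for n, tone in units:
            ref = refs.loc[(n, tone)]
            if ref <= 0:
                msg = f"neuron {n} tone {tone}: zero normalization reference"
                if msg not in excluded:
                    excluded.append(msg)
                continue
            for light in (False, True):
                r = per_cond[cond][light][tone][n]
                vals[light].append(r / ref)
        if not vals[False]:
            raise ValueError("no units with a positive reference")
        off = float(np.mean(vals[False]))
        on = float(np.mean(vals[True]))
        rows.append({"condition": cond, "mean_off": off, "mean_on": on,
                     "difference": on - off,
                     "pct_change": (on - off) / off * 100.0 if off > 0 else np.nan,
                     "n_units": len(vals[False])})
    return LightEffectSummary(table=pd.DataFrame(rows).set_index("condition"),
                              n_units=len(units), excluded=excluded)


# ---------------------------------------------------------------------------
# SSA summary
# ---------------------------------------------------------------------------

@dataclass
class SSAResult:
    """SSA indices per neuron and their population summary, per light state."""

    per_neuron: pd.DataFrame  # columns: neuron, light, D_A, D_B, S_A, S_B, index
    population: pd.DataFrame  # index: light; columns mean_index, sem, n


def ssa_summary(tc: ToneCounts, included: pd.DataFrame | None = None) -> SSAResult:
    """Per-neuron SSA index on light-off and light-on trials.

    Uses raw (unnormalized) mean rates; a neuron enters only if its deviant
    response exceeds spontaneous for both tones (``included_both``).
    """
    if included is not None:
        neurons = sorted(included[included["included_both"]]["neuron"].unique())
    else:
        neurons = list(range(tc.n_neurons))
    D = {(t, l): mean_rate(tc, tone=t, condition="deviant", light=l)
         for t in TONE_LABELS for l in (False, True)}
    S = {(t, l): mean_rate(tc, tone=t, condition="standard", light=l)
         for t in TONE_LABELS for l in (False, True)}
    rows = []
    for light in (False, True):
        for n in neurons:
            rows.append({
                "neuron": n, "light": light,
                "D_A": D[("A", light)][n], "D_B": D[("B", light)][n],
                "S_A": S[("A", light)][n], "S_B": S[("B", light)][n],
            })
    per = pd.DataFrame(rows)
    per["index"] = [ssa_index(r.D_A, r.D_B, r.S_A, r.S_B)
                    for r in per.itertuples()]
    pop = per.groupby("light")["index"].agg(
        mean_index="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
        n="count")
    return SSAResult(per_neuron=per, population=pop)


# ---------------------------------------------------------------------------
# post-event time courses
# ---------------------------------------------------------------------------

def _positions_relative(roles: np.ndarray, lit: np.ndarray,
                        event: str) -> dict[int, np.ndarray]:
    """Tone indices (0-based) at each position relative to the event.

    For ``event="deviant"``: position p >= 1 is the p-th standard after a
    deviant (reset at each deviant), p = 0 the deviant itself, p = -1 the
    standard immediately before a deviant.  Standards that follow a lit
    standard are excluded (the light, not the deviant, may have perturbed
    them).

    For ``event="light"``: positions are counted from each lit tone
    (p = 0 lit, p in -1..3 neighbours); only standards qualify and tones
    following a deviant are excluded.
    """
    n = len(roles)
    out: dict[int, list[int]] = {}

    def add(p, i):
        out.setdefault(p, []).append(i)

    if event == "deviant":
        last_dev = None
        count = 0
        for i in range(n):
            if roles[i] == "deviant":
                add(0, i)
                if i > 0 and roles[i - 1] == "standard" and not (
                        i >= 2 and roles[i - 2] == "standard" and lit[i - 2]):
                    add(-1, i - 1)
                last_dev, count = i, 0
            elif roles[i] == "standard" and last_dev is not None:
                count += 1
                follows_lit_standard = roles[i - 1] == "standard" and lit[i - 1]
                if not follows_lit_standard:
                    add(count, i)
    elif event == "light":
        lit_idx = np.flatnonzero(lit)
        for j in lit_idx:
            for p in range(-1, 4):
                i = j + p
                if not (0 <= i < n):
                    continue
                if roles[i] != "standard":
                    continue
                if i > 0 and roles[i - 1] == "deviant":
                    continue
                add(p, i)
    else:
        raise ValueError(f"unknown event {event!r}")
    return {p: np.array(v, dtype=int) for p, v in out.items()}


def post_event_timecourse(tc: ToneCounts, event: str = "deviant") -> pd.DataFrame:
    """Population firing rate by tone position relative to deviants or light.

    Rates are averaged over qualifying tones, repetitions, sequences and
    neurons, then normalized by the light-off rate at the reference
    position (T4 for the deviant analysis, T3 for the light analysis).
    Neurons whose deviant (T0) response contains no spikes are excluded
    from the deviant analysis.

    Returns
    -------
    DataFrame with one row per (position, light): columns ``rate_hz``,
    ``norm`` (NaN where no qualifying tones exist) and ``n_tones``.
    """
    ref_pos = 4 if event == "deviant" else 3
    positions = ([-1, 0, 1, 2, 3, 4] if event == "deviant"
                 else [-1, 0, 1, 2, 3])
    keep_neurons = np.ones(tc.n_neurons, dtype=bool)
    if event == "deviant":
        t0 = trial_counts(tc, condition="deviant")
        keep_neurons = t0.sum(axis=1) > 0
    rows = []
    rate_at = {}
    for p in positions:
        for light in (False, True):
            total_counts = 0.0
            total_trials = 0
            for sc in tc.seqs:
                pos_map = _positions_relative(sc.roles, sc.lit, event)
                idx = pos_map.get(p, np.array([], dtype=int))
                if idx.size == 0:
                    continue
                sel = idx[sc.lit[idx] == light]
                if sel.size == 0:
                    continue
                c = sc.evoked[keep_neurons][:, :, sel]
                total_counts += c.sum()
                total_trials += c.shape[0] * c.shape[1] * sel.size
            if total_trials == 0:
                rows.append({"position": p, "light": light,
                             "rate_hz": np.nan, "n_tones": 0})
            else:
                rate = total_counts / total_trials / tc.evoked_window_s
                rows.append({"position": p, "light": light, "rate_hz": rate,
                             "n_tones": total_trials})
            rate_at[(p, light)] = rows[-1]["rate_hz"]
    ref = rate_at.get((ref_pos, False), np.nan)
    df = pd.DataFrame(rows)
    df["norm"] = df["rate_hz"] / ref
    return df


def percent_change_of_means(on: np.ndarray, off: np.ndarray) -> tuple[float, float]:
    """Percent change of population means with its delta-method SE.

    ``pct = (mean(on)/mean(off) - 1) * 100`` over paired per-unit values;
    the standard error accounts for the on/off covariance across units.
    """
    on = np.asarray(on, float)
    off = np.asarray(off, float)
    if on.size != off.size or on.size < 2:
        raise ValueError("need paired samples of length >= 2")
    mo, mf = on.mean(), off.mean()
    if mf == 0:
        return float("nan"), float("nan")
    r = mo / mf
    cov = np.cov(on, off)
    var_r = r**2 * (cov[0, 0] / mo**2 + cov[1, 1] / mf**2
                    - 2 * cov[0, 1] / (mo * mf))
    se = np.sqrt(max(var_r, 0.0) / on.size)
    return (r - 1.0) * 100.0, se * 100.0


# ---------------------------------------------------------------------------
# matched subsets and strong/weak pooling
# ---------------------------------------------------------------------------

def matched_subsets(stat1: np.ndarray, stat2: np.ndarray,
                    tol: float = 0.05,
                    caliper: float | None = None) -> tuple[np.ndarray, np.ndarray, str]:
    """Select index subsets of two groups matched on a scalar statistic.

    Greedy nearest-neighbour pairing (each element of the smaller group to
    its closest unused partner, within an optional caliper), followed by
    iterative trimming of the most discrepant pairs until the subset means
    and standard deviations agree within ``tol`` (relative to the pooled
    mean absolute statistic).  Deterministic given the inputs.

    Returns
    -------
    (idx1, idx2, diagnostic) : matched indices into each group; empty
        arrays with a diagnostic message when no admissible matching exists.
    """
    a = np.asarray(stat1, dtype=float)
    b = np.asarray(stat2, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.array([], int), np.array([], int), "a group is empty"
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return (np.argsort(a, kind="stable"), np.argsort(b, kind="stable"),
                "identical distributions: full groups")
    scale = np.mean(np.abs(np.concatenate([a, b])))
    if scale == 0:
        scale = 1.0
    if caliper is None:
        caliper = 0.5 * max(np.std(a), np.std(b), 1e-12)
    swap = a.size > b.size
    small, large = (b, a) if swap else (a, b)
    order = np.argsort(small, kind="stable")
    used = np.zeros(large.size, dtype=bool)
    pairs = []
    for i in order:
        d = np.abs(large - small[i])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper:
            used[j] = True
            pairs.append((i, j, d[j]))
    if not pairs:
        return (np.array([], int), np.array([], int),
                "no pairs within caliper: statistic ranges do not overlap")
    pairs.sort(key=lambda p: p[2])

    def ok(idx_s, idx_l):
        ms, ml = small[idx_s].mean(), large[idx_l].mean()
        ss = small[idx_s].std(ddof=0)
        sl = large[idx_l].std(ddof=0)
        return abs(ms - ml) <= tol * scale and abs(ss - sl) <= tol * scale

    k = len(pairs)
    while k >= 2:
        idx_s = np.array([p[0] for p in pairs[:k]])
        idx_l = np.array([p[1] for p in pairs[:k]])
        if ok(idx_s, idx_l):
            if swap:
                return idx_l, idx_s, f"matched {k} pairs"
            return idx_s, idx_l, f"matched {k} pairs"
        k -= 1
    return (np.array([], int), np.array([], int),
            "trimming exhausted without meeting tolerance")


def pool_strong_weak(peaks: pd.DataFrame) -> pd.DataFrame:
    """Assign each neuron's tones to strong/weak pools by deviant-off peak.

    Parameters
    ----------
    peaks : DataFrame with columns (neuron, tone, peak_hz) -- typically the
        ``max_5ms_bin_deviant_off`` reference table.

    Returns
    -------
    DataFrame (neuron, strong_tone, weak_tone); neurons missing a tone are
    skipped.  Ties go to tone A (documented, deterministic).
    """
    rows = []
    for n, grp in peaks.groupby("neuron"):
        vals = dict(zip(grp["tone"], grp["peak_hz"]))
        if not all(t in vals for t in TONE_LABELS):
            continue
        if vals["A"] >= vals["B"]:
            strong, weak = "A", "B"
        else:
            strong, weak = "B", "A"
        rows.append({"neuron": n, "strong_tone": strong, "weak_tone": weak})
    return pd.DataFrame(rows, columns=["neuron", "strong_tone", "weak_tone"])
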