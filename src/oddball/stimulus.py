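"""Oddball and equal-probability tone sequences with optogenetic light schedules.

An oddball stimulus is a frozen pseudorandom train of pure-tone pips at two
frequencies (labelled A and B), one presented frequently (the *standard*) and
one rarely (the *deviant*).  Stimuli come in counterbalanced pairs: the second
sequence of a pair has the same deviant positions as the first with the A/B
labels swapped, so that each frequency serves as both standard and deviant.
A light schedule marks every k-th tone, on which an optogenetic suppression
pulse is delivered starting shortly before tone onset.

All times are integer milliseconds.  The tone train is a 2.5 Hz series of
100-ms pips separated by 300 ms of silence (400-ms onset-to-onset period).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd

TONE_DURATION_MS = 100
TONE_ISI_MS = 300
TONE_PERIOD_MS = TONE_DURATION_MS + TONE_ISI_MS

#: metadata carried for provenance only; never enters a computation
SOUND_LEVEL_DB_SPL = 65
TONE_SEPARATION_OCTAVES = 0.39


@dataclass(frozen=True)
class ToneEvent:
    """A single tone pip within a sequence (1-based ``index``)."""

    index: int
    tone: str  # "A" or "B"
    role: str  # "standard", "deviant" or "equal"
    onset: int  # ms
    duration: int = TONE_DURATION_MS  # ms


@dataclass
class ToneSequence:
    """An ordered, frozen train of tone events.

    Parameters
    ----------
    events : list of ToneEvent
        Ordered tone pips; onsets advance by the 400-ms period.
    p_deviant : float
        Nominal deviant probability (0.5 for an equal-probability sequence).
    deviant_tone : str or None
        Which label plays the deviant role ("A"/"B"); None for equal sequences.
    seed : int
        Seed the sequence was generated from (frozen-sequence identity).
    frozen_id : str
        Identifier shared by the two members of a counterbalanced pair.
    """

    events: list[ToneEvent]
    p_deviant: float
    deviant_tone: str | None
    seed: int
    frozen_id: str = ""
    metadata: dict = field(default_factory=lambda: {
        "level_db_spl": SOUND_LEVEL_DB_SPL,
        "tone_separation_octaves": TONE_SEPARATION_OCTAVES,
    })

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[ToneEvent]:
        return iter(self.events)

    @property
    def n_tones(self) -> int:
        return len(self.events)

    @property
    def duration_ms(self) -> int:
        """Total duration from first onset to end of last ISI."""
        return self.n_tones * TONE_PERIOD_MS

    def roles(self) -> np.ndarray:
        return np.array([e.role for e in self.events])

    def tones(self) -> np.ndarray:
        return np.array([e.tone for e in self.events])

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    def deviant_indices(self) -> np.ndarray:
        """1-based indices of deviant events."""
        return np.array([e.index for e in self.events if e.role == "deviant"],
                        dtype=int)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "p_deviant": self.p_deviant,
            "deviant_tone": self.deviant_tone,
            "seed": self.seed,
            "frozen_id": self.frozen_id,
            "metadata": self.metadata,
            "events": [asdict(e) for e in self.events],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ToneSequence":
        payload = json.loads(text)
        events = [ToneEvent(**e) for e in payload.pop("events")]
        return cls(events=events, **payload)

    def to_frame(self, light: "LightSchedule | None" = None) -> pd.DataFrame:
        """Flat table (index, tone, role, onset_ms, light_on)."""
        lit = light.lit_tone_indices if light is not None else set()
        return pd.DataFrame(
            {
                "index": [e.index for e in self.events],
                "tone": [e.tone for e in self.events],
                "role": [e.role for e in self.events],
                "onset_ms": [e.onset for e in self.events],
                "light_on": [e.index in lit for e in self.events],
            }
        )


@dataclass
class LightSchedule:
    """Optogenetic pulses delivered on every k-th tone of a sequence.

    Each pulse spans ``[tone_onset - onset_lead, tone_onset - onset_lead +
    pulse_duration)`` so the default 250-ms pulse starting 100 ms before
    tone onset covers the whole 100-ms tone.
    """

    lit_tone_indices: frozenset[int]
    every_k: int
    onset_lead: int = 100  # ms
    pulse_duration: int = 250  # ms

    def is_lit(self, index: int) -> bool:
        return index in self.lit_tone_indices

    def lit_mask(self, n_tones: int) -> np.ndarray:
        """Boolean mask over tone positions 1..n_tones."""
        mask = np.zeros(n_tones, dtype=bool)
        for i in self.lit_tone_indices:
            if 1 <= i <= n_tones:
                mask[i - 1] = True
        return mask

    def pulse_window(self, tone_onset: int) -> tuple[int, int]:
        start = tone_onset - self.onset_lead
        return (start, start + self.pulse_duration)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _deviant_positions(n_tones: int, n_dev: int, rng: np.random.Generator) -> np.ndarray:
    """Place ``n_dev`` deviants among ``n_tones`` positions (1-based).

    Inter-deviant gaps (position differences) are drawn from a shuffled
    multiset spanning the feasible gap range symmetrically around the mean
    gap, so the gap histogram is as flat as the integer constraints allow
    ("counterbalanced with respect to the number of standards preceding each
    deviant").  Gap 1 (adjacent deviants) is forbidden so every deviant is
    preceded by at least one standard.
    """
    if n_dev < 1:
        raise ValueError("need at least one deviant")
    base = n_tones // n_dev
    if base < 2:
        raise ValueError(
            f"cannot place {n_dev} non-adjacent deviants among {n_tones} tones"
        )
    lo, hi = 2, 2 * base - 2
    if lo == hi:
        gaps = [base] * n_dev
    else:
        # pairs (lo+k, hi-k) keep the per-pair mean at base while sweeping
        # the whole feasible range; odd leftover gap sits at the mean
        offsets = [(k % (base - 2)) + 0 for k in range(n_dev // 2)]
        gaps = []
        for k in offsets:
            gaps.extend([lo + k, hi - k])
        if len(gaps) < n_dev:
            gaps.append(base)
    # distribute the remainder one tone at a time, never exceeding position n
    remainder = n_tones - sum(gaps)
    i = 0
    while remainder > 0:
        gaps[i % n_dev] += 1
        remainder -= 1
        i += 1
    while remainder < 0:
        j = int(np.argmax(gaps))
        if gaps[j] <= 2:
            raise ValueError(
                f"cannot place {n_dev} non-adjacent deviants among {n_tones} tones"
            )
        gaps[j] -= 1
        remainder += 1
    gaps = np.array(gaps, dtype=int)
    rng.shuffle(gaps)
    positions = np.cumsum(gaps)
    assert positions[-1] <= n_tones and np.all(np.diff(positions) >= 2)
    return positions


def _make_events(n_tones: int, deviant_pos: set[int], deviant_tone: str,
                 standard_tone: str) -> list[ToneEvent]:
    events = []
    for i in range(1, n_tones + 1):
        if i in deviant_pos:
            tone, role = deviant_tone, "deviant"
        else:
            tone, role = standard_tone, "standard"
        events.append(ToneEvent(index=i, tone=tone, role=role,
                                onset=(i - 1) * TONE_PERIOD_MS))
    return events


def build_oddball_pair(n_tones: int = 653, p_deviant: float = 0.1,
                       seed: int = 0) -> tuple[ToneSequence, ToneSequence]:
    """Build a counterbalanced pair of frozen oddball sequences.

    Sequence 1 presents tone B as the deviant (A standard); sequence 2 swaps
    the labels at identical deviant positions.  The deviant count is
    ``round(p_deviant * n_tones)`` (half away from zero) and no two deviants
    are adjacent.

    Returns
    -------
    (ToneSequence, ToneSequence)
        The two members of the pair, sharing a ``frozen_id``.
    """
    if not (0.0 < p_deviant < 0.5):
        raise ValueError(f"p_deviant must be in (0, 0.5), got {p_deviant}")
    if n_tones < 10:
        raise ValueError(f"n_tones must be >= 10, got {n_tones}")
    n_dev = _round_half_away(p_deviant * n_tones)
    rng = np.random.default_rng(seed)
    positions = set(_deviant_positions(n_tones, n_dev, rng).tolist())
    frozen_id = f"oddball-n{n_tones}-p{p_deviant:g}-s{seed}"
    seq1 = ToneSequence(
        events=_make_events(n_tones, positions, "B", "A"),
        p_deviant=p_deviant, deviant_tone="B", seed=seed, frozen_id=frozen_id)
    seq2 = ToneSequence(
        events=_make_events(n_tones, positions, "A", "B"),
        p_deviant=p_deviant, deviant_tone="A", seed=seed, frozen_id=frozen_id)
    return seq1, seq2


def build_equal_sequence(n_tones: int = 652, seed: int = 0) -> ToneSequence:
    """Build a frozen 50:50 sequence; every event has role ``"equal"``."""
    if n_tones % 2 != 0:
        raise ValueError(f"n_tones must be even for a 50:50 sequence, got {n_tones}")
    rng = np.random.default_rng(seed)
    labels = np.array(["A"] * (n_tones // 2) + ["B"] * (n_tones // 2))
    rng.shuffle(labels)
    events = [
        ToneEvent(index=i + 1, tone=labels[i], role="equal",
                  onset=i * TONE_PERIOD_MS)
        for i in range(n_tones)
    ]
    return ToneSequence(events=events, p_deviant=0.5, deviant_tone=None,
                        seed=seed, frozen_id=f"equal-n{n_tones}-s{seed}")


def attach_light_schedule(seq: ToneSequence, every_k: int = 5,
                          onset_lead: int = 100,
                          pulse_duration: int = 250) -> LightSchedule:
    """Mark every k-th tone (1-based multiples of k) for light delivery."""
    if every_k < 2:
        raise ValueError(f"every_k must be >= 2, got {every_k}")
    lit = frozenset(range(every_k, seq.n_tones + 1, every_k))
    return LightSchedule(lit_tone_indices=lit, every_k=every_k,
                         onset_lead=onset_lead, pulse_duration=pulse_duration)
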