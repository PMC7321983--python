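"""Stimulus protocols and behavioural event logs.

Three mapping protocols are supported, mirroring a passive-fixation task:

* ``eccentricity`` — 9 hemi-annular bands of 1.5 DVA width spanning
  1.5-15 DVA; the condition value is the band centre in DVA.
* ``angular`` — 12 wedges of 15 degrees covering one hemifield (0-180
  degrees); the condition value is the wedge centre.
* ``od`` — 2 full-field monocular conditions (contralateral /
  ipsilateral eye), condition value is the eye sign (+1 contra, -1 ipsi).

A trial is: 0.5 s of fixation, the stimulus flash (0.5 s by default),
then a 3-s intertrial gap.  Logs round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "TimingConfig",
    "EventLog",
    "eccentricity_stimuli",
    "angular_stimuli",
    "od_stimuli",
    "make_event_log",
]

EVENT_COLUMNS = [
    "trial_id",
    "t_onset",
    "condition_id",
    "stimulus_kind",
    "stim_duration",
    "correct",
]


@dataclass(frozen=True)
class StimulusSet:
    """A mapping protocol: condition ids, their physical values and kinds."""

    kind: str  # 'eccentricity' | 'angular' | 'od'
    condition_values: tuple[float, ...]  # DVA / degrees / eye sign
    condition_kinds: tuple[str, ...]  # per-condition stimulus_kind label
    band_width: float  # DVA or degrees; 0 for od
    stim_duration: float = 0.5  # s

    @property
    def n_conditions(self) -> int:
        return len(self.condition_values)


def eccentricity_stimuli(
    ecc_range: tuple[float, float] = (1.5, 15.0),
    n_conditions: int = 9,
    stim_duration: float = 0.5,
) -> StimulusSet:
    """Concentric half-ring conditions; 9 bands of 1.5 DVA by default."""
    width = (ecc_range[1] - ecc_range[0]) / n_conditions
    centers = ecc_range[0] + width * (np.arange(n_conditions) + 0.5)
    return StimulusSet(
        kind="eccentricity",
        condition_values=tuple(centers),
        condition_kinds=("eccentricity",) * n_conditions,
        band_width=width,
        stim_duration=stim_duration,
    )


def angular_stimuli(
    ang_range: tuple[float, float] = (0.0, 180.0),
    n_conditions: int = 12,
    stim_duration: float = 0.5,
) -> StimulusSet:
    """Wedge conditions covering one hemifield; 12 x 15 degrees by default."""
    width = (ang_range[1] - ang_range[0]) / n_conditions
    centers = ang_range[0] + width * (np.arange(n_conditions) + 0.5)
    return StimulusSet(
        kind="angular",
        condition_values=tuple(centers),
        condition_kinds=("angular",) * n_conditions,
        band_width=width,
        stim_duration=stim_duration,
    )


def od_stimuli(stim_duration: float = 0.5) -> StimulusSet:
    """Monocular full-field conditions: contralateral (+1) and ipsilateral (-1)."""
    return StimulusSet(
        kind="od",
        condition_values=(1.0, -1.0),
        condition_kinds=("od_contra", "od_ipsi"),
        band_width=0.0,
        stim_duration=stim_duration,
    )


@dataclass(frozen=True)
class TimingConfig:
    """Trial scheduling parameters (seconds)."""

    fixation_s: float = 0.5
    iti_s: float = 3.0  # gap after stimulus offset
    t_start: float = 20.0  # first onset; leaves room for a 5-s baseline
    extra_gap_s: float = 0.0  # optional slack appended to every trial

    def trial_period(self, stim_duration: float) -> float:
        return self.fixation_s + stim_duration + self.iti_s + self.extra_gap_s


@dataclass
class EventLog:
    """Trial table with onsets, conditions and correctness."""

    table: pd.DataFrame
    stimuli: StimulusSet | None = field(default=None, repr=False)

    def __post_init__(self):
        missing = set(EVENT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"event log missing columns: {sorted(missing)}")
        t = self.table["t_onset"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t_onset must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def t_onset(self) -> np.ndarray:
        return self.table["t_onset"].to_numpy(dtype=float)

    @property
    def condition_id(self) -> np.ndarray:
        return self.table["condition_id"].to_numpy(dtype=int)

    @property
    def correct(self) -> np.ndarray:
        return self.table["correct"].to_numpy(dtype=bool)

    def correct_trials(self) -> "EventLog":
        return EventLog(self.table[self.table["correct"]].reset_index(drop=True),
                        self.stimuli)

    def for_condition(self, condition_id: int) -> "EventLog":
        sel = self.table["condition_id"] == condition_id
        return EventLog(self.table[sel].reset_index(drop=True), self.stimuli)

    def session_end(self, tail_s: float = 10.0) -> float:
        return float(self.t_onset[-1] + tail_s) if len(self) else tail_s

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stimuli: StimulusSet | None = None) -> "EventLog":
        return cls(pd.read_csv(path), stimuli)


def make_event_log(
    stimuli: StimulusSet,
    n_trials_per_condition: int,
    timing: TimingConfig | None = None,
    n_blank_trials: int = 0,
    p_correct: float = 1.0,
    seed: int | None = None,
) -> EventLog:
    """Schedule a session of randomly interleaved trials.

    Condition counts are exact (``n_trials_per_condition`` each, plus
    optional blank fixation-only trials); the interleaving order is a
    seeded permutation.  Onsets are spaced by the full trial period
    (fixation + stimulus + intertrial gap), so consecutive onsets are at
    least 0.5 + stim + 3 s apart with the defaults.
    """
    if n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)

    cond = np.repeat(np.arange(stimuli.n_conditions), n_trials_per_condition)
    cond = np.concatenate([cond, np.full(n_blank_trials, -1, dtype=int)])
    order = rng.permutation(len(cond))
    cond = cond[order]

    period = timing.trial_period(stimuli.stim_duration)
    t_onset = timing.t_start + period * np.arange(len(cond))
    kinds = [
        "blank" if c < 0 else stimuli.condition_kinds[c] for c in cond
    ]
    durations = [
        0.0 if c < 0 else stimuli.stim_duration for c in cond
    ]
    correct = (
        rng.random(len(cond)) < p_correct
        if p_correct < 1.0
        else np.ones(len(cond), dtype=bool)
    )
    table = pd.DataFrame(
        {
            "trial_id": np.arange(len(cond)),
            "t_onset": t_onset,
            "condition_id": cond,
            "stimulus_kind": kinds,
            "stim_duration": durations,
            "correct": correct,
        }
    )
    return EventLog(table, stimuli)
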