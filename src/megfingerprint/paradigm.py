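"""Braille attention-switching paradigm: trial schedules and event streams.

The task drives bilateral tactile stimulation of both index fingers. Each
trial starts (t = 0) at the end of an auditory cue telling the participant
to attend left or right. Five braille patterns are then presented, the first
at t = 1.17 s and the rest at 1.37 s intervals, each lasting 0.37 s, with a
7 s rest period closing the trial. A pattern is a rare "target" with
probability 0.2; with the default 80 trials that is exactly 80 targets and
320 non-targets over the 400 stimulus slots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrialTiming",
    "Trial",
    "TrialSchedule",
    "generate_schedule",
    "schedule_to_events",
    "write_events_tsv",
    "read_events_tsv",
]

N_STIMULI_PER_TRIAL = 5
P_TARGET = 0.2

EVENT_CUE_LEFT = "cue_left"
EVENT_CUE_RIGHT = "cue_right"
EVENT_STIM_TARGET = "stim_target"
EVENT_STIM_NONTARGET = "stim_nontarget"
EVENT_TRIAL_END = "trial_end"


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial timing, in seconds relative to cue end (t = 0)."""

    first_onset_s: float = 1.17
    inter_stimulus_interval_s: float = 1.37
    stimulus_duration_s: float = 0.37
    rest_s: float = 7.0
    cue_lead_in_s: float = 2.0  # pre-t=0 padding standing in for the auditory cue

    @property
    def stimulus_onsets_s(self) -> np.ndarray:
        k = np.arange(N_STIMULI_PER_TRIAL)
        return self.first_onset_s + k * self.inter_stimulus_interval_s

    @property
    def trial_duration_s(self) -> float:
        """Duration from cue end to trial end: last stimulus offset + rest."""
        return float(self.stimulus_onsets_s[-1] + self.stimulus_duration_s + self.rest_s)


@dataclass(frozen=True)
class Trial:
    cue_side: str  # "left" | "right"
    stimulus_onsets_s: tuple[float, ...]
    pattern_per_stimulus: tuple[str, ...]  # "target" | "non_target"


@dataclass
class TrialSchedule:
    n_trials: int
    trials: list[Trial]
    timing: TrialTiming = field(default_factory=TrialTiming)
    p_target: float = P_TARGET

    @property
    def n_slots(self) -> int:
        return self.n_trials * N_STIMULI_PER_TRIAL

    @property
    def n_targets(self) -> int:
        return sum(p == "target" for t in self.trials for p in t.pattern_per_stimulus)

    @property
    def n_nontargets(self) -> int:
        return self.n_slots - self.n_targets

    def trial_start_s(self, i: int) -> float:
        """Start time (cue end, t=0 of trial i) on the concatenated timeline."""
        return i * self.timing.trial_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * self.timing.trial_duration_s

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_trials": self.n_trials,
            "p_target": self.p_target,
            "timing": asdict(self.timing),
            "trials": [asdict(t) for t in self.trials],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialSchedule":
        payload = json.loads(Path(path).read_text())
        timing = TrialTiming(**payload["timing"])
        trials = [
            Trial(
                cue_side=t["cue_side"],
                stimulus_onsets_s=tuple(t["stimulus_onsets_s"]),
                pattern_per_stimulus=tuple(t["pattern_per_stimulus"]),
            )
            for t in payload["trials"]
        ]
        return cls(
            n_trials=payload["n_trials"],
            trials=trials,
            timing=timing,
            p_target=payload["p_target"],
        )


def generate_schedule(
    n_trials: int = 80,
    seed: int | np.random.Generator = 0,
    timing: TrialTiming | None = None,
) -> TrialSchedule:
    """Generate a seeded trial schedule with fixed target totals.

    Exactly ``ceil(0.2 * n_slots)`` targets are placed by sampling slots
    without replacement, so the default 80-trial run always contains 80
    targets and 320 non-targets. Cue sides are balanced (n_trials // 2
    each, the odd trial assigned at random) and shuffled.

    Parameters
    ----------
    n_trials:
        Number of trials (each carrying 5 stimulus slots).
    seed:
        Integer seed or a ``numpy.random.Generator``.
    timing:
        Within-trial timing; defaults to the task timing.
    """
    if n_trials < 0:
        raise ValueError(f"n_trials must be >= 0, got {n_trials}")
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)

    n_slots = n_trials * N_STIMULI_PER_TRIAL
    n_targets = int(np.ceil(P_TARGET * n_slots))
    target_slots = rng.choice(n_slots, size=n_targets, replace=False) if n_slots else np.array([], int)
    is_target = np.zeros(n_slots, dtype=bool)
    is_target[target_slots] = True

    # balanced cue sides in seeded random order
    sides = np.array(["left", "right"])[
        rng.permutation(np.arange(n_trials) % 2) if n_trials else np.array([], int)
    ]

    onsets = tuple(float(x) for x in timing.stimulus_onsets_s)
    trials = []
    for i in range(n_trials):
        patterns = tuple(
            "target" if is_target[i * N_STIMULI_PER_TRIAL + k] else "non_target"
            for k in range(N_STIMULI_PER_TRIAL)
        )
        trials.append(Trial(cue_side=str(sides[i]), stimulus_onsets_s=onsets, pattern_per_stimulus=patterns))
    return TrialSchedule(n_trials=n_trials, trials=trials, timing=timing)


def schedule_to_events(schedule: TrialSchedule, sampling_rate_hz: float) -> pd.DataFrame:
    """Expand a schedule into a sampled event table.

    Trials are concatenated end to end; t = 0 of trial i falls at
    ``i * trial_duration_s`` on the global timeline, and sample indices are
    ``round(onset_s * rate)``. Columns follow the BIDS events convention
    (onset, duration, trial_type, sample).
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    rows: list[tuple[float, float, str, int]] = []
    dur = schedule.timing.stimulus_duration_s
    for i, trial in enumerate(schedule.trials):
        t0 = schedule.trial_start_s(i)
        cue = EVENT_CUE_LEFT if trial.cue_side == "left" else EVENT_CUE_RIGHT
        rows.append((t0, 0.0, cue, round(t0 * sampling_rate_hz)))
        for onset, pattern in zip(trial.stimulus_onsets_s, trial.pattern_per_stimulus):
            t = t0 + onset
            code = EVENT_STIM_TARGET if pattern == "target" else EVENT_STIM_NONTARGET
            rows.append((t, dur, code, round(t * sampling_rate_hz)))
        t_end = t0 + schedule.timing.trial_duration_s
        rows.append((t_end, 0.0, EVENT_TRIAL_END, round(t_end * sampling_rate_hz)))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "sample"])


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write a BIDS-style ``*_events.tsv`` (round-trips bit-exactly)."""
    events.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
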