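"""Braille tactile-attention task structure.

A task trial lasts 16 s: a target braille pattern is presented to both index
fingers in the 1-3 s window, a visual cue (left/right arrow) in the 4-6 s
window directs attention to one hand, and five 260 ms probe stimuli follow at
t = 7 s with 1.1 s spacing, delivered pseudo-randomly to either hand.  A probe
is a *target* when its pattern matches the trial's target pattern and it lands
on the cued hand; the number of targets per trial is drawn from a
gamma(shape=4, scale=0.3) distribution, rounded and clipped to the number of
probes.  A 16 s rest trial follows every block of ``rest_every`` task trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRIAL_DURATION_S = 16.0
TARGET_WINDOW_S = (1.0, 3.0)
CUE_WINDOW_S = (4.0, 6.0)
PROBE_ONSETS_S = (7.0, 8.1, 9.2, 10.3, 11.4)
PROBE_DURATION_S = 0.26
N_PROBES = len(PROBE_ONSETS_S)
HANDS = ("left", "right")

#: gamma law for the number of target patterns per trial
TARGET_COUNT_SHAPE = 4.0
TARGET_COUNT_SCALE = 0.3


@dataclass(frozen=True)
class BraillePattern:
    """One 4 x 2 pin pattern; ``pins`` is row-major, True = pin up."""

    pattern_id: int
    pins: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.pins) != 8:
            raise ValueError("a braille pattern has 8 pins (4 x 2 grid)")

    @property
    def n_up(self) -> int:
        return int(sum(self.pins))


@dataclass(frozen=True)
class ProbeEvent:
    onset_s: float               # relative to trial start
    hand: str                    # "left" | "right"
    pattern_id: int
    is_target: bool
    bad_response: bool = False   # simulated incorrect button press
    duration_s: float = PROBE_DURATION_S


@dataclass(frozen=True)
class Trial:
    index: int
    is_rest: bool
    start_s: float
    cue: str | None = None               # "left" | "right", None for rest
    target_pattern_id: int | None = None
    probes: tuple[ProbeEvent, ...] = ()
    duration_s: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if not self.is_rest and len(self.probes) != N_PROBES:
            raise ValueError(f"task trial needs {N_PROBES} probes")


@dataclass(frozen=True)
class Schedule:
    trials: tuple[Trial, ...]
    rng_seed: int | None = None

    @property
    def total_duration_s(self) -> float:
        return float(sum(t.duration_s for t in self.trials))

    @property
    def task_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.is_rest)

    @property
    def rest_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.is_rest)


# 5 distinct patterns, each with exactly 4 of 8 pins raised (rows of the
# 4 x 2 grid concatenated).
_STANDARD_PINS = (
    (1, 0, 1, 0, 1, 0, 1, 0),
    (0, 1, 0, 1, 0, 1, 0, 1),
    (1, 1, 0, 0, 0, 0, 1, 1),
    (0, 0, 1, 1, 1, 1, 0, 0),
    (1, 0, 0, 1, 1, 0, 0, 1),
)


def make_standard_patterns() -> tuple[BraillePattern, ...]:
    """The five braille patterns used by the task (4 pins up, 4 down each)."""
    return tuple(
        BraillePattern(pattern_id=i, pins=tuple(bool(p) for p in pins))
        for i, pins in enumerate(_STANDARD_PINS)
    )


def sample_target_count(rng: np.random.Generator,
                        shape: float = TARGET_COUNT_SHAPE,
                        scale: float = TARGET_COUNT_SCALE) -> int:
    """Number of target presentations in one trial.

    Drawn from gamma(shape=4, scale=0.3), rounded to the nearest integer and
    clipped to [0, 5] since only five probes exist.
    """
    raw = rng.gamma(shape=shape, scale=scale)
    return int(np.clip(np.rint(raw), 0, N_PROBES))


def _make_task_trial(
    index: int,
    start_s: float,
    cue: str,
    rng: np.random.Generator,
    response_error_rate: float,
    gamma_shape: float,
    gamma_scale: float,
) -> Trial:
    patterns = make_standard_patterns()
    target = patterns[rng.integers(len(patterns))]
    n_targets = sample_target_count(rng, gamma_shape, gamma_scale)
    target_slots = set(rng.choice(N_PROBES, size=n_targets, replace=False).tolist())

    probes = []
    for k, onset in enumerate(PROBE_ONSETS_S):
        if k in target_slots:
            hand, pid, is_target = cue, target.pattern_id, True
        else:
            hand = HANDS[rng.integers(2)]
            # any pattern; only the (target pattern, cued hand) pair is a target
            pid = int(rng.integers(len(patterns)))
            is_target = False
            if pid == target.pattern_id and hand == cue:
                pid = (pid + 1) % len(patterns)
        bad = bool(rng.random() < response_error_rate)
        probes.append(
            ProbeEvent(onset_s=onset, hand=hand, pattern_id=pid,
                       is_target=is_target, bad_response=bad)
        )
    return Trial(
        index=index,
        is_rest=False,
        start_s=start_s,
        cue=cue,
        target_pattern_id=target.pattern_id,
        probes=tuple(probes),
    )


def generate_schedule(
    n_trials: int,
    rest_every: int,
    rng: np.random.Generator | int,
    response_error_rate: float = 0.0,
    gamma_shape: float = TARGET_COUNT_SHAPE,
    gamma_scale: float = TARGET_COUNT_SCALE,
) -> Schedule:
    """Generate a balanced, seeded task schedule.

    ``n_trials`` task trials with exactly half cued left (``n_trials`` must be
    even), in randomised order, with one 16 s rest trial inserted after every
    ``rest_every`` task trials.  (80, 10) reproduces the 1408 s session.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if rest_every < 1:
        raise ValueError("rest_every must be >= 1")
    if n_trials % 2:
        raise ValueError("n_trials must be even for a balanced left/right cue design")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)

    cues = ["left"] * (n_trials // 2) + ["right"] * (n_trials // 2)
    cues = [cues[i] for i in rng.permutation(n_trials)]

    trials: list[Trial] = []
    t = 0.0
    for i, cue in enumerate(cues):
        trials.append(_make_task_trial(len(trials), t, cue, rng, response_error_rate,
                                       gamma_shape, gamma_scale))
        t += TRIAL_DURATION_S
        if (i + 1) % rest_every == 0:
            trials.append(Trial(index=len(trials), is_rest=True, start_s=t))
            t += TRIAL_DURATION_S
    return Schedule(trials=tuple(trials), rng_seed=seed)


def schedule_to_events(schedule: Schedule) -> pd.DataFrame:
    """Flatten a schedule into a BIDS-style events table.

    Columns follow the events.tsv dialect (onset, duration, trial_type first);
    onsets are on the experiment clock and non-decreasing.
    """
    rows: list[dict] = []
    for trial in schedule.trials:
        t0 = trial.start_s
        if trial.is_rest:
            rows.append(dict(onset=t0, duration=trial.duration_s, trial_type="rest",
                             hand="n/a", pattern_id=-1, is_target=False,
                             bad_response=False, trial_index=trial.index))
            continue
        rows.append(dict(onset=t0 + TARGET_WINDOW_S[0],
                         duration=TARGET_WINDOW_S[1] - TARGET_WINDOW_S[0],
                         trial_type="target", hand="both",
                         pattern_id=trial.target_pattern_id, is_target=False,
                         bad_response=False, trial_index=trial.index))
        rows.append(dict(onset=t0 + CUE_WINDOW_S[0],
                         duration=CUE_WINDOW_S[1] - CUE_WINDOW_S[0],
                         trial_type=f"cue_{trial.cue}", hand=trial.cue,
                         pattern_id=-1, is_target=False, bad_response=False,
                         trial_index=trial.index))
        for p in trial.probes:
            attended = "attended" if p.hand == trial.cue else "nonattended"
            rows.append(dict(onset=t0 + p.onset_s, duration=p.duration_s,
                             trial_type=f"probe_{attended}", hand=p.hand,
                             pattern_id=p.pattern_id, is_target=p.is_target,
                             bad_response=p.bad_response, trial_index=trial.index))
    cols = ["onset", "duration", "trial_type", "hand", "pattern_id",
            "is_target", "bad_response", "trial_index"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def events_to_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def events_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
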