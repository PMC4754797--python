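"""Monetary incentive delay (MID) trial sequences and staircase simulation.

One session of the task presents 75 trials, 15 for each of five win/loss
contingencies (-$1.0, -$0.25, $0, +$0.25, +$1.0).  Each trial shows a cue,
waits through an anticipation delay, flashes a speeded target whose duration
is adapted online, and gives monetary feedback.  The target duration follows
a 2-down/1-up staircase in steps of one display frame (1/75 s): shortened
after two consecutive hits, lengthened after every miss, which holds the
long-run hit probability near the level p with p^2 = 1/2 (~0.71); the
empirical rate the task aims for is about two thirds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "StaircaseState",
    "FRAME",
    "TRIAL_CONDITIONS",
    "generate_trial_sequence",
    "staircase_update",
    "simulate_performance",
    "trials_to_events",
]

#: one display frame at 75 Hz, the staircase step (seconds)
FRAME = 1.0 / 75.0

#: the five win/loss contingencies
TRIAL_CONDITIONS = ("-$1.0", "-$0.25", "$0", "+$0.25", "+$1.0")


@dataclass
class Trial:
    index: int
    condition: str
    onset: float
    delay_duration: float
    target_duration: float
    feedback_duration: float
    outcome: str | None = None  # "hit", "miss" or None while pending
    response_time: float | None = None


@dataclass
class StaircaseState:
    target_duration: float
    consecutive_hits: int = 0

    def __post_init__(self):
        if self.target_duration <= 0:
            raise ValueError("target duration must be positive")
        if self.consecutive_hits not in (0, 1):
            raise ValueError("consecutive_hits must be 0 or 1")


def generate_trial_sequence(
    trials_per_condition: int,
    seed: int,
    delay_range: tuple[float, float] = (2.0, 2.5),
    feedback_duration: float = 1.5,
    iti_range: tuple[float, float] = (1.5, 3.5),
    target_duration: float = 0.3,
    start_time: float = 10.0,
) -> list[Trial]:
    """Seeded random ordering of ``5 * trials_per_condition`` trials.

    Timing defaults (anticipation delay uniform 2.0-2.5 s, feedback 1.5 s,
    inter-trial interval jittered 1.5-3.5 s) are standard MID choices sized
    so a 75-trial session fits a 272-volume scan at TR 2 s; all are
    configurable.  Onsets are laid out sequentially from ``start_time``.
    """
    if trials_per_condition < 0:
        raise ValueError("trials_per_condition must be non-negative")
    rng = np.random.default_rng(seed)
    conditions = np.repeat(TRIAL_CONDITIONS, trials_per_condition)
    rng.shuffle(conditions)
    trials = []
    t = float(start_time)
    for i, cond in enumerate(conditions):
        delay = float(rng.uniform(*delay_range))
        trials.append(
            Trial(
                index=i,
                condition=str(cond),
                onset=t,
                delay_duration=delay,
                target_duration=target_duration,
                feedback_duration=feedback_duration,
            )
        )
        t += delay + target_duration + feedback_duration + float(rng.uniform(*iti_range))
    return trials


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """Advance the 2-down/1-up staircase by one trial.

    A miss lengthens the target by one frame and resets the hit streak; a
    first hit only arms the streak; a second consecutive hit shortens the
    target by one frame.  The duration never drops below one frame.
    """
    if outcome not in ("hit", "miss"):
        raise ValueError("outcome must be 'hit' or 'miss'")
    if outcome == "miss":
        return StaircaseState(state.target_duration + FRAME, 0)
    if state.consecutive_hits == 0:
        return StaircaseState(state.target_duration, 1)
    return StaircaseState(max(state.target_duration - FRAME, FRAME), 0)


def simulate_performance(
    trials: list[Trial],
    rt_model: dict[str, float],
    initial_duration: float,
    seed: int,
) -> tuple[list[Trial], float]:
    """Simulate a subject's responses through the staircase.

    Response times are Gaussian with ``rt_model["mean"]`` and
    ``rt_model["sd"]``; a trial is a hit when the sampled response time is at
    most the current target duration.  Returns the trials with outcomes,
    response times and the adapted per-trial target durations filled in, plus
    the overall hit rate.
    """
    if rt_model.get("sd", 0.0) < 0:
        raise ValueError("response-time sd must be non-negative")
    rng = np.random.default_rng(seed)
    state = StaircaseState(initial_duration)
    out = []
    hits = 0
    for trial in trials:
        rt = max(float(rng.normal(rt_model["mean"], rt_model["sd"])), 0.0)
        hit = rt <= state.target_duration
        hits += hit
        out.append(
            replace(
                trial,
                outcome="hit" if hit else "miss",
                response_time=rt,
                target_duration=state.target_duration,
            )
        )
        state = staircase_update(state, "hit" if hit else "miss")
    rate = hits / len(trials) if trials else float("nan")
    return out, rate


def trials_to_events(trials: list[Trial]) -> pd.DataFrame:
    """BIDS-like events table (onset, duration, trial_type, response_time,
    outcome) with the anticipation delay as the trial duration."""
    return pd.DataFrame(
        [
            (t.onset, t.delay_duration, t.condition, t.response_time, t.outcome)
            for t in trials
        ],
        columns=["onset", "duration", "trial_type", "response_time", "outcome"],
    )
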