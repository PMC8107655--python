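"""Transformed 3-up/1-down adaptive staircase on the noise-dot count.

Three consecutive correct responses raise the noise count (harder); one
error lowers it (easier).  This rule converges on the level where
p(correct)^3 = 1/2, i.e. p = (1/2)^(1/3) ~ 0.794 — the staircase tracks the
~79%-correct point of the observer's psychometric function.  Steps are 3
dots until the fourth reversal, then 2; a track self-terminates after 16
reversals (4 initial reversals discarded, 12 counted), and its threshold is
the mean noise count over its last 10 trials.  Two tracks per condition are
run and averaged; four tracks (two upright, two inverted) interleave at
random within a block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialSpec",
    "BIRD_STAIRCASE",
    "HUMAN_STAIRCASE",
    "init_staircase",
    "update",
    "threshold",
    "pair_threshold",
    "next_trial",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Rule parameters of the transformed up/down procedure.

    ``start_range`` is the inclusive range of the random starting level:
    (5, 10) noise dots for birds, (10, 15) for humans.  Steps are in dots;
    the step size switches from ``step_initial`` to ``step_final`` after
    ``step_change_after_reversal`` reversals, and the track terminates after
    ``reversals_excluded + reversals_counted`` reversals in total.
    """

    n_up_correct: int = 3
    step_initial: int = 3
    step_final: int = 2
    step_change_after_reversal: int = 4
    reversals_excluded: int = 4
    reversals_counted: int = 12
    start_range: tuple[int, int] = (5, 10)
    level_floor: int = 0
    threshold_window: int = 10

    def __post_init__(self) -> None:
        for name in ("n_up_correct", "step_initial", "step_final",
                     "step_change_after_reversal", "reversals_excluded",
                     "reversals_counted", "threshold_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.level_floor < 0:
            raise ValueError("level_floor must be >= 0")
        if self.start_range[0] > self.start_range[1]:
            raise ValueError("start_range low must be <= high")

    @property
    def reversals_total(self) -> int:
        return self.reversals_excluded + self.reversals_counted


BIRD_STAIRCASE = StaircaseConfig(start_range=(5, 10))
HUMAN_STAIRCASE = StaircaseConfig(start_range=(10, 15))


@dataclass
class StaircaseState:
    """Mutable bookkeeping of one adaptive track."""

    level: int
    correct_streak: int = 0
    last_step_direction: str = "none"  # "up" | "down" | "none"
    reversal_count: int = 0
    trial_levels: list[int] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)
    terminated: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trial_levels)


@dataclass(frozen=True)
class TrialSpec:
    """What one trial presents: which track it feeds, the condition, the
    ground truth (intact vs scrambled), the noise count, and the facing."""

    staircase_id: tuple[tuple[str, str], int]  # ((domain, orientation), replicate)
    condition: tuple[str, str]
    truth: str
    n_noise: int
    facing: str


def init_staircase(
    config: StaircaseConfig, rng: np.random.Generator
) -> StaircaseState:
    """Fresh track with a uniform-random integer starting level in
    ``config.start_range`` (inclusive)."""
    lo, hi = config.start_range
    return StaircaseState(level=int(rng.integers(lo, hi + 1)))


def update(
    state: StaircaseState, correct: bool, config: StaircaseConfig | None = None
) -> StaircaseState:
    """Record one response and apply the 3-up/1-down rule; mutates and
    returns *state*.

    The recorded trial level is the level at presentation.  An up step fires
    when the correct streak reaches 3 (and resets it); any error resets the
    streak and fires a down step.  The step size is 3 dots until four
    reversals have occurred, 2 thereafter; a step opposite in direction to
    the previous applied step counts as a reversal.  The level is clamped at
    the floor (0 dots), and the track terminates at 16 total reversals.
    """
    config = config or StaircaseConfig()
    if state.terminated:
        raise RuntimeError("cannot update a terminated staircase")
    state.trial_levels.append(state.level)
    state.responses.append(bool(correct))

    direction: str | None = None
    if correct:
        state.correct_streak += 1
        if state.correct_streak >= config.n_up_correct:
            direction = "up"
            state.correct_streak = 0
    else:
        state.correct_streak = 0
        direction = "down"
    if direction is None:
        return state

    # step size is governed by the reversals accumulated before this step
    step = (
        config.step_final
        if state.reversal_count >= config.step_change_after_reversal
        else config.step_initial
    )
    if state.last_step_direction != "none" and direction != state.last_step_direction:
        state.reversal_count += 1
    state.last_step_direction = direction
    if direction == "up":
        state.level += step
    else:
        state.level = max(config.level_floor, state.level - step)
    if state.reversal_count >= config.reversals_total:
        state.terminated = True
    return state


def threshold(state: StaircaseState, config: StaircaseConfig | None = None) -> float:
    """Sensitivity of one track: mean noise count over its last 10 trials.

    Requires a terminated track with at least ``threshold_window`` trials.
    """
    config = config or StaircaseConfig()
    if not state.terminated:
        raise RuntimeError("threshold requires a terminated staircase")
    w = config.threshold_window
    if state.n_trials < w:
        raise RuntimeError(
            f"threshold requires >= {w} trials, got {state.n_trials}"
        )
    return float(np.mean(state.trial_levels[-w:]))


def pair_threshold(
    s1: StaircaseState, s2: StaircaseState, config: StaircaseConfig | None = None
) -> float:
    """Condition sensitivity: mean of the two replicate tracks' thresholds."""
    return (threshold(s1, config) + threshold(s2, config)) / 2.0


def next_trial(
    staircases: dict[tuple[tuple[str, str], int], StaircaseState],
    rng: np.random.Generator,
) -> TrialSpec:
    """Draw the next trial from the interleaved block.

    Picks uniformly among non-terminated tracks; the trial's truth (intact
    vs scrambled) and facing (left vs right) are each drawn with probability
    1/2, and its noise count is the chosen track's current level.
    """
    active = [sid for sid, st in staircases.items() if not st.terminated]
    if not active:
        raise RuntimeError("all staircases have terminated")
    sid = active[int(rng.integers(len(active)))]
    truth = "intact" if rng.random() < 0.5 else "scrambled"
    facing = "left" if rng.random() < 0.5 else "right"
    return TrialSpec(
        staircase_id=sid,
        condition=sid[0],
        truth=truth,
        n_noise=staircases[sid].level,
        facing=facing,
    )
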