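"""Simulated experimental sessions: blocks, practice, interleaved staircases.

A session has two blocks, one per object domain (bird, human), in a
counterbalanced order.  Each block starts with 28 practice trials without
noise and 28 with a constant 8 noise dots (logged but never fed to the
staircases), then runs four independent interleaved staircases — two
replicates for upright and two for inverted displays — until all four
terminate.  The per-condition sensitivity is the mean of the two replicate
thresholds (each the mean noise count of the track's last 10 trials).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import ParametricObserver, p_correct, respond
from .scramble import ScrambleConfig, compose_trial
from .staircase import (
    BIRD_STAIRCASE,
    HUMAN_STAIRCASE,
    StaircaseConfig,
    StaircaseState,
    TrialSpec,
    init_staircase,
    next_trial,
    pair_threshold,
    update,
)
from .stimuli import WALKER_VIEW_ANGLES, StimulusSpec, generate_stimulus
from .trajectory import ScreenGeometry

__all__ = ["SessionConfig", "SessionRecord", "run_block", "run_session",
           "write_session", "read_session", "simulate_staircase",
           "recompute_thresholds", "window_accuracy"]


def simulate_staircase(
    obs: ParametricObserver,
    config: StaircaseConfig,
    rng: np.random.Generator,
) -> StaircaseState:
    """Drive a single staircase against a parametric observer until it
    terminates (used for convergence and threshold-recovery studies)."""
    state = init_staircase(config, rng)
    while not state.terminated:
        correct = rng.random() < p_correct(obs, state.level)
        update(state, correct, config)
    return state


def window_accuracy(state: StaircaseState, window: int = 10) -> float:
    """Proportion correct over the last *window* trials of a track — the
    quantity the 3-up/1-down rule drives toward (1/2)^(1/3) ~ 79.4%."""
    if state.n_trials < window:
        raise ValueError(f"need >= {window} trials")
    return float(np.mean(state.responses[-window:]))

DOMAINS = ("bird", "human")
ORIENTATIONS = ("upright", "inverted")
CONDITIONS = tuple((d, o) for d in DOMAINS for o in ORIENTATIONS)

_TRIAL_COLUMNS = [
    "block", "phase", "domain", "orientation", "replicate", "trial_index",
    "n_noise", "truth", "facing", "correct", "level_after", "reversal_count",
]


@dataclass
class SessionConfig:
    """One simulated participant's session.

    ``observers`` maps each (domain, orientation) condition to the
    parametric observer answering its trials.  ``compose_stimuli`` controls
    whether the full display (signal + scrambling + noise dots) is
    synthesized on every trial; the parametric observer consumes only the
    noise count, so large batch simulations can turn composition off.
    """

    participant_id: str = "sim"
    group: str = "novice"  # "expert" | "novice"
    block_order: tuple[str, str] = ("bird", "human")
    observers: dict[tuple[str, str], ParametricObserver] = field(default_factory=dict)
    staircase_configs: dict[str, StaircaseConfig] = field(
        default_factory=lambda: {"bird": BIRD_STAIRCASE, "human": HUMAN_STAIRCASE}
    )
    scramble_config: ScrambleConfig = field(default_factory=ScrambleConfig)
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    n_practice_clean: int = 28
    n_practice_noise: int = 28
    practice_noise_level: int = 8
    compose_stimuli: bool = True

    def __post_init__(self) -> None:
        if sorted(self.block_order) != sorted(DOMAINS):
            raise ValueError("block_order must be a permutation of (bird, human)")
        if self.group not in ("expert", "novice"):
            raise ValueError("group must be expert or novice")


@dataclass
class SessionRecord:
    """Tidy per-trial log plus the per-condition threshold summary."""

    participant_id: str
    group: str
    trials: pd.DataFrame
    thresholds: pd.DataFrame  # columns: domain, orientation, threshold

    def condition_threshold(self, domain: str, orientation: str) -> float:
        m = (self.thresholds["domain"] == domain) & (
            self.thresholds["orientation"] == orientation
        )
        return float(self.thresholds.loc[m, "threshold"].iloc[0])


def _random_exemplar(domain: str, rng: np.random.Generator) -> int:
    if domain == "bird":
        return int(rng.integers(1, 8))
    return int(WALKER_VIEW_ANGLES[rng.integers(len(WALKER_VIEW_ANGLES))])


def _maybe_compose(
    config: SessionConfig, trial: TrialSpec, rng: np.random.Generator
) -> None:
    """Synthesize the trial display (signal, scrambling, noise, shuffle)."""
    domain, orientation = trial.condition
    spec = StimulusSpec(
        domain=domain,
        orientation=orientation,
        facing=trial.facing,
        exemplar_id=_random_exemplar(domain, rng),
    )
    signal = generate_stimulus(spec, rng, config.screen)
    compose_trial(
        signal,
        trial.truth,
        trial.n_noise,
        config.scramble_config,
        rng,
        condition=trial.condition,
    )


def run_block(
    domain: str,
    config: SessionConfig,
    rng: np.random.Generator,
    block_index: int = 0,
) -> tuple[list[dict], dict[tuple[str, str], tuple[StaircaseState, StaircaseState]]]:
    """Run one block: practice, then four interleaved staircases to
    termination.  Returns the trial rows and the per-orientation pair of
    terminated staircases."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    sc_config = config.staircase_configs[domain]
    rows: list[dict] = []

    # practice: fixed noise levels, random orientation/truth/facing, no updates
    practice_phases = [
        ("practice_clean", config.n_practice_clean, 0),
        ("practice_noise", config.n_practice_noise, config.practice_noise_level),
    ]
    for phase, n_trials, n_noise in practice_phases:
        for i in range(n_trials):
            orientation = ORIENTATIONS[int(rng.integers(2))]
            truth = "intact" if rng.random() < 0.5 else "scrambled"
            facing = "left" if rng.random() < 0.5 else "right"
            obs = config.observers[(domain, orientation)]
            trial = TrialSpec(
                staircase_id=((domain, orientation), 0),
                condition=(domain, orientation),
                truth=truth,
                n_noise=n_noise,
                facing=facing,
            )
            if config.compose_stimuli:
                _maybe_compose(config, trial, rng)
            correct = respond(obs, trial, rng)
            rows.append({
                "block": block_index, "phase": phase, "domain": domain,
                "orientation": orientation, "replicate": 0, "trial_index": i,
                "n_noise": n_noise, "truth": truth, "facing": facing,
                "correct": correct, "level_after": n_noise, "reversal_count": 0,
            })

    staircases: dict[tuple[tuple[str, str], int], StaircaseState] = {
        ((domain, o), r): init_staircase(sc_config, rng)
        for o in ORIENTATIONS
        for r in (1, 2)
    }
    trial_index = 0
    while any(not s.terminated for s in staircases.values()):
        trial = next_trial(staircases, rng)
        if config.compose_stimuli:
            _maybe_compose(config, trial, rng)
        obs = config.observers[trial.condition]
        correct = respond(obs, trial, rng)
        state = staircases[trial.staircase_id]
        update(state, correct, sc_config)
        rows.append({
            "block": block_index, "phase": "staircase", "domain": domain,
            "orientation": trial.condition[1],
            "replicate": trial.staircase_id[1], "trial_index": trial_index,
            "n_noise": trial.n_noise, "truth": trial.truth,
            "facing": trial.facing, "correct": correct,
            "level_after": state.level, "reversal_count": state.reversal_count,
        })
        trial_index += 1

    pairs = {
        (domain, o): (staircases[((domain, o), 1)], staircases[((domain, o), 2)])
        for o in ORIENTATIONS
    }
    return rows, pairs


def run_session(config: SessionConfig, rng: np.random.Generator) -> SessionRecord:
    """Run both blocks in ``config.block_order`` and summarize the four
    condition thresholds via the replicate-pair mean."""
    for cond in CONDITIONS:
        if cond not in config.observers:
            raise ValueError(f"no observer for condition {cond}")
    all_rows: list[dict] = []
    summaries: list[dict] = []
    for bi, domain in enumerate(config.block_order):
        rows, pairs = run_block(domain, config, rng, block_index=bi)
        all_rows.extend(rows)
        sc_config = config.staircase_configs[domain]
        for (d, o), (s1, s2) in pairs.items():
            summaries.append({
                "domain": d, "orientation": o,
                "threshold": pair_threshold(s1, s2, sc_config),
            })
    trials = pd.DataFrame(all_rows, columns=_TRIAL_COLUMNS)
    thresholds = pd.DataFrame(summaries).sort_values(
        ["domain", "orientation"], ignore_index=True
    )
    return SessionRecord(config.participant_id, config.group, trials, thresholds)


def write_session(record: SessionRecord, path) -> None:
    """Write a session as plain text: trials.csv, thresholds.csv, meta.json
    inside the directory *path* (created if needed)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    record.trials.to_csv(p / "trials.csv", index=False)
    record.thresholds.to_csv(p / "thresholds.csv", index=False)
    (p / "meta.json").write_text(json.dumps({
        "participant_id": record.participant_id, "group": record.group,
    }, indent=2))


def read_session(path) -> SessionRecord:
    """Reload a session written by :func:`write_session`."""
    p = Path(path)
    meta = json.loads((p / "meta.json").read_text())
    trials = pd.read_csv(p / "trials.csv")
    thresholds = pd.read_csv(p / "thresholds.csv")
    return SessionRecord(meta["participant_id"], meta["group"], trials, thresholds)


def recompute_thresholds(record: SessionRecord) -> pd.DataFrame:
    """Recompute the per-condition thresholds from the raw trial log
    (self-consistency check for the summary): for each condition, the mean
    over its two replicate tracks of the mean noise count in the track's
    last 10 trials."""
    sc = record.trials[record.trials["phase"] == "staircase"]
    out = []
    for (domain, orientation), grp in sc.groupby(["domain", "orientation"]):
        reps = []
        for _, track in grp.groupby("replicate"):
            track = track.sort_values("trial_index")
            reps.append(track["n_noise"].tail(10).mean())
        out.append({
            "domain": domain, "orientation": orientation,
            "threshold": float(np.mean(reps)),
        })
    return pd.DataFrame(out).sort_values(["domain", "orientation"], ignore_index=True)
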