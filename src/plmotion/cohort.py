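"""Synthetic participant cohorts with the study's factorial structure.

A cohort crosses group (expert, novice; between subjects) with object
domain (bird, human) and orientation (upright, inverted; both within
subjects).  Each participant contributes one sensitivity score — noise dots
at ~79% accuracy — per condition.  Two fidelities are provided:

* ``direct`` draws scores from cell means plus a shared per-participant
  offset and independent measurement noise (fast; used for calibration and
  power studies);
* ``full`` maps each participant's latent cell sensitivities to logistic
  observers whose 79.4%-correct point equals the latent value and runs the
  complete two-block staircase session, so scores inherit genuine staircase
  measurement noise.

The default cell means reproduce the qualitative pattern the study reports:
a large inversion effect for human walkers (upright ~29 vs inverted ~13
dots), none for birds (~11 vs ~10), and no group differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ParametricObserver
from .runner import CONDITIONS, SessionConfig, run_session

__all__ = ["CohortSpec", "DEFAULT_CELL_MEANS", "simulate_cohort_direct",
           "simulate_cohort_full", "simulate_cohort"]

GROUPS = ("expert", "novice")

# (group, domain, orientation) -> mean sensitivity in dots; both groups share
# the reported condition means since group effects were not significant.
DEFAULT_CELL_MEANS: dict[tuple[str, str, str], float] = {
    (g, d, o): m
    for g in GROUPS
    for (d, o), m in {
        ("human", "upright"): 28.97,
        ("human", "inverted"): 13.28,
        ("bird", "upright"): 11.19,
        ("bird", "inverted"): 10.08,
    }.items()
}


@dataclass
class CohortSpec:
    """Cohort structure: group sizes, the 8 cell means, and noise scales.

    ``between_subject_sd`` is the SD of a participant-level offset shared by
    all four of that participant's conditions; ``measurement_sd`` is
    independent per-condition noise (direct mode only — full-simulation mode
    gets its measurement noise from the staircases themselves).
    """

    n_per_group: int = 20
    condition_means: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_MEANS)
    )
    between_subject_sd: float = 10.0
    measurement_sd: float = 4.0
    observer_slope: float = 3.0
    observer_p_max: float = 0.99

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.between_subject_sd < 0 or self.measurement_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        expected = {(g, d, o) for g in GROUPS for d, o in CONDITIONS}
        if set(self.condition_means) != expected:
            raise ValueError("condition_means must cover all 8 (group, domain, "
                             "orientation) cells")


def _participant_ids(spec: CohortSpec) -> list[tuple[str, str]]:
    return [
        (g, f"{g[0]}{i + 1:02d}") for g in GROUPS for i in range(spec.n_per_group)
    ]


def simulate_cohort_direct(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a cohort table directly from the latent model.

    sensitivity = cell mean + participant offset (Normal(0, between_sd),
    shared across the participant's four cells) + Normal(0, measurement_sd),
    truncated at 0 dots.  Returns a long table with one row per participant
    x domain x orientation.
    """
    rows = []
    for group, pid in _participant_ids(spec):
        offset = rng.normal(0.0, spec.between_subject_sd)
        for domain, orientation in CONDITIONS:
            mean = spec.condition_means[(group, domain, orientation)]
            value = mean + offset + rng.normal(0.0, spec.measurement_sd)
            rows.append({
                "participant": pid, "group": group, "domain": domain,
                "orientation": orientation, "sensitivity": max(0.0, value),
            })
    return pd.DataFrame(rows)


def simulate_cohort_full(
    spec: CohortSpec,
    rng: np.random.Generator,
    compose_stimuli: bool = False,
) -> pd.DataFrame:
    """Simulate every participant's full two-block staircase session.

    Each participant's latent cell sensitivity (cell mean + shared offset,
    floored at 1 dot) parameterizes a logistic observer whose 79.4%-correct
    point equals that latent value; the reported sensitivity is then the
    staircase estimate from :func:`plmotion.runner.run_session`.  Block
    order is counterbalanced: the first half of each group runs bird-first.
    """
    rows = []
    for idx, (group, pid) in enumerate(_participant_ids(spec)):
        offset = rng.normal(0.0, spec.between_subject_sd)
        observers = {}
        for domain, orientation in CONDITIONS:
            latent = spec.condition_means[(group, domain, orientation)] + offset
            observers[(domain, orientation)] = ParametricObserver.with_threshold(
                max(1.0, latent),
                slope=spec.observer_slope,
                p_max=spec.observer_p_max,
            )
        bird_first = (idx % spec.n_per_group) < spec.n_per_group / 2
        config = SessionConfig(
            participant_id=pid,
            group=group,
            block_order=("bird", "human") if bird_first else ("human", "bird"),
            observers=observers,
            compose_stimuli=compose_stimuli,
        )
        record = run_session(config, rng)
        for domain, orientation in CONDITIONS:
            rows.append({
                "participant": pid, "group": group, "domain": domain,
                "orientation": orientation,
                "sensitivity": record.condition_threshold(domain, orientation),
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec, rng: np.random.Generator, mode: str = "direct"
) -> pd.DataFrame:
    """Dispatch to the requested fidelity ("direct" or "full")."""
    if mode == "direct":
        return simulate_cohort_direct(spec, rng)
    if mode == "full":
        return simulate_cohort_full(spec, rng)
    raise ValueError(f"unknown cohort mode {mode!r}")
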