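"""Simulated observers for the intact-vs-scrambled detection task.

The contractual observer is parametric: a logistic psychometric function
mapping the noise-dot count n to the probability of a correct response,

    p(n) = guess + (p_max - guess) / (1 + exp((n - mu) / slope)),

which falls from ``p_max`` (accuracy with no noise; 1 minus the lapse rate)
to the guessing rate 0.5 as noise increases.  ``mu`` is the inflection of
the decline and ``slope`` its width in dots.  The closed-form inverse
(:func:`percent_point`) defines the observer's "true" threshold at any
accuracy — in particular the 79.4%-correct point the 3-up/1-down staircase
tracks — which is what parameter-recovery tests compare against.

A structural observer front-end is also provided: it scores a trial by how
rigidly a displacement-matched subset of dots moves together, the relational
structure that spatial scrambling destroys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .scramble import TrialStimulus
from .staircase import TrialSpec
from .trajectory import Trajectory

__all__ = [
    "ParametricObserver",
    "p_correct",
    "percent_point",
    "respond",
    "structural_match_score",
    "CONVERGENCE_P",
]

# equilibrium accuracy of the 3-up/1-down rule: p with p^3 = 1/2
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class ParametricObserver:
    """Logistic observer: accuracy declines smoothly with the noise count.

    Parameters
    ----------
    mu
        Inflection point of the decline, in dots.
    slope
        Width of the decline, in dots; must be positive.
    p_max
        Asymptotic accuracy with no noise, in (0.5, 1].
    guess
        Guessing rate (two-alternative task: 0.5).
    """

    mu: float
    slope: float
    p_max: float = 0.99
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (self.guess < self.p_max <= 1.0):
            raise ValueError("require guess < p_max <= 1")

    @classmethod
    def with_threshold(
        cls,
        threshold_dots: float,
        p: float = CONVERGENCE_P,
        slope: float = 3.0,
        p_max: float = 0.99,
    ) -> "ParametricObserver":
        """Observer whose p-percent-correct point sits at ``threshold_dots``
        (by default the 79.4% point the staircase converges to)."""
        # invert percent_point for mu: n(p) = mu + slope*log((p_max-g)/(p-g) - 1)
        probe = cls(mu=0.0, slope=slope, p_max=p_max)
        return cls(
            mu=threshold_dots - percent_point(probe, p),
            slope=slope,
            p_max=p_max,
        )


def p_correct(obs: ParametricObserver, n_noise: float) -> float:
    """Probability of a correct response with ``n_noise`` noise dots."""
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    return float(
        obs.guess
        + (obs.p_max - obs.guess) * expit(-(n_noise - obs.mu) / obs.slope)
    )


def percent_point(obs: ParametricObserver, p: float) -> float:
    """The unique noise count at which accuracy equals *p* (logistic inverse).

    Defined for ``guess < p < p_max``; the midpoint (guess + p_max)/2 maps
    back to ``mu``.
    """
    if not (obs.guess < p < obs.p_max):
        raise ValueError(f"p must lie in ({obs.guess}, {obs.p_max}) exclusive")
    return obs.mu + obs.slope * np.log((obs.p_max - obs.guess) / (p - obs.guess) - 1.0)


def respond(
    obs: ParametricObserver, trial: TrialSpec, rng: np.random.Generator
) -> bool:
    """Bernoulli response: correct with probability p_correct(obs, n_noise)."""
    return bool(rng.random() < p_correct(obs, trial.n_noise))


def structural_match_score(trial: TrialStimulus, template: Trajectory) -> float:
    """Configural rigidity of the best displacement-matched dot subset.

    For each template dot, candidate trial dots are those whose displacement
    sequence matches exactly (scrambling and noise generation copy sequences
    verbatim, so exact matches exist by construction).  Dots are assigned
    greedily, each pick minimising the variance over frames of its distances
    to the already-assigned dots.  The score is the negative mean of the
    pairwise inter-dot distance variances of the assigned subset: 0 for a
    rigidly translating intact display, negative once relative motion exists.
    Intact trials score higher than scrambled ones in expectation.
    """
    if template.n_dots > trial.dots.n_dots:
        raise ValueError("template has more dots than the trial display")
    t_disp = template.displacements()
    d_disp = trial.dots.displacements()
    candidates: list[list[int]] = []
    for i in range(template.n_dots):
        cand = [
            j
            for j in range(trial.dots.n_dots)
            if np.array_equal(t_disp[i], d_disp[j])
        ]
        if not cand:
            raise ValueError(f"no displacement match for template dot {i}")
        candidates.append(cand)

    coords = trial.dots.coords
    # most-constrained template dots first: a dot with a unique displacement
    # match anchors the assignment on the true signal subset
    order = sorted(range(template.n_dots), key=lambda i: len(candidates[i]))

    def greedy(anchor: int) -> list[int]:
        assigned = [anchor]
        used = {anchor}
        for i in order[1:]:
            free = [j for j in candidates[i] if j not in used]
            if not free:
                raise ValueError(
                    f"no unused displacement match for template dot {i}"
                )
            prev = coords[assigned]  # (k, T, 2)
            costs = []
            for j in free:
                diff = prev - coords[j]
                dist = np.hypot(diff[..., 0], diff[..., 1])  # (k, T)
                costs.append(dist.var(axis=1).mean())
            pick = free[int(np.argmin(costs))]
            assigned.append(pick)
            used.add(pick)
        return assigned

    def subset_score(assigned: list[int]) -> float:
        sub = coords[assigned]
        k = len(assigned)
        if k < 2:
            return 0.0
        variances = []
        for a in range(k):
            for b in range(a + 1, k):
                diff = sub[a] - sub[b]
                variances.append(np.hypot(diff[:, 0], diff[:, 1]).var())
        return float(-np.mean(variances))

    # ambiguity in the anchor (noise dots duplicate signal displacement
    # sequences) is resolved by trying every anchor candidate and keeping
    # the most rigid assignment
    return max(subset_score(greedy(a)) for a in candidates[order[0]])
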