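"""One adaptive staircase against a simulated observer.

A 3-up/1-down track (steps 3 dots, then 2 after the fourth reversal,
terminating after 16 reversals) is run against a logistic observer whose
79.4%-correct point is at 20 noise dots.  The threshold estimate — the mean
noise count over the last 10 trials — should land near 20, and accuracy in
that window near (1/2)^(1/3) = 79.4%.
"""

import numpy as np

from plmotion import (
    CONVERGENCE_P,
    HUMAN_STAIRCASE,
    ParametricObserver,
    percent_point,
    simulate_staircase,
    threshold,
    window_accuracy,
)

obs = ParametricObserver.with_threshold(20.0)
print(f"observer: mu={obs.mu:.2f}, slope={obs.slope}, p_max={obs.p_max}")
print(f"true {100 * CONVERGENCE_P:.1f}%-correct point: "
      f"{percent_point(obs, CONVERGENCE_P):.1f} dots")

state = simulate_staircase(obs, HUMAN_STAIRCASE, np.random.default_rng(1))
print(f"trials: {state.n_trials}, reversals: {state.reversal_count}")
print(f"last 10 levels: {state.trial_levels[-10:]}")
print(f"threshold estimate: {threshold(state, HUMAN_STAIRCASE):.1f} dots")
print(f"window accuracy: {100 * window_accuracy(state):.0f}%")

# averaging many tracks tightens the estimate around the true point
est = [
    threshold(simulate_staircase(obs, HUMAN_STAIRCASE, np.random.default_rng(s)),
              HUMAN_STAIRCASE)
    for s in range(100)
]
print(f"mean over 100 tracks: {np.mean(est):.2f} dots (true: 20)")
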