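# Methods

`plmotion` simulates, end to end, a biological-motion detection experiment:
observers discriminate intact point-light (PL) displays from spatially
scrambled ones while both are embedded in noise dots, and the number of
noise dots tolerable at ~79% accuracy — the *sensitivity*, in dots — is
estimated with adaptive staircases and analysed in a mixed factorial design
(group: expert/novice, between subjects; object domain: bird/human and
orientation: upright/inverted, within subjects).

## Stimuli

A `Trajectory` holds per-dot, per-frame (x, y) positions in screen pixels
(y up, origin at the stimulus center after centering; 40 px/deg by default —
the original display's pixel geometry is a free parameter).

Because the original tagged bird footage and motion-capture walker files are
not deposited, the generators are parametric stand-ins.  They are designed
to honour the facts that are contractual for the pipeline, and nothing more:

* **Bird** — 7 dots (beak, 2 body, 4 wing), 75 frames / 2.5 s at 30 Hz,
  scaled to 4.8° × 2.1°.  Wing dots (mid-wing and tip per side) flap
  sinusoidally and in phase (default 2 Hz); axis dots carry small Gaussian
  positional jitter; the whole bird glides slowly across its bounding
  rectangle.  The glide widens the bounding box the way traversing footage
  would, which keeps the dots themselves central — this is what makes the
  bird's mean inversion displacement smaller than the walker's, the
  qualitative asymmetry the analysis relies on.  Vertical motion dominates:
  mean |Δy| > mean |Δx| per frame.
* **Walker** — 13 dots (head, shoulders, elbows, wrists, hips, knees, feet),
  30 frames / 1 s, scaled to 2.5° × 5.5°, treadmill-style (no net
  translation).  A 3-D articulated sinusoidal gait (1 Hz; left/right limbs
  in counter-phase, small double-frequency trunk bob) is orthographically
  projected at one of seven view angles, 150°–210° in 10° steps (180° =
  profile).  Horizontal motion dominates.  Projected width is normalised to
  the standard extent at every view rather than shrinking off-profile.

Flap/stride amplitudes and static postures were chosen so that **every
dot's total travel fits inside any scrambling grid segment plus the 25 px
slack** (travel ≤ extent/3 + 25 px per axis).  Without this, trial-by-trial
scrambling of a dot assigned to a far segment would be geometrically
infeasible.  Amplitudes are still large enough that the domain-specific
motion-axis dominance holds for every seed tested (1–100).

Orientation inversion is a literal 180° picture-plane rotation (point
reflection about the bounding-rectangle center), not a vertical flip; the
two differ by a left/right mirror, which the random facing absorbs.
Inversion and facing-mirroring are exact involutions and preserve
per-transition displacement magnitudes bit-for-bit.

**Coordinate grid.**  All trajectory coordinates are snapped to a binary
grid of 2⁻³⁰ px (~10⁻⁹ px) at construction.  With positions on a common
power-of-two grid and magnitudes below ~4·10⁶ px, constant-shift
translations and point reflections incur no floating-point rounding, so
scrambling preserves displacement sequences *exactly* (float equality), and
serialization (shortest-round-trip decimal) is bit-stable.  The grid is far
below any perceptual or statistical scale.

## Scrambling and noise dots

Scrambling redraws each dot's frame-1 position while replaying its exact
displacement sequence: the bounding rectangle (over all dots and frames) is
divided into a 3 × 3 grid; dots are assigned to segments as evenly as
possible (each segment holds ⌊n/9⌋ or ⌈n/9⌉ dots, the extras chosen
uniformly without replacement); a new start is drawn uniformly inside the
assigned segment and accepted only if **all** frames of the replayed path
stay within the rectangle expanded by 25 px on every side (rejection
sampling, bounded at 10,000 draws, then an error advising a larger slack).
The all-frames reading of the containment constraint was chosen over a
frame-1-only reading because the latter would let moving dots drift
arbitrarily far outside the display.

Noise dots copy, with replacement, the displacement sequence of a randomly
chosen signal dot and are repositioned by the same rule; their segment
assignment is computed over the noise set independently of the signal set,
and they are always generated from the current trial's stimulus.  A trial
display is the (possibly scrambled) signal plus noise with the dot order
uniformly shuffled, so dot identity cannot leak through ordering.

Consequences worth noting: scrambling never alters any single dot's motion,
so dots that co-moved rigidly (identical displacement sequences) remain
rigid after scrambling; what breaks is the spatial configuration of dots
with *different* motions, measured by `configural_variance` (variance over
frames of a pair's inter-dot distance: 0 for rigid pairs, positive
otherwise).  The optional structural observer scores a trial by the
rigidity of the best displacement-matched dot subset; it separates intact
from scrambled displays for rigid configurations, but for strongly
articulated displays the larger inter-dot separations after scrambling can
*reduce* raw distance variance, so it is a demonstration tool, not the
contractual observer.

## Staircases

The noise-dot count is driven by a transformed 3-up/1-down rule: three
consecutive correct responses raise the count (harder), one error lowers it
(easier); the equilibrium is the level where p(correct)³ = ½, i.e.
p = (½)^(1/3) ≈ 0.794.  Steps are 3 dots until four reversals have
occurred, 2 thereafter (the step that *causes* the fourth reversal still
uses the old size); a reversal is an applied step opposite in direction to
the previous applied step; a track terminates after 16 reversals in total
(4 initial ones discarded, 12 counted — the discarded ones matter only for
the step-size schedule, since the threshold uses trials, not reversals).
The level is clamped at 0 dots.  Starting levels are uniform random
integers: 5–10 for birds, 10–15 for humans.  The 3-in-a-row counter is kept
per staircase (two independent replicate tracks run per condition) and
resets after every applied up-step and after any error.  Correctness on
scrambled trials means correct rejection; both trial types feed the track.

A track's threshold is the mean presented level over its last 10 trials
(inclusive of the trial on which the final reversal occurred); a condition's
sensitivity is the mean of its two replicate thresholds.  Within a block,
four tracks (2 orientations × 2 replicates) interleave: each trial picks
uniformly among non-terminated tracks and draws truth (intact/scrambled)
and facing (left/right) each with probability ½.

## Observers

The contractual observer is logistic in the raw noise count:
p(n) = ½ + (p_max − ½) / (1 + exp((n − μ)/σ)), with closed-form inverse
`percent_point`.  A logistic (rather than Weibull) form keeps the inverse
closed-form; nothing in the pipeline depends on the choice.  Observers are
independent per condition (no shared state).  `with_threshold(t)` places
the 79.4%-correct point at exactly *t* dots, which is how "true"
sensitivities are injected for recovery studies.

## Sessions and cohorts

A session runs two blocks (bird, human) in a counterbalanced order.  Each
block starts with 28 practice trials without noise and 28 at a constant 8
noise dots; practice is logged but never updates the staircases.  Trial
timing (fixation, response screen) is presentation metadata and is not
simulated.  `SessionConfig.compose_stimuli` (default on) controls whether
the full display is synthesized each trial; the parametric observer reads
only the noise count, so batch cohort simulation turns composition off for
speed without changing any recorded number.

Cohorts come in two fidelities sharing one latent model — cell mean +
participant offset ~ N(0, between-subject SD):

* **direct**: adds independent N(0, measurement SD) noise per cell and
  truncates at 0 dots (thresholds cannot be negative);
* **full**: maps each participant's latent cell values to observers via
  `with_threshold` (floored at 1 dot) and runs the complete two-block
  session, so measurement noise is genuine staircase noise.  Block order is
  counterbalanced (first half of each group bird-first).

Default cell means follow the reported pattern (upright human 28.97,
inverted human 13.28, upright bird 11.19, inverted bird 10.08 dots, equal
across groups since no group effects were found); defaults for the noise
scales are between-subject SD 10 dots and measurement SD 4 dots, consistent
with the reported between-subject SEs (~2–3.6 dots at n = 40).  All values
are configurable.

## Statistics

* **Mixed 2 × 2 × 2 ANOVA**: explicit sums-of-squares decomposition with
  subject as a random factor nested in group.  Error strata: subjects
  within groups (tests group); domain × subject, orientation × subject and
  domain × orientation × subject within groups (test the corresponding
  within-subject effects); each error stratum has 2(n − 1) df.  No
  installed Python package covers two within-subject factors in a
  split-plot design, so the decomposition is implemented here and verified
  against an independent split-plot analysis (R's `aov` with
  `Error(subject/(domain*orientation))`) frozen into the test suite, plus
  an SS-conservation property (total SS = Σ effect + error SS to 1e-9
  relative) and a Monte-Carlo type-I calibration (each effect rejects at
  ~5% on null cohorts).  Degenerate inputs (zero error SS) raise.
* **Generalized eta squared**: SS_effect / (SS_effect + sum of all four
  subject-related error SS), the all-factors-manipulated convention.
* **Marginal means**: unweighted averages of constituent cell means; their
  SEs are between-subject SEs of participant-level marginal scores.
* **Welch's t** from group summaries with Welch–Satterthwaite df.  The
  expertise-score dispersions printed as "SE" (0.53, 0.30) are treated as
  SDs: with n = 19 and 20 only that reading reproduces the printed
  t(28.13) = 7.68 (reading them as SEs gives t ≈ 42).
* **Paired t** on matched per-participant scores, df = n − 1.  No
  multiple-testing correction is applied anywhere (none was used in the
  analysis being reproduced).

## Problem sizes and numerical choices

The verification studies use: 200 staircases for convergence, 50 staircase
pairs for threshold recovery, 500 seeded scrambles for the scrambling
invariants, 1,000 null cohorts at n = 10/group for type-I calibration, 100
cohorts at n = 20/group for the power check, and 10–20 participants per
group for full-fidelity cohort recovery — sizes at which Monte-Carlo error
is comfortably below the effects being checked while the whole suite runs
in well under a minute per study.  Random draws all flow through
`numpy.random.Generator`; every simulation entry point takes the generator
(or a seed) explicitly, and identical seeds reproduce sessions bit-for-bit.

## Limitations

* The generators emulate dot counts, durations, extents and motion-axis
  statistics, not the kinematics of real birds or real gait; absolute
  motion magnitudes (px/frame) and inversion-displacement values are
  properties of this synthetic geometry, and only their *directions*
  (vertical vs horizontal dominance; human displaced more than bird) carry
  over to the original stimuli.  Passing tests therefore validate the
  machinery, not claims about real footage.
* Simulated observers have no sequential dependencies, lapses beyond
  1 − p_max, fatigue, or learning; human staircase data are noisier.
* The structural observer is a demonstration of configural disruption, not
  a model of human strategy (see above).
* Bayes-factor analyses and trial-level d′ computation for the expertise
  test are out of scope; the expertise comparison enters only through its
  printed group summaries.
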