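# plmotion

Simulation and analysis machinery for point-light (PL) biological-motion
detection experiments, built for visual psychophysicists who want to
prototype, power, or validate staircase-based sensitivity designs before
(or instead of) running them on people.

The modelled task: on each trial an observer sees a PL display — a flying
bird (7 dots, 2.5 s) or a human walker (13 dots, 1 s) — either *intact* or
*spatially scrambled*, embedded in *n* noise dots, and reports which.
Scrambling redraws each dot's starting position on a 3 × 3 grid over the
display's bounding rectangle while replaying its frame-to-frame
displacement sequence exactly, so local motion is preserved and only the
global configuration is destroyed; noise dots copy signal-dot motions and
are placed the same way.  Sensitivity is the noise-dot count at ~79%
accuracy, tracked by a transformed 3-up/1-down staircase: three consecutive
correct responses make the task harder, one error makes it easier, which
converges on the level where p(correct) = (½)^(1/3) ≈ 0.794.  Thresholds
(mean level over a track's last 10 trials, averaged over two replicate
tracks per condition) feed a 2 × 2 × 2 mixed-design ANOVA — group (expert,
novice) between subjects; object domain (bird, human) and orientation
(upright, inverted) within — with generalized eta squared effect sizes,
marginal means, and Welch / paired t follow-ups.

The package provides every stage as a composable library: stimulus
synthesis (`plmotion.stimuli`), scrambling and trial composition
(`plmotion.scramble`), the staircase engine (`plmotion.staircase`),
psychometric simulated observers (`plmotion.observer`), session and cohort
simulation (`plmotion.runner`, `plmotion.cohort`) and the statistics stage
(`plmotion.analysis`), plus plain-text serialization for trajectories,
session logs and cohort tables.

## Worked example

Run a staircase against a logistic observer whose 79.4%-correct point is at
20 noise dots (`examples/run_staircase.py`):

```text
observer: mu=21.21, slope=3.0, p_max=0.99
true 79.4%-correct point: 20.0 dots
trials: 67, reversals: 16
last 10 levels: [17, 17, 19, 19, 19, 21, 21, 19, 19, 19]
threshold estimate: 19.0 dots
window accuracy: 90%
mean over 100 tracks: 19.63 dots (true: 20)
```

A single track terminates after 16 reversals and estimates the observer's
79.4% point to within a few dots; averaging tracks removes most of the
remaining noise (19.63 vs the true 20).  The other scripts in `examples/`
each demonstrate one capability — stimulus generation, scrambling, a full
two-block session, and cohort simulation with the complete ANOVA stage.
`examples/cohort_analysis.py` simulates a 20 + 20 cohort with the default
effect structure and prints, among other things:

```text
mixed ANOVA (group between; domain, orientation within):
                  effect      F  df_num  df_den      p   ges
                   group   0.47       1      38 0.4955 0.011
                  domain 171.12       1      38 0.0000 0.239
             orientation 224.15       1      38 0.0000 0.153
      domain:orientation 118.54       1      38 0.0000 0.095
```

— a large human inversion effect and no group effects, the pattern injected
by the default cohort specification.

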