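# thermarm

Thermal-imaging analysis of muscle activation during resistance training.

During isolated resistance exercise of the upper arm (brachium), the skin
above the working muscle warms: slowly while the weight is moving and much
faster during the recovery interval that follows, until the temperature
plateaus after a few minutes of rest. An infrared camera pointed at the
exposed arm therefore sees a localized, slowly developing hotspot over the
activated muscle — the biceps brachii, triceps brachii or deltoid, depending
on the exercise. `thermarm` turns sequences of skin-temperature frames into
that localization signal and classifies which muscle was activated.

The pipeline, per recorded session (sets of repetitions with recovery
intervals between them):

1. **Frame selection** — from the session protocol (sets × reps at a fixed
   cadence, recovery seconds between sets), compute the timestamps of the
   beginning (S1…Sn) and end (E1…En) of every set and pick the matching
   frames.
2. **Preprocessing** — orient the image so the biceps side faces left,
   apply a moving-average filter, segment the arm from the cool background
   with Otsu's global threshold (largest connected component, holes filled),
   and crop to the arm's bounding box.
3. **Heat maps** — divide the segmented region of interest into a
   60-row × 20-column grid and record each cell's mean temperature. The
   upper half of the grid is the deltoid region, the lower-left quadrant the
   biceps, the lower-right quadrant the triceps.
4. **Difference heat maps** — subtract the heat map at the start of the
   first set from later maps cellwise (heating is positive), e.g. the
   (S1, E3) pair spans the whole session. Region means of the difference
   map quantify each muscle's temperature rise; ranking the admissible
   pairs per session shows which time span separates the muscles best.
5. **Statistics** — per-phase elevation rates (°C/min), target-vs-nontarget
   temperature-difference trajectories, and a Kruskal–Wallis rank test for
   order effects across training orders.
6. **Classification** — the difference heat maps, labeled biceps / triceps /
   deltoid / vague ("vague" = no valid localized activation), optionally
   augmented by a 3 rotations × 3 scalings × 2 noise-state factorial, train
   a compact convolutional network (Adam, cross-entropy, learning rate 1e-4,
   batch 16, 50 epochs) that predicts the activated muscle from a single
   difference map.

Because thermal recordings of training sessions are not publicly available,
the package ships a first-class simulator (`thermarm.simulate`): a warm
elliptical arm on a cool background, piecewise-linear temperature dynamics
(default 0.13 °C/min during exercise, 0.47 °C/min during recovery, plateau
after 3 min), a Gaussian hotspot over the target muscle, diffuse arm-wide
warming, and Gaussian sensor noise at the camera's 0.05 °C sensitivity.
Every analysis in the package is exercised end to end on simulated sessions.

## Worked example

```python
from thermarm import (MuscleClass, SessionProtocol, simulate_session,
                      select_set_heatmaps, diff_heatmap, region_means)
from thermarm.benchmark import study_config

protocol = SessionProtocol(n_sets=3, reps_per_set=12, rep_rate=15,
                           recovery_s=92, weight_kg=10,
                           target_muscle=MuscleClass.BICEPS, arm_side="left")
config = study_config(MuscleClass.BICEPS, seed=0, noise_sd=0.05)

recording = simulate_session(protocol, config)     # 83 frames, 0–328 s
heatmaps = select_set_heatmaps(recording)          # S1,E1,...,S3,E3
change = diff_heatmap(heatmaps, ("S1", "E3"))      # Δ°C over the session
print(region_means(change))
```

Output:

```
RegionSummary(deltoid=0.5295850067290138, biceps=1.703405437203744, triceps=0.7900776077213062)
```

The biceps region warmed by about 1.7 °C over the three-set session —
roughly the 0.13 °C/min × 3 × 48 s of exercise plus 0.47 °C/min × 2 × 92 s
of recovery that the dynamics model prescribes — while the nontarget
regions show only the diffuse-warming share plus hotspot spill, so the
activated muscle is immediately identifiable from the difference map.

The same pipeline is available from the shell:

```sh
thermarm demo --seed 0 --outdir demo/
```

which simulates a small labeled study, writes heat maps and difference maps
as CSV, produces the region statistics report and trains/evaluates the
classifier (metrics in `demo/classifier/metrics.json`).

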