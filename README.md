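# pitchkit

Quantitative analysis of pitch-axis posture and locomotion in freely
swimming larval zebrafish, plus decoding of pitch-tilt direction from
cerebellar Purkinje-cell responses.

Larval zebrafish swim in discrete bouts and balance in the pitch
(nose-up/nose-down) axis by coordinating trunk rotations, which redirect
thrust, with fin movements, which generate lift. High-throughput videographic
assays (SAMPL-style apparatus) record each fish's horizontal position *x*,
depth *z*, and pitch angle over hours; tilt-in-place microscopy records
Purkinje-cell calcium responses to rapid body tilts. `pitchkit` implements
the full analysis chain for both kinds of data, for behavioral
neuroscientists who need the standard kinematic, statistical and decoding
conventions in one tested package — together with a synthetic-data generator
so that every stage can be validated against known ground truth without any
recordings.

## What it computes

**Swim bouts.** Speed is `sqrt(dx² + dz²)·fs` by centered differences; a bout
is a maximal interval with speed > 5 mm/s, aligned at peak speed into a
−250…+250 ms window. Bouts are excluded for peak speed < 5 mm/s or > 30° of
pitch rotation during the acceleration phase; repeats with < 650 accepted
bouts are dropped, and control/condition repeats are subsampled to matched
bout counts.

**Per-bout kinematics.** Posture (pitch at −250 ms), trajectory
(`atan2(Δz, |Δx|)` at peak speed; climbs > 0°, dives otherwise), upward
rotation (pitch change from −250 ms to the peak angular velocity), and lift —
the depth change in excess of posture-predicted travel,

```
lift = Δz(−100…+100 ms) − |Δx(−100…+100 ms)| · tan(pitch(−100 ms))
```

with peak speed assigning bouts to slow [5, 7.5), medium [7.5, 15) or
fast [15, ∞) mm/s bins.

**Fin–body coordination.** Within each speed bin, the slope of a robust
linear fit (Tukey bisquare, c = 4.685) of lift against upward rotation, over
bouts with positive rotation and positive lift; 100-sample bootstrap for
slope and R², a group p-value from the overlap of bootstrap distributions,
Spearman correlation of the lift/rotation ratio with speed, and Fisher-z
comparison of correlations.

**Group statistics.** Percentile-bootstrap 95% CIs of medians (1000
samples), two-sided Wilcoxon rank-sum tests with Šidák-corrected critical p,
scaled-MAD outlier detection (3 × 1.4826 × MAD), Fisher's exact test for
activated-cell counts (activated iff F/F₀ > 2), and the effect-size
convention `100·(condition − control)/reference` with significance requiring
both p < p_critical and |effect| ≥ 15%.

**Tilt decoding.** dF/F normalization, per-trial integrated responses (or
peak dF/F in the first second after return, for the return-tilt protocol),
the directionality index `DI = (up − down)/(up + down)` with |DI| > 0.35
defining tuned cells, PCA of trials × cells response matrices, and a
linear-kernel SVM under stratified 5-fold cross-validation with a
100-shuffle label-permutation null, evaluated on pseudo-populations of 3–13
untuned cells.

## Worked example

```python
import numpy as np
from pitchkit import (SwimSimParams, generate_epoch, segment_epoch,
                      kinematics_table, fit_speed_bins, speed_ratio_correlation)

params = SwimSimParams(fs=160, duration=480, bout_rate=0.5, seed=42)
epoch, truth = generate_epoch(params)
bouts = segment_epoch(epoch)
kin = kinematics_table(bouts)
print(f"{len(bouts)} bouts detected ({len(truth)} generated), "
      f"{(kin.direction_class == 'climb').mean():.0%} climbs")
fits = fit_speed_bins(kin, n_boot=100, seed=0)
for name, fit in fits.items():
    lo, hi = np.percentile(fit.bootstrap_slopes, [2.5, 97.5])
    print(f"{name:>6}: slope {fit.slope:.4f} mm/deg  (95% CI {lo:.4f}-{hi:.4f}, "
          f"R2 {fit.r2:.2f}, n={fit.n_bouts})")
rho = speed_ratio_correlation(kin)
print(f"lift/rotation ratio vs speed: Spearman rho = {rho.rho:.3f} (n={rho.n})")
```

prints

```
201 bouts detected (201 generated), 87% climbs
  slow: slope 0.0234 mm/deg  (95% CI 0.0173-0.0325, R2 0.63, n=18)
medium: slope 0.0415 mm/deg  (95% CI 0.0392-0.0440, R2 0.90, n=135)
  fast: slope 0.0733 mm/deg  (95% CI 0.0702-0.0764, R2 0.97, n=46)
lift/rotation ratio vs speed: Spearman rho = 0.569 (n=199)
```

Every generated bout is found again by segmentation, the fitted slopes
bracket the generator's lift gains (0.03/0.04/0.07 mm/deg per bin), and the
lift/rotation ratio rises with speed because the gains do. The same pattern
continues on the neural side:

```python
from pitchkit import (CellSimParams, generate_cell_trials, build_cell_response,
                      pseudo_population_decode)

M, labels = generate_cell_trials(CellSimParams(seed=42), 13)
cells = [build_cell_response(f"c{i:02d}", M[:, i], labels) for i in range(13)]
untuned = [c for c in cells if c.tuning_class == "untuned"]
print(f"{len(untuned)}/13 cells untuned (|DI| < 0.35)")
for size, res in pseudo_population_decode(untuned, sizes=(3, 7, 13),
                                          n_draws=20, seed=0).items():
    lo, hi = res.iqr
    print(f"{size:>2} cells: median accuracy {res.median:.2f}  [IQR {lo:.2f}-{hi:.2f}]")
```

```
13/13 cells untuned (|DI| < 0.35)
 3 cells: median accuracy 0.88  [IQR 0.82-0.97]
 7 cells: median accuracy 0.97  [IQR 0.93-1.00]
13 cells: median accuracy 1.00  [IQR 1.00-1.00]
```

No single cell is directionally tuned, yet the population decodes tilt
direction almost perfectly once a handful of cells are pooled — the
shared-signal regime the generator is built to emulate.

A command-line interface mirrors the library
(`pitchkit simulate | segment | kinematics | coordination | stats | decode`);
see `pitchkit --help`.

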