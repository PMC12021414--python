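# Methods

This note records the models, conventions and numerical choices behind
`pitchkit`, what the synthetic-data generator does and does not emulate, and
the known limitations. It documents how quantities are computed; every
empirical number cited here is produced by the test suite or by
`scripts/acceptance.py`.

## Coordinate and measurement conventions

Pitch is the angle between the fish's long body axis and the horizon,
positive nose-up, in degrees. Depth *z* is in mm, positive up; horizontal
position *x* is in mm with no preferred direction — fish swim both ways, so
wherever a horizontal displacement enters a formula it enters as a magnitude
and any sign is carried by depth. Epochs are uniform time series at 40 or
160 Hz; both rates place the analysis marks (−250, −100, 0, +100 ms around a
bout's peak speed) on exact grid samples, which is why those two rates are
enforced rather than resampling silently.

Speed is computed from centered differences (one-sided at the ends) with no
smoothing. Whether the acquisition software smooths speed before
thresholding is not documented for the source apparatus; unsmoothed is the
most literal reading of a bare threshold, and a smoothing option is exposed
rather than guessed at.

## Bout segmentation and screening

A bout is a maximal contiguous interval with speed strictly greater than
5 mm/s, indexed by the argmax of speed within the interval (ties to the
earlier sample — arbitrary but fixed). Windows span ±250 ms around the peak;
a window that runs past either end of the epoch is excluded as
`window_out_of_bounds`. The two kinematic exclusions are strict in the
stated direction: peak speed < 5 mm/s excludes, and pitch rotation over the
acceleration phase (−250…0 ms) strictly greater than 30° excludes, so a bout
rotating exactly 30° is kept. The rotation rule uses the *net* pitch change
over the acceleration phase; cumulative path rotation was rejected because
it is not equivalent to a 30°-in-250-ms (120°/s) criterion. Experimental
repeats with fewer than 650 accepted bouts are dropped (649 drops, 650
keeps), and the larger of a control/condition repeat pair is subsampled
without replacement, seeded, to the smaller count before any comparison.

## Per-bout kinematics

* **Posture**: pitch at the −250 ms sample.
* **Trajectory**: `atan2(Δz, |Δx|)` in degrees over the two frames
  bracketing the peak-speed sample. Climb iff trajectory > 0°; both the
  climb and dive definitions are strict inequalities, so exactly 0° needs a
  tie rule — it classifies as dive by default and the rule is configurable.
  A bout with zero displacement in both axes has undefined trajectory and is
  dropped from direction-classified analyses.
* **Upward rotation**: angular velocity is the centered difference of pitch
  times fs; its peak is searched over −250…0 ms (the acceleration phase,
  where trunk rotation redirects thrust), and the rotation is pitch at that
  moment minus pitch at −250 ms. Ties in the argmax break toward the *later*
  sample: a constant-rate ramp has tied interior angular velocities, and the
  later-sample rule reports the full extent of the ramp rather than its
  first step. The exact search window is an interpretation (the convention's
  source does not state one); it is a parameter in spirit, fixed here.
* **Lift**: `observed_dz − expected_dz` with
  `expected_dz = |Δx(−100…+100 ms)| · tan(pitch(−100 ms))`. A reference
  pitch at or beyond ±90° is an error (degenerate tangent). Lift is the
  fins' contribution to depth change; expected_dz is the trunk's.
* **Speed bins**: half-open, [5, 7.5) slow, [7.5, 15) medium, [15, ∞) fast
  mm/s, assigned from peak speed of accepted bouts only.

## Fin–body coordination

Within each speed bin, lift is regressed on upward rotation over bouts with
strictly positive rotation and strictly positive lift (the qualifying rule
of the convention this package implements). The fit is iteratively
reweighted least squares with Tukey bisquare weights, tuning constant 4.685
(the conventional 95%-efficiency value; only "bisquare" is specified
upstream), at most 50 iterations, convergence when coefficients change by
less than 1e−8. The implementation delegates the IRLS to statsmodels' RLM
behind the package's own interface; an exact line (zero residuals) is
returned from the OLS fit directly because the robust scale estimate
degenerates at zero. R² is reported as plain `1 − SSres/SStot` over all
fitted points (a robust-weighted variant is available by flag). Bins with
fewer than 10 qualifying bouts (configurable) are reported absent, never
extrapolated.

Slope and R² uncertainty come from a 100-draw bootstrap over qualifying
bouts, summarized as median with 25th/75th percentiles. The group p-value is
computed from the overlap of the two groups' bootstrap slope distributions:
the smaller one-sided fraction of pairwise differences crossing zero,
add-one corrected, doubled and capped at 1 — so fully separated
distributions yield the minimum attainable p for the number of draws rather
than zero. Speed dependence of the lift/rotation ratio is Spearman's rank
correlation (average ranks for ties); two correlations are compared by
Fisher's z-transform, `z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3) + 1/(n₂−3))`,
with n taken as the number of bouts (exposed as a parameter, since the
choice of n is not fixed by the convention).

## Group statistics

Medians carry percentile-bootstrap 95% CIs (1000 resamples, seeded). Group
differences use the two-sided Wilcoxon rank-sum test — exact enumeration
when the pooled sample is ≤ 20 and tie-free, otherwise the normal
approximation with tie and continuity corrections. The critical p for a
family of m parameter comparisons is Šidák's `1 − (1−α)^(1/m)` with
α = 0.05; m comes from the analysis manifest because the convention reports
it per dataset without a formula. Effect size is
`100·(condition − control)/reference`, reference = control value except for
fin-slope comparisons, which use the control fast-bin slope to avoid
inflating changes measured against small control slopes; values are
reported rounded to integer percent with full precision retained in tables.
Significance requires both p < p_critical and |effect| ≥ 15%. Outliers
deviate more than 3 × 1.4826 × MAD from the median; a zero MAD has no finite
threshold, and the documented degenerate rule flags any value different from
the median (real data never hits this). Activated-cell counts (activated
iff F/F₀ > 2, strict) are compared with Fisher's exact test, two-sided by
summing hypergeometric probabilities no larger than the observed table's.

## Tilt-response analysis and decoding

Traces are normalized as `(F − F₀)/F₀` with a positive baseline mean — the
pre-trial window average for the return-tilt (±19°) protocol, the
anesthetized eccentric baseline for the ±30° protocol. The per-trial
response statistic is the trapezoidal integral of dF/F over the 15 s
stimulus for the ±30° protocol and the maximum dF/F within (0, 1] s after
return (3 samples at 3.82 volumes/s) for the ±19° protocol. The
directionality index is `(mean_up − mean_down)/(mean_up + mean_down)`;
|DI| strictly greater than 0.35 defines tuned cells, and a non-positive
denominator (possible with negative integrals) makes the cell
unclassifiable — it is excluded with a log entry rather than given an
unbounded index.

PCA is column-centered on the covariance scale (correlation scaling was the
other candidate; covariance preserves each cell's response magnitude, and
the decoder standardizes separately anyway). Decoding uses a linear-kernel
SVM with unit regularization — only "linear kernel" is fixed by the
convention, so C = 1 and per-training-fold standardization are explicit,
exposed parameters. Cross-validation is stratified 5-fold (the trial design
is balanced, 21 up / 21 down; plain k-fold is available), accuracy is one
minus the mean held-out 0–1 loss, and k is reduced with a warning if a class
has fewer than k trials. The null distribution comes from 100 decoding runs
with permuted trial identities; the reported p is the add-one fraction of
null accuracies at or above the observed one, which is super-uniform under
the null by construction. Pseudo-populations align trials by type (all up,
then all down) — the construction itself, since cells were not recorded
simultaneously; for each ensemble size, random cell subsets are drawn and
the full pool admits exactly one subset, hence zero spread. The
least-tuned-subset control selects the n cells with smallest |DI|, ties by
cell id.

## The synthetic-data generator

The swim generator produces what the analysis assumes: discrete bouts of
rapid translation over a quiescent baseline. Bout count is Poisson with the
requested rate; candidate peak times are uniform, and candidates closer than
0.6 s to an accepted one are dropped (never merged), so each pulse crosses
the 5 mm/s threshold as exactly one contiguous interval. Per bout the
generator draws a climb/dive launch posture, an upward rotation (normal,
truncated below at 0.5° — the peak-angular-velocity estimator cannot
recover a downward ramp, and near-zero rotations make lift/rotation ratios
unstable), a horizontal-speed amplitude (normal truncated at 5.5 mm/s) and
a random ±x travel direction.

Three analytic primitives make the construction exact under the downstream
estimators, which is the point of the module:

* the horizontal speed pulse is a raised cosine of half-width 150 ms;
* the pitch ramp is the integral of a raised-cosine angular-velocity bump of
  half-width 250 ms whose peak falls on the peak-speed sample, so the
  measured upward rotation (pitch at peak angular velocity minus pitch at
  −250 ms) equals the drawn value exactly — a ramp that goes flat at the
  peak cannot achieve this, because the centered-difference argmax then
  lands inside the ramp;
* depth is built from the −100 ms reference pitch plus a lift bump supported
  on −100…+100 ms integrating to `gain(speed bin) × rotation + noise`, so
  the lift formula recovers the drawn lift exactly.

Because the lift bump itself feeds back on peak speed, the speed-bin
assignment is iterated (≤ 5 rounds); the rare bout that oscillates between
bins at a boundary is dropped and logged. With all noise off, bout counts,
postures, rotations and lifts are recovered to numerical precision (the
suite asserts ≤ 1e−6; observed ~1e−14).

Noise model — and what it is *not*. Pitch noise is band-limited (white noise
convolved with a 50 ms Gaussian kernel, scaled to the requested marginal
sd): a body with rotational inertia cannot jump degree-scale between 6 ms
frames, and white per-sample noise would make any derivative-based angular
velocity meaningless at 160 Hz. The default sds (pitch 0.1°, lift 0.04 mm)
are at tracking-precision scale, deliberately. Two mechanisms push fitted
slopes away from the generative gain as noise grows: pitch noise perturbs
the regressor (errors-in-variables attenuation, which biases *every* slope
estimator), and lift noise is truncated by the positive-lift qualifying
rule (selection bias, strongest in the slow bin where lifts are smallest).
Parameter recovery is therefore only a well-posed claim in the
measurement-noise regime, and that is the regime the defaults define. The
consequences are stated plainly: synthetic fits are far cleaner (R² ≈
0.6–0.97) than fits to real fish, the generator does not model biological
trial-to-trial scatter, refractory dynamics, restorative post-bout
rotations, or tracking dropouts, and passing the recovery tests demonstrates
that the estimators are calibrated — not that they are robust to biological
variability. Note also that the generator's climb/dive *draw* controls the
launch-posture distribution while the analysis classifies direction from
the trajectory at peak speed; shallow dive-drawn bouts with positive lift
can legitimately classify as climbs, so the climb fraction measured on
default settings exceeds the draw probability, and the correspondence is
only tight when the two posture distributions are well separated.

The tilt-trial generator draws per-trial integrated responses as
`mean(direction) + dir · s · wᵢ + ε`, with loadings `wᵢ ~ N(0, 1)` per cell
and `s` the shared-direction-signal scale. Zero-mean loadings keep the
expected DI of every cell at zero (an explicit invariant) while the
population carries direction information of magnitude `s·‖w‖` along the
loading vector — the untuned-but-collectively-decodable regime. Correlated
noise could produce the same phenomenology; the latent-signal form was
chosen for analytic control of per-cell DI. Defaults (21 trials per
direction, means 10, trial noise 1, s = 1) put a 13-cell pool near ceiling
accuracy while every cell stays below the 0.35 tuning cutoff with high
probability. Both generators use a single seeded numpy PCG64 stream per
call and are bit-identical under a fixed seed.

## Problem sizes and runtime choices

The suite's heavier checks use 480 s epochs at 160 Hz and 0.5 bouts/s
(~190 accepted bouts, all three speed bins populated), 50 seeded replicates
for bootstrap-interval calibration of the slope fits, 50 replicates × 100
shuffles for the decoding null, and 50 signal-free replicates for the
chance-level check. These sizes were chosen so each check has enough
resolution to fail informatively while the whole suite runs in minutes on a
single core. The acceptance script uses the same sizes.

## Known limitations

* The epoch format is package-defined (delimited text plus a YAML
  manifest); no proprietary acquisition format is read.
* Roll- and yaw-axis kinematics are out of scope, as is any post-bout
  restorative-rotation analysis.
* The coordination analysis treats bouts as exchangeable within a group;
  there is no mixed-effects modeling across fish (bouts are anonymous in
  the assay).
* The decoder's regularization and standardization choices are conventions,
  not fitted hyperparameters; no model selection is performed.
* The generator's depth construction uses the −100 ms reference pitch for
  the whole bout rather than integrating instantaneous pitch, an
  idealization that makes the lift definition exact by construction.
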