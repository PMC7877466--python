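# Methods

This note documents the models, numerical choices, and limitations of the
`nfloop` simulation and analysis pipeline.

## Experimental model

The package simulates a single-session SMA neurofeedback study: 10
neurofeedback (NF) and 10 yoked-sham subjects, each completing one
localizer run (7 × 16 s fixation / 6 × 30 s bimanual tapping, 292 s) and
seven NF runs (10 × 16 s fixation / 9 × 30 s feedback, 430 s), at
TR = 2 s, plus a Go/No-go reaction-time test before and after the
session. Volume *i* covers the half-open interval [i·TR, (i+1)·TR); block
onsets are in seconds from run start.

## Hemodynamic model

Task regressors are unit boxcars convolved with the canonical
double-gamma HRF (SPM parameterization: response peak 6 s, undershoot
peak 16 s, response/undershoot ratio 6), sampled at the TR via
`nilearn`'s `spm_hrf`. The kernel is normalized to unit sum, so the
response to a sustained block plateaus at 1 and a generator amplitude
*a* equals the plateau signal change in raw units. Amplitudes sit on a
baseline of 100 raw units, so *a* = 1 is a 1% sustained signal change.

## Synthetic BOLD generator

Each run is `baseline + Σ_regions amplitude·regressor + drift + nuisance
+ AR(1) noise` on a 24 × 24 × 12 lattice of 3-mm isotropic voxels (large
enough for spatially meaningful cluster statistics, small enough that
whole-brain Monte-Carlo runs in seconds). Defaults, chosen once as the
study conditions:

| parameter | default | rationale |
|---|---|---|
| noise SD `sigma` | 1.0 (1% of baseline) | typical single-voxel BOLD noise level |
| AR(1) `ar1_phi` | 0.3 | typical short-TR temporal autocorrelation |
| linear drift | 1 unit/run, per-voxel gain U(0.5, 1.5) | slow scanner drift |
| cosine drift | 0.5, 0.3 units at 1 and 2 cycles/run | low-frequency physiological drift |
| NF SMA trajectory | base 0.252, slope 0.062 units/run | the fitted learning line used as generator truth |
| sham SMA trajectory | flat at 0 | no upregulation under yoked feedback |
| non-specific motor amplitude | 0.3, both groups | motor imagery engages the wider motor network |
| localizer tapping amplitude | 1.0, all motor blobs | overt movement responds strongly |
| between-subject amplitude SD | 0.05 | moderate individual differences |
| Go/No-go mean RT | 380 ms pre; −30 ms post, right hand, NF only | the group-specific training effect |

Per-run amplitudes follow `base + slope·(run−1)`, floored at zero. The
sham trajectory is generated flat rather than declining; a declining
sham is available through configuration. Motion is emitted only as six
smooth random-walk confound columns — it does not displace voxels — so
the online motion-correction stage can be an identity pass-through and
the loop is testable without a registration engine. White-matter and
ventricle blocks carry their own slow signals whose spatial means form
the `wm`/`vent` confound columns.

What the generator does **not** emulate: image displacement from motion,
slice-timing offsets (volumes are generated at volume resolution),
physiological waveforms (cardiac/respiratory), susceptibility artifacts,
spatial heterogeneity of the HRF, and non-linear BOLD saturation.
Passing tests therefore demonstrate the correctness and calibration of
the *analysis machinery* under the assumed signal model, not robustness
to every artifact of real scanner data.

## Online engine

Streaming preprocessing is detrend-then-smooth. The incremental detrend
keeps per-voxel running sums and subtracts the currently estimated
linear trend referenced to time zero, preserving the (positive) signal
level that the feedback baseline division requires. Smoothing is a
normalized 8-mm FWHM Gaussian (reflect boundary, which preserves the
image mean exactly). Slice-timing and motion stages accept pluggable
callables for real data and default to identity on phantom input.

The cumulative GLM accumulates the normal equations (X'X, X'y, y'y) and
solves on demand, so estimates after k volumes are exactly a batch OLS
fit on those k volumes (asserted against `lstsq` in tests rather than
trusting the recursion). t statistics are reported only once the design
has at least p+2 volumes and full rank; rank deficiency is flagged, not
raised.

ROI delineation thresholds the tapping t-map at t > 5.0 inside the
search box (the tight bounding box of the SMA blob plus one voxel) and
keeps the largest 6-face-connected component. The reference region is a
full axial slice distant from all motor blobs. The feedback baseline is
recomputed at every fixation→feedback transition from the last three
fixation volumes of the block immediately preceding — the only causal
choice. The thermometer height is the continuous value; display
quantization is available but off by default. Sham subjects replay a
recorded trace (each control is yoked, uniformly with replacement, to
one of the first seven NF subjects) while their own ROI means are still
logged, so the offline β analysis treats both groups identically.

## Offline engine

Preprocessing discards the first two volumes (T1 equilibration), then
projects out a drift basis — centered linear trend plus DCT components
at or below 3 cycles/run (basis functions k = 1..6; DCT basis k spans
k/2 cycles) — and smooths at 4-mm FWHM. All drift columns are zero-mean,
so the signal mean survives for percent-signal-change computations. The
first-level design (task regressor computed on the full design and
truncated, preserving convolution history, plus motion/WM/ventricle
confounds) passes through the same drift projection as the data, which
keeps the task β unbiased; constant confound columns are dropped as
degenerate with the intercept. Designs with condition number above 1e8
are rejected, naming near-duplicate columns.

The ROI-GLM averages the mask time course first, then fits — by
linearity equal to averaging per-voxel βs, and asserted so in tests.
Event-related averages baseline each feedback block to the mean of the
three pre-onset volumes (mirroring the online three-volume rule) and
report mean ± SEM across blocks; blocks whose window leaves the run are
skipped with a log entry.

## Group statistics

The mixed-design ANOVA is the classical balanced split-plot
decomposition, computed by inclusion-exclusion over margin means:
subjects are random and nested in the between factor; between effects
test against subjects-within-groups, within effects against their
interaction with subjects-within-groups. It is cross-checked against an
explicit hand sums-of-squares oracle on a 2×2×2 table and against
`pingouin` for the two-way case. Greenhouse–Geisser epsilons are
computed and reported, but headline F/df/p use uncorrected degrees of
freedom. All tests are two-sided by default.

The group × run linear trend is tested as a per-subject contrast score
(centered run weights · β) compared between groups — F(1, 18) with
10+10 subjects. Learning slopes come from OLS of the seven per-run group
means on run number (F(1, 5)); slopes are compared with a pooled-SE t on
(7−2)+(7−2) = 10 df. ROI specificity uses a deviation contrast: each
ROI's per-subject linear trend of (ROI − mean of the other six ROIs),
compared between groups, one F(1, 18) per ROI. Go/No-go analysis trims
reaction times outside 100–1000 ms (the target display limit), averages
valid go trials per subject × hand × session, runs the three-way mixed
ANOVA (hand × session within, group between) and the four per-group,
per-hand pre/post paired t tests.

## Whole-brain inference

Group maps are voxel-wise one-sample t (df n−1), pooled two-sample t
(df n_A+n_B−2), and the group × run interaction F from the same mixed
decomposition vectorized over voxels (df (r−1), (r−1)(N−g)); voxels with
zero variance are masked. Spatial smoothness is estimated per axis from
the lag-1 autocorrelation ρ of standardized residual volumes under a
Gaussian-kernel autocorrelation model (σ² = −1/(4 ln ρ)), combined by
geometric mean and floored at one voxel — smoothness below the sampling
grid is unresolvable, so white noise reports ≈ 1 voxel. Monte-Carlo
calibration simulates null fields by smoothing white noise to the target
FWHM on a periodic lattice and re-standardizing, thresholds one-sided at
the voxel p, and records the maximal cluster size per iteration; the
minimum cluster extent is the smallest k with empirical
P(max ≥ k) ≤ α, and clusters of exactly that size survive. Cluster
formation uses 18-neighbor connectivity by default (6 and 26 available).

## Orchestration and reproducibility

One YAML file specifies a study; `validate_config` returns typed
error/warning issues without mutating the config. All randomness derives
from a single master seed through `SeedSequence` spawn keys — per
subject, per run, per analysis stage — so adding a subject never
perturbs existing ones and two runs with the same seed are
byte-identical. The NF group is simulated first because its recorded
feedback traces form the sham pool.

Problem sizes in the test suite are the package's own choices: unit
tests use a 16 × 16 × 10 phantom; the end-to-end replicate suite runs
twenty full 10+10-subject studies at the default lattice with a
500-iteration cluster calibration each; the Monte-Carlo calibration
check uses the full 1000 iterations plus 1000 fresh validation fields;
the null-calibration check of the trend test uses 200 table-level
replicates.

## Known limitations

- The measured learning slope is attenuated relative to the generative
  slope because spatial smoothing dilutes edge voxels of the delineated
  ROI; tests therefore assert sign and significance, not raw magnitude.
- The split-plot ANOVA requires balanced complete tables; unbalanced
  designs are rejected rather than approximated.
- Smoothness estimation assumes a stationary Gaussian autocorrelation;
  heavy anisotropy is reduced to a geometric mean.
- The empirical minimum cluster size is a step function of α at
  resolution 1/n_iterations; very small α requires more iterations.
- Sham feedback replays recorded traces but the simulated sham subjects'
  brains do not react to the display; frustration or strategy-switching
  dynamics in real control groups are out of scope.
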