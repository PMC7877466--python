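# nfloop

Closed-loop fMRI neurofeedback, end to end, on a synthetic BOLD phantom.

Real-time fMRI neurofeedback (NF) trains a person to upregulate a chosen
brain region: each incoming volume is analyzed online, and a thermometer
display shows the current activity of a target region — here the
supplementary motor area (SMA), driven by motor imagery — relative to a
resting baseline. Whether such training works is decided offline, by
comparing the run-by-run growth of SMA activation in subjects who received
true feedback against yoked sham controls who watched a replay of someone
else's signal. `nfloop` implements that entire experiment as testable
software: a voxel-lattice phantom stands in for the scanner, the online
engine computes the feedback value volume by volume, and the offline
engines reproduce the ROI-learning and whole-brain group analyses.

## The core computations

**Feedback signal.** During each feedback block, the thermometer column
height at volume *t* is the reference-corrected fractional signal change

```
height(t) = (SMA(t) − SMA_base) / SMA_base − (REF(t) − REF_base) / REF_base
```

where SMA(t) and REF(t) are the mean preprocessed signals of the target
ROI and of a reference slab (one axial slice far from the motor network,
which cancels global scanner drifts), and the `_base` values are the means
of the last three volumes of the preceding fixation block.

**Online analysis.** The target ROI comes from a functional localizer run
(7 × 16 s fixation alternating with 6 × 30 s finger tapping) analyzed with
a cumulative GLM: after every volume the per-voxel OLS fit equals a batch
fit on all volumes so far. Voxels with t > 5.0 inside a search rectangle,
restricted to the largest face-connected component, form the SMA mask.

**Offline analysis.** Each 430-s NF run (10 × 16 s fixation alternating
with 9 × 30 s feedback) is preprocessed (first two volumes discarded,
linear trend and drifts ≤ 3 cycles/run removed, 4-mm FWHM smoothing) and
fit voxel-wise with a GLM: HRF-convolved task regressor plus nine nuisance
columns (six motion traces, white-matter and ventricular means,
intercept). The ROI-GLM β per run feeds a group × run mixed ANOVA, paired
first-vs-last-run t tests, per-group linear regressions of mean β on run
number (the learning slope), a slope comparison, and a deviation-contrast
analysis across seven motor ROIs. Whole-brain random-effects t and F maps
are corrected by Monte-Carlo cluster-extent thresholding: null Gaussian
fields at the map's estimated smoothness calibrate the minimum cluster
size whose family-wise false-positive rate is 5%.

**Synthetic subjects.** The generator produces block-locked BOLD responses
(boxcar ⊗ double-gamma HRF) in an SMA blob and six other motor-network
blobs on a 24 × 24 × 12 lattice of 3-mm voxels, with AR(1) noise,
low-frequency drift, motion/WM/ventricle nuisance traces, and a per-run
SMA amplitude that grows linearly over the 7 runs for NF subjects
(0.062 β-units/run on a 0.252 base) and stays flat for sham subjects. A
Go/No-go table generator (250 trials per hand, pre and post) provides the
behavioral outcome.

## Worked example

```python
from nfloop import run_study, StudyConfig

report = run_study(StudyConfig(master_seed=42))
print(report.summary())
```

prints

```
Neurofeedback study report
==============================
subjects: 10+10, runs: 7, TR 2.0 s
SMA group effect: F(1,18) = 590.14, p = 3.278e-15
group x run linear trend: F(1,18) = 333.99, p = 4.541e-13
NF run regression: y = 0.031x + 0.103, F(1,5) = 631.34, r2 = 0.99, p = 1.863e-06
control run regression: y = 0.000x + 0.006, F(1,5) = 0.14, r2 = 0.03, p = 0.7216
slope difference: t(10) = 21.85, p = 9.007e-10
cluster threshold: 7 voxels (189 mm3) at voxel p 0.01, alpha 0.05
clusters [nf_group]: 3
clusters [control_group]: 2
clusters [nf_gt_control]: 1
clusters [interaction]: 1
```

Reading this: the NF group's SMA β grows significantly across the seven
runs (positive fitted slope, F(1,5) test) while the sham group stays flat;
the slopes differ (t with 10 degrees of freedom, from two 7-point fits);
and after cluster correction the two-sample map retains an SMA cluster
where the NF group exceeds the controls. The fitted slope (0.031) is
smaller than the generative slope (0.062) because spatial smoothing
dilutes signal over the delineated ROI's edge voxels — the inference, not
the raw amplitude, is the outcome of interest.

A `nfloop` command-line tool exposes the stages individually
(`simulate`, `localize`, `nf`, `analyze`, `behavior`, `wholebrain`,
`study`, `report`); volumes and masks travel as NIfTI-1, designs,
confounds, traces and result tables as TSV, configuration as YAML.

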