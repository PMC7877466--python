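"""Synthetic 4-D BOLD generation with the structure the analyses assume.

Each run is built as

    volume(t) = baseline + sum_regions amplitude * regressor(t)   (active voxels)
              + low-frequency drift + nuisance signals (WM, ventricle)
              + AR(1) noise,

with six smooth motion traces emitted alongside as confound columns
(motion perturbs the confound table only, not the images, so that the
online motion-correction stage can be an identity pass-through).

Per-run SMA amplitudes follow a linear learning trajectory: positive
slope for neurofeedback subjects, flat for sham subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from nfloop.paradigm import BlockDesign, design_to_regressor
from nfloop.phantom import ACTIVE_REGIONS, PhantomSpec

#: generator truth for the learning trajectories, per group.
#: The neurofeedback line follows the fitted learning effect
#: (slope 0.062 beta-units/run, intercept 0.252); sham subjects are flat
#: at zero, reflecting the absence of upregulation under yoked feedback.
DEFAULT_TRAJECTORY = {
    "NF": {"base_amp": 0.252, "slope": 0.062},
    "control": {"base_amp": 0.0, "slope": 0.0},
}

MOTION_COLUMNS = ("mot_tx", "mot_ty", "mot_tz", "mot_rx", "mot_ry", "mot_rz")
CONFOUND_COLUMNS = MOTION_COLUMNS + ("wm", "vent")


def learning_trajectory(
    group: str,
    n_runs: int,
    base_amp: float | None = None,
    slope: float | None = None,
) -> np.ndarray:
    """Per-run activation amplitudes: base + slope*(run-1), floored at 0."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if group not in DEFAULT_TRAJECTORY:
        raise ValueError(f"unknown group {group!r}")
    if base_amp is None:
        base_amp = DEFAULT_TRAJECTORY[group]["base_amp"]
    if slope is None:
        slope = DEFAULT_TRAJECTORY[group]["slope"]
    amps = base_amp + slope * np.arange(n_runs, dtype=float)
    return np.maximum(amps, 0.0)


@dataclass
class SubjectState:
    """Generator parameters for one simulated subject."""

    group: str  # "NF" or "control"
    subject_id: str
    seed: int
    #: region -> per-run amplitude vector (beta-scale raw signal units)
    run_amplitudes: dict[str, np.ndarray]
    #: region -> amplitude during the localizer tapping blocks
    localizer_amplitudes: dict[str, float]
    ar1_phi: float = 0.3
    sigma: float = 1.0  # stationary noise SD, raw units (1% of baseline)
    baseline: float = 100.0
    drift_slope: float = 1.0  # raw units drifted linearly over a run
    cosine_amps: tuple[float, ...] = (0.5, 0.3)  # 1- and 2-cycle/run components
    motion_scale: float = 0.02  # random-walk innovation SD (mm / degrees)
    wm_amp: float = 0.5
    vent_amp: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        for region, amps in self.run_amplitudes.items():
            if np.any(np.asarray(amps) < 0):
                raise ValueError(f"negative amplitude for region {region}")

    @property
    def n_runs(self) -> int:
        return len(next(iter(self.run_amplitudes.values())))


@dataclass
class RunRecording:
    """One run: 4-D volumes (time first), confound table, and its design."""

    volumes: np.ndarray  # shape (T, nx, ny, nz)
    confounds: pd.DataFrame
    design: BlockDesign
    tr: float
    n_discarded: int = 0  # volumes dropped from the front by preprocessing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.confounds):
            raise ValueError("volumes and confound table lengths differ")
        if len(self.volumes) + self.n_discarded != self.design.n_volumes:
            raise ValueError("time length inconsistent with design volume count")

    @property
    def n_volumes(self) -> int:
        return len(self.volumes)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def to_nifti(self, path: str | Path, voxel_size_mm: float = 3.0) -> None:
        img = nib.Nifti1Image(
            np.moveaxis(self.volumes, 0, -1).astype(np.float32),
            np.diag([voxel_size_mm] * 3 + [1.0]),
        )
        img.header.set_zooms((voxel_size_mm,) * 3 + (self.tr,))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(
        cls, path: str | Path, design: BlockDesign, confounds: pd.DataFrame | None = None
    ) -> "RunRecording":
        img = nib.load(str(path))
        vols = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        if confounds is None:
            confounds = pd.DataFrame(index=range(len(vols)))
        return cls(volumes=vols, confounds=confounds, design=design, tr=design.tr)


def _ar1(rng: np.random.Generator, phi: float, sigma: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) series along axis 0 with marginal SD `sigma`."""
    if sigma == 0:
        return np.zeros(shape)
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(shape)
    eps *= innov_sd
    if phi == 0:
        return eps
    # in-place recursion; cheaper than lfilter on (T, V) at this scale
    for t in range(1, shape[0]):
        eps[t] += phi * eps[t - 1]
    return eps


def _motion_traces(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, scale, size=(n, 6)), axis=0)
    return gaussian_filter1d(walk, sigma=3.0, axis=0)


def simulate_run(
    phantom: PhantomSpec,
    state: SubjectState,
    design: BlockDesign,
    run_index: int,
) -> RunRecording:
    """Simulate one run; reproducible by (state.seed, run_index).

    `run_index` 1..n_runs selects the per-run amplitudes; 0 denotes the
    localizer run and uses `state.localizer_amplitudes`.
    """
    if run_index < 0 or run_index > state.n_runs:
        raise ValueError(f"run_index {run_index} outside [0, {state.n_runs}]")
    rng = np.random.default_rng(np.random.SeedSequence(state.seed, spawn_key=(run_index,)))
    T = design.n_volumes
    dims = phantom.dims
    nvox = phantom.n_voxels

    task_condition = "tapping" if any(b.condition == "tapping" for b in design.blocks) else "feedback"
    reg = design_to_regressor(design, task_condition)

    flat = np.full((T, nvox), state.baseline, dtype=float)
    for region in ACTIVE_REGIONS:
        if run_index == 0:
            amp = float(state.localizer_amplitudes.get(region, 0.0))
        else:
            amps = state.run_amplitudes.get(region)
            amp = float(amps[run_index - 1]) if amps is not None else 0.0
        if amp:
            flat[:, phantom.masks[region].ravel()] += amp * reg[:, None]

    # low-frequency drift: shared waveform, per-voxel random gain
    t_norm = np.arange(T) / max(T - 1, 1)
    drift = state.drift_slope * t_norm
    for k, a in enumerate(state.cosine_amps, start=1):
        drift = drift + a * np.cos(np.pi * k * (np.arange(T) + 0.5) / T)
    if state.drift_slope or any(state.cosine_amps):
        gain = rng.uniform(0.5, 1.5, size=nvox)
        flat += np.outer(drift, gain)

    # slow nuisance signals concentrated in WM / ventricle regions
    for region, amp in (("WM", state.wm_amp), ("VENT", state.vent_amp)):
        if amp:
            sig = gaussian_filter1d(rng.normal(0.0, amp, size=T), sigma=4.0)
            flat[:, phantom.masks[region].ravel()] += sig[:, None]

    flat += _ar1(rng, state.ar1_phi, state.sigma, (T, nvox))

    confounds = pd.DataFrame(
        _motion_traces(rng, T, state.motion_scale), columns=list(MOTION_COLUMNS)
    )
    confounds["wm"] = flat[:, phantom.masks["WM"].ravel()].mean(axis=1)
    confounds["vent"] = flat[:, phantom.masks["VENT"].ravel()].mean(axis=1)

    return RunRecording(
        volumes=flat.reshape(T, *dims),
        confounds=confounds,
        design=design,
        tr=design.tr,
    )
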