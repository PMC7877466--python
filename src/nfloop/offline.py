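"""Offline preprocessing, first-level GLM, ROI betas, event averages.

Preprocessing drops the first two volumes (T1 equilibration), removes
the linear trend and discrete-cosine components at or below three
cycles/run (mean preserved), and smooths with a 4-mm FWHM kernel. The
first-level GLM regresses each voxel on the HRF-convolved task regressor
plus nine nuisance columns (six motion traces, white-matter and
ventricular means, intercept); the task and nuisance regressors pass
through the same temporal filter as the data so the task beta is
unbiased. The ROI-GLM averages the mask time course first and fits the
same design (equal, by linearity, to averaging per-voxel betas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from nfloop.paradigm import BlockDesign, design_to_regressor
from nfloop.realtime import smooth_volume
from nfloop.simulate import CONFOUND_COLUMNS, RunRecording

logger = logging.getLogger(__name__)

DEFAULT_DISCARD = 2
DEFAULT_HP_CYCLES = 3
DEFAULT_FWHM_MM = 4.0


class CollinearityError(ValueError):
    """Design matrix numerically collinear; names the offending columns."""


@lru_cache(maxsize=8)
def _basis_q(n_volumes: int, hp_cycles: int) -> np.ndarray:
    q, _ = np.linalg.qr(highpass_basis(n_volumes, hp_cycles))
    return q


def highpass_basis(n_volumes: int, hp_cycles: int = DEFAULT_HP_CYCLES) -> np.ndarray:
    """Zero-mean drift basis: centered linear trend + DCT terms <= hp_cycles/run.

    DCT-II basis function k completes k/2 cycles over the run, so
    removing components with k <= 2*hp_cycles removes all fluctuations
    at or below hp_cycles cycles per run. All columns are zero-mean, so
    projecting them out preserves the signal mean.
    """
    t = np.arange(n_volumes, dtype=float)
    cols = [t - t.mean()]
    for k in range(1, 2 * hp_cycles + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n_volumes))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def _drift_projection(series: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residualize axis-0 series against the drift basis (mean kept)."""
    q, _ = np.linalg.qr(basis)
    return series - q @ (q.T @ series)


def preprocess_offline(
    recording: RunRecording,
    n_discard: int = DEFAULT_DISCARD,
    hp_cycles: int = DEFAULT_HP_CYCLES,
    fwhm_mm: float = DEFAULT_FWHM_MM,
    voxel_size_mm: float = 3.0,
) -> RunRecording:
    """Discard, detrend/high-pass, and smooth a run."""
    if recording.n_volumes <= n_discard:
        raise ValueError("run too short for discard window")
    vols = recording.volumes[n_discard:].astype(float)
    conf = recording.confounds.iloc[n_discard:].reset_index(drop=True)
    T = len(vols)
    q = _basis_q(T, hp_cycles)
    flat = vols.reshape(T, -1)
    flat -= q @ (q.T @ flat)
    vols = flat.reshape(vols.shape)
    if fwhm_mm > 0:
        vols = np.stack([smooth_volume(v, fwhm_mm, voxel_size_mm) for v in vols])
    meta = dict(recording.meta)
    meta.update({"hp_cycles": hp_cycles, "filtered": True, "fwhm_mm": fwhm_mm})
    return RunRecording(
        volumes=vols,
        confounds=conf,
        design=recording.design,
        tr=recording.tr,
        n_discarded=recording.n_discarded + n_discard,
        meta=meta,
    )


def _task_condition(design: BlockDesign) -> str:
    return "tapping" if any(b.condition == "tapping" for b in design.blocks) else "feedback"


def build_design_matrix(
    recording: RunRecording, condition: str | None = None
) -> pd.DataFrame:
    """Task regressor + confounds + intercept, on the retained volumes.

    The task regressor is computed on the full design (preserving
    convolution history) and truncated by the discarded volumes; task and
    confound columns are passed through the same drift filter applied to
    the data when the recording was preprocessed.
    """
    design = recording.design
    if condition is None:
        condition = _task_condition(design)
    reg = design_to_regressor(design, condition)[recording.n_discarded :]
    cols = {"task": reg}
    for c in CONFOUND_COLUMNS:
        if c in recording.confounds:
            v = recording.confounds[c].to_numpy(dtype=float)
            # constant confounds are degenerate with the intercept
            if np.ptp(v) > 1e-12 * max(1.0, np.abs(v).max()):
                cols[c] = v
    X = pd.DataFrame(cols)
    if recording.meta.get("filtered"):
        q = _basis_q(len(X), recording.meta.get("hp_cycles", DEFAULT_HP_CYCLES))
        Z = X.to_numpy()
        X = pd.DataFrame(Z - q @ (q.T @ Z), columns=X.columns)
    X["intercept"] = 1.0
    return X


def _check_collinearity(X: pd.DataFrame, cond_limit: float = 1e8) -> None:
    Z = X.to_numpy(dtype=float)
    scale = np.linalg.norm(Z, axis=0)
    scale[scale == 0] = 1.0
    cond = np.linalg.cond(Z / scale)
    if cond > cond_limit:
        corr = np.corrcoef((Z / scale).T)
        bad = [
            f"{X.columns[i]}~{X.columns[j]}"
            for i in range(len(X.columns))
            for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(
            f"design condition number {cond:.2e} exceeds {cond_limit:.0e}"
            + (f"; near-duplicate columns: {', '.join(bad)}" if bad else "")
        )


@dataclass
class FirstLevelFit:
    """Per-voxel OLS results for one run."""

    betas: np.ndarray  # (p, nx, ny, nz)
    t_task: np.ndarray  # (nx, ny, nz)
    residuals: np.ndarray | None  # (T, nx, ny, nz); None unless requested
    design_matrix: pd.DataFrame
    dof: int

    @property
    def task_beta_map(self) -> np.ndarray:
        return self.betas[self.design_matrix.columns.get_loc("task")]


def fit_first_level(
    recording: RunRecording,
    condition: str | None = None,
    compute_residuals: bool = True,
) -> FirstLevelFit:
    """Voxel-wise OLS of the run on task + nuisance regressors."""
    X = build_design_matrix(recording, condition)
    _check_collinearity(X)
    Z = X.to_numpy(dtype=float)
    T, p = Z.shape
    Y = recording.volumes.reshape(T, -1)
    xtx = Z.T @ Z
    xty = Z.T @ Y
    beta = np.linalg.solve(xtx, xty)
    dof = T - p
    # residual SS without materializing residuals: y'y - beta' X'y
    rss = np.einsum("tv,tv->v", Y, Y) - np.einsum("pv,pv->v", beta, xty)
    sigma2 = np.maximum(rss, 0.0) / dof
    xtx_inv = np.linalg.inv(xtx)
    ti = X.columns.get_loc("task")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_task = beta[ti] / np.sqrt(sigma2 * xtx_inv[ti, ti])
    dims = recording.dims
    resid = (Y - Z @ beta).reshape(T, *dims) if compute_residuals else None
    return FirstLevelFit(
        betas=beta.reshape(p, *dims),
        t_task=t_task.reshape(dims),
        residuals=resid,
        design_matrix=X,
        dof=dof,
    )


def roi_betas(
    recording: RunRecording,
    masks: dict[str, np.ndarray],
    condition: str | None = None,
) -> dict[str, float]:
    """ROI-GLM task betas for several masks, sharing one design matrix.

    Per ROI the mask time course is averaged first, then fit with the
    same design used voxel-wise (equal, by linearity, to averaging the
    per-voxel betas over the mask).
    """
    X = build_design_matrix(recording, condition)
    _check_collinearity(X)
    Z = X.to_numpy(dtype=float)
    flat = recording.volumes.reshape(len(Z), -1)
    ti = X.columns.get_loc("task")
    out = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"empty ROI mask {name!r}")
        y = flat[:, mask.ravel()].mean(axis=1)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        out[name] = float(beta[ti])
    return out


def roi_beta(recording: RunRecording, mask: np.ndarray, condition: str | None = None) -> float:
    """ROI-GLM task beta: average the mask time course, then fit."""
    return roi_betas(recording, {"roi": mask}, condition)["roi"]


@dataclass
class EventAverage:
    """Block-onset-locked mean percent-signal-change time course."""

    time_s: np.ndarray  # relative to block onset
    mean_psc: np.ndarray
    sem_psc: np.ndarray | None  # None with a single block
    n_blocks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "mean_psc": self.mean_psc,
                "sem_psc": np.full_like(self.mean_psc, np.nan)
                if self.sem_psc is None
                else self.sem_psc,
            }
        )


def event_related_average(
    recording: RunRecording,
    mask: np.ndarray,
    window_s: tuple[float, float] = (-6.0, 36.0),
    condition: str | None = None,
    n_baseline: int = 3,
) -> EventAverage:
    """Average PSC across task blocks, baselined to 3 pre-onset volumes.

    Per block, PSC(t) = 100*(x(t) - b)/b with b the mean of the
    `n_baseline` volumes immediately preceding onset. Blocks whose window
    falls outside the run are skipped with a log entry.
    """
    design = recording.design
    if condition is None:
        condition = _task_condition(design)
    tr = recording.tr
    roi = recording.volumes.reshape(recording.n_volumes, -1)[:, mask.ravel()].mean(axis=1)
    off0 = int(round(window_s[0] / tr))
    off1 = int(round(window_s[1] / tr))
    offsets = np.arange(off0, off1 + 1)
    segments = []
    for b in design.blocks:
        if b.condition != condition:
            continue
        onset_i = int(round(b.onset / tr)) - recording.n_discarded
        lo, hi = onset_i + off0, onset_i + off1
        if lo - (n_baseline - off0 if off0 > -n_baseline else 0) < 0 or hi >= len(roi):
            logger.info("skipping block at %.0f s: window outside run", b.onset)
            continue
        if onset_i - n_baseline < 0:
            logger.info("skipping block at %.0f s: no baseline volumes", b.onset)
            continue
        base = roi[onset_i - n_baseline : onset_i].mean()
        segments.append(100.0 * (roi[onset_i + offsets] - base) / base)
    if not segments:
        raise ValueError("no task block fully inside the run")
    seg = np.stack(segments)
    sem = seg.std(axis=0, ddof=1) / np.sqrt(len(seg)) if len(seg) > 1 else None
    return EventAverage(
        time_s=offsets * tr,
        mean_psc=seg.mean(axis=0),
        sem_psc=sem,
        n_blocks=len(seg),
    )
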