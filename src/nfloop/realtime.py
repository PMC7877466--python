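"""The closed online loop.

Streaming stages mirror a real-time fMRI pipeline: incremental linear
detrending and 8-mm Gaussian smoothing per incoming volume (slice-timing
and motion correction are pluggable stages, identity by default on
phantom data), a cumulative GLM whose estimates after k volumes equal a
batch OLS fit on those k volumes, t-threshold ROI delineation inside a
search box, and the thermometer feedback value

    height(t) = (SMA(t) - SMA_base)/SMA_base - (REF(t) - REF_base)/REF_base

where the bases are the mean of the last three volumes of the fixation
block preceding each feedback block. Sham subjects receive a replay of a
recorded trace while their own ROI signals are still logged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from nfloop.paradigm import BlockDesign
from nfloop.simulate import RunRecording

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: FeedbackTrace schema: one row per volume
TRACE_COLUMNS = ("volume", "block", "height", "sma_mean", "ref_mean", "sma_base", "ref_base")


class LocalizerError(RuntimeError):
    """No voxel survived the localizer threshold inside the search box."""


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Normalized Gaussian smoothing; preserves the image mean."""
    if fwhm_mm <= 0:
        return volume
    sigma = fwhm_mm / (FWHM_TO_SIGMA * voxel_size_mm)
    return ndimage.gaussian_filter(volume, sigma, mode="reflect")


class OnlinePreprocessor:
    """Per-volume incremental preprocessing: detrend then smooth.

    The detrend stage keeps a running per-voxel regression of intensity
    on volume index and subtracts the fitted trend referenced to time 0,
    so a drifting voxel is flattened to its initial level while the
    signal keeps its raw (positive) baseline. Slice-timing and motion
    stages default to identity but accept pluggable callables for real
    data.
    """

    def __init__(
        self,
        fwhm_mm: float = 8.0,
        voxel_size_mm: float = 3.0,
        detrend: bool = True,
        slice_timing: Callable[[np.ndarray], np.ndarray] | None = None,
        motion_correct: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> None:
        self.fwhm_mm = fwhm_mm
        self.voxel_size_mm = voxel_size_mm
        self.detrend = detrend
        self.slice_timing = slice_timing
        self.motion_correct = motion_correct
        self._n = 0
        self._shape: tuple[int, ...] | None = None
        self._sx = None  # sum x
        self._stx = None  # sum t*x

    def process(self, volume: np.ndarray) -> np.ndarray:
        if self._shape is None:
            self._shape = volume.shape
            self._sx = np.zeros(volume.size)
            self._stx = np.zeros(volume.size)
        elif volume.shape != self._shape:
            raise ValueError(f"volume shape {volume.shape} != expected {self._shape}")
        if self.slice_timing is not None:
            volume = self.slice_timing(volume)
        if self.motion_correct is not None:
            volume = self.motion_correct(volume)
        flat = volume.reshape(-1).astype(float)
        t = self._n
        self._sx += flat
        self._stx += t * flat
        self._n += 1
        out = flat
        if self.detrend and self._n >= 2:
            n = self._n
            st = n * (n - 1) / 2.0
            stt = (n - 1) * n * (2 * n - 1) / 6.0
            denom = stt - st * st / n
            slope = (self._stx - st * self._sx / n) / denom
            out = flat - slope * t
        return smooth_volume(out.reshape(self._shape), self.fwhm_mm, self.voxel_size_mm)


class OnlineGlm:
    """Cumulative GLM: refit-equivalent OLS updated volume by volume.

    Normal equations are accumulated (X'X, X'y, y'y) and solved on
    demand; after k volumes the per-voxel beta, residual variance, and t
    statistics equal a batch OLS fit on the first k volumes.
    """

    def __init__(self, n_predictors: int) -> None:
        self.p = int(n_predictors)
        self.n_volumes_seen = 0
        self._xtx = np.zeros((self.p, self.p))
        self._xty: np.ndarray | None = None
        self._yty: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def update(self, volume: np.ndarray, design_row: np.ndarray) -> "OnlineGlm":
        row = np.asarray(design_row, dtype=float)
        if row.shape != (self.p,):
            raise ValueError(f"design row has {row.size} entries, expected {self.p}")
        flat = volume.reshape(-1).astype(float)
        if self._xty is None:
            self._shape = volume.shape
            self._xty = np.zeros((self.p, flat.size))
            self._yty = np.zeros(flat.size)
        elif volume.shape != self._shape:
            raise ValueError("volume shape changed mid-stream")
        self._xtx += np.outer(row, row)
        self._xty += np.outer(row, flat)
        self._yty += flat * flat
        self.n_volumes_seen += 1
        return self

    @property
    def rank_deficient(self) -> bool:
        return np.linalg.matrix_rank(self._xtx) < self.p if self.n_volumes_seen else True

    def betas(self) -> np.ndarray:
        """Per-voxel OLS coefficients, shape (p, *volume_shape)."""
        if self._xty is None:
            raise RuntimeError("no volumes seen")
        if self.rank_deficient:
            beta = np.linalg.pinv(self._xtx) @ self._xty
        else:
            beta = np.linalg.solve(self._xtx, self._xty)
        return beta.reshape(self.p, *self._shape)

    def residual_variance(self) -> np.ndarray:
        dof = self.n_volumes_seen - self.p
        if dof < 1:
            raise RuntimeError("not enough volumes for residual variance")
        beta = self.betas().reshape(self.p, -1)
        rss = self._yty - np.sum(beta * self._xty, axis=0)
        return np.maximum(rss, 0.0).reshape(self._shape) / dof

    def t_map(self, contrast: np.ndarray | int) -> np.ndarray | None:
        """Per-voxel t statistic for a contrast (or predictor index).

        Returns None (flagged, not an error) while the accumulated design
        is rank deficient or has fewer than p+2 volumes.
        """
        if self.n_volumes_seen < self.p + 2 or self.rank_deficient:
            return None
        c = np.zeros(self.p)
        if np.isscalar(contrast):
            c[int(contrast)] = 1.0
        else:
            c = np.asarray(contrast, dtype=float)
        beta = self.betas().reshape(self.p, -1)
        var = self.residual_variance().reshape(-1)
        cvc = c @ np.linalg.solve(self._xtx, c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ beta) / np.sqrt(var * cvc)
        return t.reshape(self._shape)


@dataclass(frozen=True)
class RoiSet:
    """Target and reference masks driving the feedback computation."""

    sma_mask: np.ndarray
    reference_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.sma_mask.shape != self.reference_mask.shape:
            raise ValueError("mask shapes differ")
        if (self.sma_mask & self.reference_mask).any():
            raise ValueError("SMA and reference masks overlap")
        if not self.sma_mask.any() or not self.reference_mask.any():
            raise ValueError("both masks must be non-empty")

    @property
    def n_sma(self) -> int:
        return int(self.sma_mask.sum())

    @property
    def n_reference(self) -> int:
        return int(self.reference_mask.sum())


def delineate_sma(
    t_map: np.ndarray,
    bbox: tuple[slice, slice, slice],
    threshold: float = 5.0,
) -> np.ndarray:
    """Active voxels (t > threshold) inside the search box.

    Restricted to the largest 6-face-connected component. Raises
    LocalizerError (with the maximum in-box t) when nothing survives.
    """
    inbox = np.zeros(t_map.shape, bool)
    inbox[bbox] = True
    mask = inbox & (t_map > threshold)
    if not mask.any():
        raise LocalizerError(
            f"no voxel exceeded t > {threshold} in the search box "
            f"(max t = {np.nanmax(t_map[inbox]):.3f})"
        )
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


@dataclass(frozen=True)
class BaselineState:
    """Eq.-1 bases from the last three fixation volumes of a block."""

    roi_sma_base: float
    roi_ref_base: float
    source_volumes: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.roi_sma_base <= 0 or self.roi_ref_base <= 0:
            raise ValueError("baseline signals must be positive")


def update_baseline(
    fixation_volumes: list[np.ndarray],
    rois: RoiSet,
    volume_indices: list[int] | None = None,
) -> BaselineState:
    """Bases = ROI means of the average of the last three fixation volumes."""
    if len(fixation_volumes) < 3:
        raise ValueError("need at least 3 fixation volumes for a baseline")
    last3 = np.mean(np.stack(fixation_volumes[-3:]), axis=0)
    if volume_indices is None:
        volume_indices = list(range(len(fixation_volumes)))
    return BaselineState(
        roi_sma_base=float(last3[rois.sma_mask].mean()),
        roi_ref_base=float(last3[rois.reference_mask].mean()),
        source_volumes=tuple(volume_indices[-3:]),
    )


def compute_feedback(roi_sma_mean: float, roi_ref_mean: float, baseline: BaselineState) -> float:
    """Thermometer column height: reference-corrected fractional change."""
    return (roi_sma_mean - baseline.roi_sma_base) / baseline.roi_sma_base - (
        roi_ref_mean - baseline.roi_ref_base
    ) / baseline.roi_ref_base


def run_nf_loop(
    recording: RunRecording,
    rois: RoiSet,
    mode: str = "true_feedback",
    sham_source: pd.DataFrame | None = None,
    preprocessor: OnlinePreprocessor | None = None,
    quantize_steps: int | None = None,
) -> pd.DataFrame:
    """Stream a run through the online loop; returns the feedback trace.

    The trace has one row per volume (columns TRACE_COLUMNS); `height` is
    NaN outside feedback blocks. In sham mode heights are replayed from
    `sham_source` while the subject's own ROI means are still logged, so
    the offline beta analysis works identically for both groups.
    """
    if mode not in ("true_feedback", "sham"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "sham" and sham_source is None:
        raise ValueError("sham mode requires sham_source")
    design = recording.design
    labels = design.volume_labels()
    if recording.n_volumes < design.n_volumes:
        raise ValueError("stream shorter than design")
    if preprocessor is None:
        preprocessor = OnlinePreprocessor()

    rows = []
    fix_buffer: deque[tuple[int, np.ndarray]] = deque(maxlen=3)
    baseline: BaselineState | None = None
    prev_label = None
    for i in range(design.n_volumes):
        vol = preprocessor.process(recording.volumes[i])
        label = labels[i]
        sma_mean = float(vol[rois.sma_mask].mean())
        ref_mean = float(vol[rois.reference_mask].mean())
        if label == "fixation":
            if prev_label is not None and prev_label != "fixation":
                fix_buffer.clear()
            fix_buffer.append((i, vol))
            height = np.nan
        else:
            if prev_label == "fixation":
                if len(fix_buffer) < 3:
                    raise ValueError("fewer than 3 fixation volumes before feedback block")
                idx = [j for j, _ in fix_buffer]
                baseline = update_baseline([v for _, v in fix_buffer], rois, idx)
            if baseline is None:
                raise ValueError("feedback block before any fixation baseline")
            if mode == "sham":
                height = float(sham_source["height"].iloc[i])
            else:
                height = compute_feedback(sma_mean, ref_mean, baseline)
                if quantize_steps:
                    height = round(height * quantize_steps) / quantize_steps
        rows.append(
            {
                "volume": i,
                "block": label,
                "height": height,
                "sma_mean": sma_mean,
                "ref_mean": ref_mean,
                "sma_base": baseline.roi_sma_base if baseline else np.nan,
                "ref_base": baseline.roi_ref_base if baseline else np.nan,
            }
        )
        prev_label = label
    return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))


def assign_yoked_sources(
    pool_ids: list[str],
    control_ids: list[str],
    seed: int,
) -> dict[str, str]:
    """Map each sham subject to a recorded trace set, uniformly with replacement."""
    if not pool_ids:
        raise ValueError("empty pool of recorded traces")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(pool_ids), size=len(control_ids))
    return {cid: pool_ids[k] for cid, k in zip(control_ids, picks)}
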