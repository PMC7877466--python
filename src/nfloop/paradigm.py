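"""Block-design construction and conversion to GLM regressors.

The experiment uses two block paradigms, both sampled at TR = 2 s:

* the functional localizer: seven 16-s fixation blocks interleaved with
  six 30-s bimanual finger-tapping blocks (292 s, 146 volumes), used to
  delineate the SMA target ROI from an online t-map;
* the neurofeedback run: ten 16-s fixation blocks alternating with nine
  30-s feedback (motor-imagery) blocks (430 s, 215 volumes).

Designs serialize to a three-column TSV (onset, duration, condition) and
convert to per-volume regressors by convolving a unit boxcar with the
canonical double-gamma HRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf

CONDITIONS = ("fixation", "tapping", "feedback")

FIXATION_S = 16.0
TASK_BLOCK_S = 30.0
N_NF_FEEDBACK_BLOCKS = 9
N_LOCALIZER_TAP_BLOCKS = 6


@dataclass(frozen=True)
class Block:
    """One contiguous block of a single condition."""

    condition: str
    onset: float  # seconds from run start
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.onset < 0:
            raise ValueError("block onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("block duration must be > 0")


@dataclass(frozen=True)
class BlockDesign:
    """An ordered, contiguous, non-overlapping sequence of blocks."""

    blocks: tuple[Block, ...]
    tr: float

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        t = 0.0
        for b in self.blocks:
            if abs(b.onset - t) > 1e-9:
                raise ValueError(
                    f"blocks must be contiguous: expected onset {t}, got {b.onset}"
                )
            t += b.duration
        n = self.total_duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"total duration {self.total_duration} s not divisible by tr {self.tr} s"
            )

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))

    def condition_boxcar(self, condition: str) -> np.ndarray:
        """Unit-height indicator of `condition`, one sample per volume.

        Volume i covers the half-open interval [i*TR, (i+1)*TR); a volume
        is assigned to the block containing its start time.
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        box = np.zeros(self.n_volumes)
        times = np.arange(self.n_volumes) * self.tr
        for b in self.blocks:
            if b.condition == condition:
                box[(times >= b.onset - 1e-9) & (times < b.onset + b.duration - 1e-9)] = 1.0
        return box

    def volume_labels(self) -> list[str]:
        """Condition label of each volume (by its start time)."""
        labels = []
        times = np.arange(self.n_volumes) * self.tr
        for t in times:
            for b in self.blocks:
                if b.onset - 1e-9 <= t < b.onset + b.duration - 1e-9:
                    labels.append(b.condition)
                    break
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [b.onset for b in self.blocks],
                "duration": [b.duration for b in self.blocks],
                "condition": [b.condition for b in self.blocks],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float) -> "BlockDesign":
        df = pd.read_csv(path, sep="\t")
        blocks = tuple(
            Block(condition=str(r.condition), onset=float(r.onset), duration=float(r.duration))
            for r in df.itertuples()
        )
        return cls(blocks=blocks, tr=tr)


def _alternating_design(
    tr: float, n_rest: int, rest_s: float, task_condition: str, n_task: int, task_s: float
) -> BlockDesign:
    blocks = []
    t = 0.0
    for i in range(n_rest + n_task):
        if i % 2 == 0:
            blocks.append(Block("fixation", t, rest_s))
            t += rest_s
        else:
            blocks.append(Block(task_condition, t, task_s))
            t += task_s
    return BlockDesign(blocks=tuple(blocks), tr=tr)


def make_nf_design(tr: float = 2.0) -> BlockDesign:
    """Neurofeedback run: 10 fixation (16 s) alternating with 9 feedback (30 s).

    Starts and ends with fixation; total 430 s.
    """
    return _alternating_design(tr, 10, FIXATION_S, "feedback", N_NF_FEEDBACK_BLOCKS, TASK_BLOCK_S)


def make_localizer_design(tr: float = 2.0) -> BlockDesign:
    """Localizer run: 7 fixation (16 s) interleaved with 6 tapping (30 s).

    Starts and ends with fixation; total 292 s.
    """
    return _alternating_design(tr, 7, FIXATION_S, "tapping", N_LOCALIZER_TAP_BLOCKS, TASK_BLOCK_S)


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR.

    SPM parameterization (response peak 6 s, undershoot peak 16 s,
    response/undershoot ratio 6), normalized to unit sum so that the
    sustained response to a long unit boxcar plateaus at 1; a generator
    amplitude `a` therefore equals the plateau signal change in raw units.
    """
    h = spm_hrf(tr, oversampling=1, time_length=duration_s)
    return h / h.sum()


def design_to_regressor(
    design: BlockDesign, condition: str, hrf: np.ndarray | None = None
) -> np.ndarray:
    """HRF-convolved unit boxcar for `condition`, truncated to run length."""
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    box = design.condition_boxcar(condition)
    return np.convolve(box, hrf)[: design.n_volumes]
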