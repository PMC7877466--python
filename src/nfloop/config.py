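"""Study configuration: one structured-text file specifies a full study."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class StudyConfig:
    """Defaults reproduce the study design shape: 10+10 subjects, 7 runs, TR 2 s."""

    n_per_group: int = 10
    n_runs: int = 7
    tr: float = 2.0
    # phantom
    dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 3.0
    # generator effect sizes (raw signal units on a baseline of `baseline`)
    nf_base_amp: float = 0.252
    nf_slope: float = 0.062
    control_base_amp: float = 0.0
    control_slope: float = 0.0
    nonspecific_amp: float = 0.3  # flat motor-network activation, both groups
    localizer_amp: float = 1.0  # tapping response in all motor blobs
    baseline: float = 100.0
    sigma: float = 1.0
    ar1_phi: float = 0.3
    drift_slope: float = 1.0
    amp_between_sd: float = 0.05  # between-subject jitter of base amplitude
    # behavior (go RT means, ms)
    rt_pre_ms: float = 380.0
    rt_post_shift_nf_right_ms: float = -30.0
    rt_post_shift_other_ms: float = 0.0
    # online analysis
    localizer_threshold: float = 5.0
    online_fwhm_mm: float = 8.0
    n_yoked_sources: int = 7
    # offline / group analysis
    offline_fwhm_mm: float = 4.0
    hp_cycles: int = 3
    alpha: float = 0.05
    voxel_p: float = 0.01
    mc_iterations: int = 1000
    connectivity: int = 18
    two_sided: bool = True
    master_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dims" in raw:
            raw["dims"] = tuple(raw["dims"])
        return cls(**raw)


def validate_config(config: StudyConfig) -> list[Issue]:
    """Typed error/warning issues; an empty list means the config is usable."""
    issues: list[Issue] = []
    err = lambda m: issues.append(Issue("error", m))
    warn = lambda m: issues.append(Issue("warning", m))
    if config.n_runs < 1:
        err("n_runs must be >= 1")
    if config.n_per_group < 2:
        err("n_per_group must be >= 2 for group statistics")
    if config.tr <= 0:
        err("tr must be positive")
    if any(d < 8 for d in config.dims):
        err("each phantom dimension must be >= 8")
    if not 0 <= config.ar1_phi < 1:
        err("ar1_phi must be in [0, 1)")
    if config.sigma < 0:
        err("sigma must be >= 0")
    if not 0 < config.voxel_p < 1:
        err("voxel_p must be in (0, 1)")
    if not 0 < config.alpha < 1:
        err("alpha must be in (0, 1)")
    elif config.alpha > 0.1:
        warn(f"alpha = {config.alpha} is unusually permissive")
    if config.mc_iterations < 100:
        err("mc_iterations must be >= 100")
    if config.connectivity not in (6, 18, 26):
        err("connectivity must be 6, 18 or 26")
    if config.localizer_threshold <= 0:
        warn("non-positive localizer threshold admits noise voxels")
    if config.baseline <= 0:
        err("baseline must be positive (feedback divides by it)")
    return issues
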