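"""Group-level voxel-wise maps and Monte-Carlo cluster-extent correction.

Random-effects maps (one- and two-sample t, and the voxel-wise group x
run mixed-ANOVA interaction F) are thresholded at an uncorrected voxel
p, then corrected for multiple comparisons by cluster extent: null
Gaussian fields matched to the map's estimated spatial smoothness are
simulated, the maximal suprathreshold cluster size is recorded per
iteration, and the smallest extent whose family-wise false-positive
rate is at or below alpha becomes the minimum cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """A 3-D statistic lattice with its sampling distribution."""

    values: np.ndarray
    kind: str  # "t" or "F"
    df: tuple[int, ...]  # (df,) for t, (df1, df2) for F
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("t", "F"):
            raise ValueError("kind must be 't' or 'F'")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def stat_cutoff(self, voxel_p: float) -> float:
        """One-sided statistic threshold matching an uncorrected voxel p."""
        if self.kind == "t":
            return float(sps.t.isf(voxel_p, self.df[0]))
        return float(sps.f.isf(voxel_p, self.df[0], self.df[1]))


def rfx_one_sample(beta_maps: np.ndarray, voxel_size_mm: float = 3.0) -> StatMap:
    """Voxel-wise one-sample t across subject beta maps; df = n - 1.

    Voxels with zero between-subject variance are masked (NaN).
    """
    maps = np.asarray(beta_maps, float)
    n = len(maps)
    if n < 2:
        raise ValueError("need at least 2 subject maps")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(values=t, kind="t", df=(n - 1,), voxel_size_mm=voxel_size_mm)


def rfx_two_sample(
    maps_a: np.ndarray, maps_b: np.ndarray, voxel_size_mm: float = 3.0
) -> StatMap:
    """Voxel-wise pooled-variance two-sample t; df = n_a + n_b - 2."""
    a, b = np.asarray(maps_a, float), np.asarray(maps_b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 maps per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            sp2 > 0,
            (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)),
            np.nan,
        )
    return StatMap(values=t, kind="t", df=(na + nb - 2,), voxel_size_mm=voxel_size_mm)


def voxelwise_interaction(
    data: np.ndarray, groups: np.ndarray, voxel_size_mm: float = 3.0
) -> StatMap:
    """Per-voxel group x run mixed-ANOVA interaction F.

    `data` has shape (n_subjects, n_runs, nx, ny, nz); `groups` labels
    each subject. Balanced groups required. df = ((r-1), (r-1)(N-g)) --
    (6, 108) for 7 runs and 20 subjects in 2 groups.
    """
    groups = np.asarray(groups)
    gnames = np.unique(groups)
    counts = [int((groups == g).sum()) for g in gnames]
    if len(set(counts)) != 1:
        raise ValueError("groups must be balanced")
    n_sub, n_run = data.shape[:2]
    dims = data.shape[2:]
    flat = data.reshape(n_sub, n_run, -1)
    grand = flat.mean(axis=(0, 1))
    run_m = flat.mean(axis=0)
    sub_m = flat.mean(axis=1)
    cell = np.stack([flat[groups == g].mean(axis=0) for g in gnames])  # (g, r, V)
    grp_m = cell.mean(axis=1)  # (g, V)
    n_per = counts[0]
    ss_run = n_sub * ((run_m - grand) ** 2).sum(axis=0)
    ss_gr = n_per * ((cell - grp_m[:, None, :] - run_m[None] + grand) ** 2).sum(axis=(0, 1))
    grp_of_sub = np.stack([grp_m[list(gnames).index(g)] for g in groups])
    ss_subw = n_run * ((sub_m - grp_of_sub) ** 2).sum(axis=0)
    ss_grp = n_per * n_run * ((grp_m - grand) ** 2).sum(axis=0)
    ss_tot = ((flat - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_tot - ss_grp - ss_subw - ss_run - ss_gr
    df1 = n_run - 1
    df2 = (n_run - 1) * (n_sub - len(gnames))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ss_err > 0, (ss_gr / df1) / (ss_err / df2), np.nan)
    return StatMap(values=F.reshape(dims), kind="F", df=(df1, df2), voxel_size_mm=voxel_size_mm)


def estimate_smoothness(residuals: np.ndarray, voxel_size_mm: float = 3.0) -> float:
    """Equivalent Gaussian-kernel FWHM (mm) of residual spatial noise.

    Per volume and axis, the lag-1 spatial autocorrelation of the
    standardized residuals gives the std of the Gaussian kernel that,
    applied to white noise, would reproduce it. Axes are combined by
    geometric mean; the estimate is floored at one voxel (smoothness
    below the sampling grid is unresolvable).
    """
    res = np.asarray(residuals, float)
    if res.ndim == 3:
        res = res[None]
    if np.allclose(res.std(axis=(1, 2, 3)), 0):
        raise ValueError("flat residuals: smoothness undefined")
    fwhm_axes = []
    for axis in range(3):
        rhos = []
        for vol in res:
            v = vol - vol.mean()
            sd = v.std()
            if sd == 0:
                continue
            z = v / sd
            d = np.diff(z, axis=axis)
            rhos.append(1.0 - (d**2).mean() / 2.0)
        rho = float(np.mean(rhos))
        if rho <= 0:
            fwhm_axes.append(1.0)
            continue
        sigma = np.sqrt(-1.0 / (4.0 * np.log(rho)))
        fwhm_axes.append(max(1.0, FWHM_TO_SIGMA * sigma))
    return float(np.exp(np.mean(np.log(fwhm_axes))) * voxel_size_mm)


def _null_field(
    rng: np.random.Generator, dims: tuple[int, int, int], sigma_vox: float
) -> np.ndarray:
    """Standardized smooth Gaussian null field (periodic boundary)."""
    f = rng.standard_normal(dims)
    if sigma_vox > 0:
        f = ndimage.gaussian_filter(f, sigma_vox, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / sd


def max_cluster_size(mask: np.ndarray, connectivity: int = 18) -> int:
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


@dataclass
class McThreshold:
    """Minimum cluster extent calibrated by null-field simulation."""

    voxel_p: float
    alpha: float
    n_iterations: int
    fwhm_mm: float
    min_cluster_voxels: int
    min_cluster_mm3: float
    seed: int
    connectivity: int = 18
    max_sizes: np.ndarray | None = field(default=None, repr=False)


def monte_carlo_min_cluster(
    dims: tuple[int, int, int],
    fwhm_mm: float,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 18,
    seed: int = 0,
    voxel_size_mm: float = 3.0,
) -> McThreshold:
    """Simulate null fields to calibrate the minimum cluster size.

    Each iteration draws a Gaussian field smoothed to `fwhm_mm`,
    thresholds it one-sided at `voxel_p`, and records the maximal
    cluster size. The returned extent is the smallest k whose empirical
    P(max cluster >= k) <= alpha; clusters of exactly this size survive.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not 0 < alpha < 1 and alpha != 1.0:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma_vox = (fwhm_mm / voxel_size_mm) / FWHM_TO_SIGMA if fwhm_mm > voxel_size_mm else 0.0
    zthr = sps.norm.isf(voxel_p)
    maxima = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        f = _null_field(rng, tuple(dims), sigma_vox)
        maxima[i] = max_cluster_size(f > zthr, connectivity)
    sorted_max = np.sort(maxima)
    k = 1
    while (sorted_max >= k).mean() > alpha:
        k += 1
        if k > np.prod(dims):
            raise ValueError("requested alpha unattainable on this lattice")
    return McThreshold(
        voxel_p=voxel_p,
        alpha=alpha,
        n_iterations=n_iter,
        fwhm_mm=fwhm_mm,
        min_cluster_voxels=k,
        min_cluster_mm3=k * voxel_size_mm**3,
        seed=seed,
        connectivity=connectivity,
        max_sizes=maxima,
    )


def apply_cluster_threshold(
    stat_map: StatMap,
    voxel_p: float,
    mc: McThreshold,
    connectivity: int | None = None,
) -> tuple[StatMap, pd.DataFrame]:
    """Voxel-threshold a map and drop clusters below the calibrated extent.

    Returns the thresholded map (sub-threshold voxels zeroed) and a
    cluster table (label, peak statistic, peak voxel, size) sorted by
    size, largest first. Cluster extents equal to the minimum survive.
    """
    if connectivity is None:
        connectivity = mc.connectivity
    cutoff = stat_map.stat_cutoff(voxel_p)
    vals = np.nan_to_num(stat_map.values, nan=0.0)
    supra = vals > cutoff
    labels, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    out = np.zeros_like(vals)
    rows = []
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < mc.min_cluster_voxels:
            continue
        out[comp] = vals[comp]
        flat_idx = np.flatnonzero(comp & (vals == vals[comp].max()))[0]
        i, j, k = np.unravel_index(flat_idx, vals.shape)
        rows.append(
            {
                "label": len(rows) + 1,
                "peak_stat": float(vals[comp].max()),
                "i": int(i),
                "j": int(j),
                "k": int(k),
                "n_voxels": size,
                "mm3": size * stat_map.voxel_volume_mm3,
            }
        )
    table = pd.DataFrame(rows, columns=["label", "peak_stat", "i", "j", "k", "n_voxels", "mm3"])
    if len(table):
        table = table.sort_values("n_voxels", ascending=False, ignore_index=True)
        table["label"] = np.arange(1, len(table) + 1)
    thresholded = StatMap(
        values=out, kind=stat_map.kind, df=stat_map.df, voxel_size_mm=stat_map.voxel_size_mm
    )
    return thresholded, table
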