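"""Voxel-lattice phantom geometry for the synthetic neurofeedback study.

The phantom is a small 3-D lattice (default 24 x 24 x 12 voxels of 3 mm)
carrying labeled region masks: an ellipsoidal SMA blob inside a known
bounding box (the online ROI search rectangle), six further motor-network
blobs (bilateral M1, PMC, PPC), a white-matter block and a ventricle
block used as nuisance-signal sources, and a reference slab -- one full
axial slice away from the motor network -- used by the online engine to
correct the feedback signal for global scanner effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

REGIONS = ("SMA", "REF_SLAB", "M1_L", "M1_R", "PMC_L", "PMC_R", "PPC_L", "PPC_R", "WM", "VENT")
#: blobs that can carry task-locked signal
ACTIVE_REGIONS = ("SMA", "M1_L", "M1_R", "PMC_L", "PMC_R", "PPC_L", "PPC_R")
#: the seven ROIs entering the beta-table analyses
ANALYSIS_ROIS = ACTIVE_REGIONS


@dataclass(frozen=True)
class PhantomSpec:
    """Lattice geometry plus named boolean region masks."""

    dims: tuple[int, int, int]
    voxel_size_mm: float
    masks: dict[str, np.ndarray]
    sma_bbox: tuple[slice, slice, slice]

    def __post_init__(self) -> None:
        for name in REGIONS:
            if name not in self.masks:
                raise ValueError(f"missing region mask {name!r}")
            m = self.masks[name]
            if m.shape != self.dims:
                raise ValueError(f"mask {name!r} shape {m.shape} != dims {self.dims}")
            if not m.any():
                raise ValueError(f"region mask {name!r} is empty")
        if (self.masks["SMA"] & self.masks["REF_SLAB"]).any():
            raise ValueError("SMA overlaps the reference slab")
        bbox = np.zeros(self.dims, bool)
        bbox[self.sma_bbox] = True
        if (self.masks["SMA"] & ~bbox).any():
            raise ValueError("SMA extends outside sma_bbox")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def label_map(self) -> np.ndarray:
        """Integer label volume (1-based in REGIONS order; 0 = background).

        Regions are painted in order, so a voxel in several regions keeps
        the last label; the boolean masks remain authoritative.
        """
        lab = np.zeros(self.dims, dtype=np.int16)
        for i, name in enumerate(REGIONS, start=1):
            lab[self.masks[name]] = i
        return lab

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.label_map(), self.affine), str(path))


def _ellipsoid(dims: tuple[int, int, int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    ii = np.indices(dims, dtype=float)
    d2 = sum(((ii[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def build_phantom(
    dims: tuple[int, int, int] = (24, 24, 12),
    voxel_size_mm: float = 3.0,
    seed: int = 0,
    jitter: int = 0,
) -> PhantomSpec:
    """Construct a deterministic-by-seed phantom.

    With `jitter` > 0, blob centers are displaced by up to that many
    voxels (seeded), emulating anatomical variability; the construction
    raises if a displaced geometry violates region separation (in
    particular, if a non-target blob enters the SMA search box).
    """
    dims = tuple(int(d) for d in dims)
    if any(d < 8 for d in dims):
        raise ValueError("each lattice dimension must be >= 8")
    nx, ny, nz = dims
    rng = np.random.default_rng(seed)

    def jit() -> np.ndarray:
        return rng.integers(-jitter, jitter + 1, size=3) if jitter else np.zeros(3, int)

    # fractional layout scaled to the lattice; z partitioned so the
    # reference slab (low z) never touches the motor blobs (high z);
    # lateral blobs pushed outward so the midline SMA search box stays
    # clear of them
    ref_z = max(1, nz // 6)
    sma_center = np.array([nx / 2, ny / 2, 3 * nz / 4]) + jit()
    sma_radii = np.array([max(2.0, nx / 9), max(2.0, ny / 9), max(1.5, nz / 7)])
    blob_r = max(1.5, nx / 14)
    lat = nx / 5.5
    blob_centers = {
        "M1_L": np.array([lat, ny * 0.42, 3 * nz / 4]),
        "M1_R": np.array([nx - lat, ny * 0.42, 3 * nz / 4]),
        "PMC_L": np.array([lat, ny * 0.62, 3 * nz / 4]),
        "PMC_R": np.array([nx - lat, ny * 0.62, 3 * nz / 4]),
        "PPC_L": np.array([lat, ny * 0.2, 0.6 * nz]),
        "PPC_R": np.array([nx - lat, ny * 0.2, 0.6 * nz]),
    }

    masks: dict[str, np.ndarray] = {}
    masks["SMA"] = _ellipsoid(dims, sma_center, sma_radii)
    for name, c in blob_centers.items():
        masks[name] = _ellipsoid(dims, c + jit(), np.array([blob_r, blob_r, blob_r]))

    ref = np.zeros(dims, bool)
    ref[:, :, ref_z] = True
    masks["REF_SLAB"] = ref

    wm = np.zeros(dims, bool)
    wm[nx // 2 - 2 : nx // 2 + 2, ny // 2 - 2 : ny // 2 + 2, ref_z + 1 : ref_z + 3] = True
    masks["WM"] = wm
    vent = np.zeros(dims, bool)
    vent[nx // 2 - 1 : nx // 2 + 1, ny // 2 + 3 : ny // 2 + 5, ref_z + 1 : ref_z + 3] = True
    masks["VENT"] = vent

    # search box: tight bound of the SMA mask plus a 1-voxel margin
    idx = np.argwhere(masks["SMA"])
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, dims)
    sma_bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    bbox_mask = np.zeros(dims, bool)
    bbox_mask[sma_bbox] = True
    for name in ACTIVE_REGIONS:
        if name != "SMA" and (masks[name] & bbox_mask).any():
            raise ValueError(f"region {name} intrudes into the SMA search box")
        if (masks[name] & masks["REF_SLAB"]).any():
            raise ValueError(f"region {name} collides with the reference slab")
    for name in ("WM", "VENT"):
        for active in ACTIVE_REGIONS:
            if (masks[name] & masks[active]).any():
                raise ValueError(f"nuisance region {name} collides with {active}")
    if (masks["WM"] & masks["VENT"]).any():
        raise ValueError("WM collides with VENT")

    return PhantomSpec(dims=dims, voxel_size_mm=voxel_size_mm, masks=masks, sma_bbox=sma_bbox)
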