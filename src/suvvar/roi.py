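"""Sphere detection and voxel masks.

Three masks drive the SUV metrics: the 3-D sphere mask (voxel centers
within the nominal radius of the detected center), its restriction to the
central axial plane (the 2-D disk), and the 1 cm^3 spherical neighbourhood
used for the peak value.  The inclusion rule is always *center-in*: a
voxel belongs to a mask iff its geometric center lies inside the region —
no partial weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, ImageVolume, PhantomGeometry

__all__ = [
    "DetectionError",
    "SphereROI",
    "VoxelMask",
    "detect_spheres",
    "sphere_mask_3d",
    "disk_mask_2d",
    "peak_mask",
    "PEAK_RADIUS_MM",
]

#: Radius of the 1 cm^3 spherical peak neighbourhood: (3*1000 / 4pi)^(1/3) mm.
PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

#: Minimum separation between detected sphere candidates (mm).
_MIN_PEAK_SEPARATION_MM = 20.0


class DetectionError(RuntimeError):
    """Sphere detection failed."""


@dataclass(frozen=True)
class SphereROI:
    """A detected sphere: label, physical center, nominal size, central slice."""

    sphere_id: int
    center_mm: tuple[float, float, float]
    nominal_diameter_mm: float
    central_plane_index: int


@dataclass(frozen=True)
class VoxelMask:
    """A set of voxel indices on a grid, stored as an (N, 3) integer array."""

    indices: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        idx = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if idx.size and (np.any(idx < 0) or np.any(idx >= np.asarray(self.grid.shape))):
            raise ValueError("mask indices out of grid bounds")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return 0 if self.indices.size == 0 else self.indices.shape[0]

    def extract(self, image: ImageVolume) -> np.ndarray:
        """Values of the masked voxels."""
        return image.values[tuple(self.indices.T)]

    def to_boolean(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        if len(self):
            out[tuple(self.indices.T)] = True
        return out


def _central_plane_index(center_z_mm: float, grid: GridSpec) -> int:
    """Axial slice nearest the center; exact ties go to the lower index."""
    q = (center_z_mm - grid.origin_mm[2]) / grid.voxel_size_mm
    idx = int(np.ceil(q - 0.5))  # ties (q = k + 0.5) resolve to k
    return int(np.clip(idx, 0, grid.shape[2] - 1))


def _roi_from_center(sphere_id: int, center_mm, diameter_mm: float, grid: GridSpec) -> SphereROI:
    return SphereROI(
        sphere_id=int(sphere_id),
        center_mm=tuple(float(c) for c in center_mm),
        nominal_diameter_mm=float(diameter_mm),
        central_plane_index=_central_plane_index(float(center_mm[2]), grid),
    )


def _refine_center_of_mass(image: ImageVolume, center_mm, diameter_mm: float) -> np.ndarray:
    """Intensity center-of-mass within the nominal sphere around ``center_mm``."""
    grid = image.grid
    roi = _roi_from_center(0, center_mm, diameter_mm, grid)
    mask = sphere_mask_3d(roi, grid)
    vals = mask.extract(image)
    w = np.clip(vals, 0, None)
    if w.sum() <= 0:
        return np.asarray(center_mm, dtype=float)
    com_idx = (mask.indices * w[:, None]).sum(axis=0) / w.sum()
    return grid.index_to_mm(com_idx)


def detect_spheres(
    image: ImageVolume,
    geom_hint: PhantomGeometry | None = None,
    expected_diameters_mm: tuple[float, ...] | None = None,
) -> list[SphereROI]:
    """Locate the six spheres; returns ROIs sorted by nominal diameter.

    With a geometry hint the known centers are refined by center-of-mass
    within each nominal sphere.  Without one, the image is lightly
    smoothed, the six strongest local maxima at least 20 mm apart are
    taken as candidates, each candidate's size is estimated from the
    volume of its half-contrast isocontour (50% between the background
    level and the local max), and candidates are matched to the expected
    diameters by size rank.

    Raises
    ------
    DetectionError
        If fewer than six candidate regions are found in automatic mode.
    """
    grid = image.grid
    if geom_hint is not None:
        diameters = np.asarray(geom_hint.sphere_diameters_mm, dtype=float)
        rois = []
        for d, c, sid in zip(diameters, geom_hint.sphere_centers_mm, geom_hint.sphere_ids()):
            refined = _refine_center_of_mass(image, c, d)
            rois.append(_roi_from_center(sid, refined, d, grid))
        return sorted(rois, key=lambda r: r.nominal_diameter_mm)

    if expected_diameters_mm is None:
        from .geometry import DEFAULT_SPHERE_DIAMETERS_MM

        expected_diameters_mm = DEFAULT_SPHERE_DIAMETERS_MM
    expected = np.sort(np.asarray(expected_diameters_mm, dtype=float))

    smoothed = ndimage.gaussian_filter(np.asarray(image.values, dtype=float), sigma=1.0)
    min_sep_vox = max(1, int(np.ceil(_MIN_PEAK_SEPARATION_MM / grid.voxel_size_mm)))
    footprint = np.ones((2 * min_sep_vox + 1,) * 3, dtype=bool)
    is_max = (smoothed == ndimage.maximum_filter(smoothed, footprint=footprint)) & (
        smoothed > smoothed.mean()
    )
    if not np.any(is_max):
        raise DetectionError("no local maxima found (uniform image?)")
    # a flat region produces a plateau of tied maxima: reduce each connected
    # plateau to a single representative voxel
    labels, n_plateaus = ndimage.label(is_max)
    reps = ndimage.maximum_position(smoothed, labels, index=range(1, n_plateaus + 1))
    cand = np.asarray(reps, dtype=int)
    # strongest first; greedily enforce the minimum separation
    order = np.argsort(smoothed[tuple(cand.T)])[::-1]
    picked: list[np.ndarray] = []
    for i in order:
        p = cand[i]
        if all(np.linalg.norm((p - q) * grid.voxel_size_mm) >= _MIN_PEAK_SEPARATION_MM for q in picked):
            picked.append(p)
        if len(picked) == 6:
            break
    if len(picked) < 6:
        raise DetectionError(
            f"found only {len(picked)} candidate sphere regions "
            f"at {[tuple(map(int, p)) for p in picked]}"
        )

    # equivalent diameter from the half-contrast isocontour volume
    # (50% between the background level and the local max)
    positive = smoothed[smoothed > 0]
    background = float(np.median(positive)) if positive.size else 0.0
    est = []
    for p in picked:
        thr = background + 0.5 * (smoothed[tuple(p)] - background)
        labels, _ = ndimage.label(smoothed >= thr)
        region = labels == labels[tuple(p)]
        vol_mm3 = region.sum() * grid.voxel_size_mm**3
        eq_diam = (6.0 * vol_mm3 / np.pi) ** (1.0 / 3.0)
        com = ndimage.center_of_mass(np.asarray(image.values, dtype=float) * region)
        est.append((eq_diam, grid.index_to_mm(com)))

    est.sort(key=lambda t: t[0])
    rois = []
    for (eq_diam, center), d in zip(est, expected):
        refined = _refine_center_of_mass(image, center, d)
        rois.append(_roi_from_center(int(round(d)), refined, d, grid))
    return sorted(rois, key=lambda r: r.nominal_diameter_mm)


def _centers_within(center_mm, radius_mm: float, grid: GridSpec, clip: bool) -> np.ndarray:
    """Integer indices of voxels whose centers lie within ``radius_mm`` of a point."""
    center_mm = np.asarray(center_mm, dtype=float)
    lo = np.floor(grid.mm_to_index(center_mm - radius_mm)).astype(int)
    hi = np.ceil(grid.mm_to_index(center_mm + radius_mm)).astype(int)
    if clip:
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(grid.shape) - 1)
    elif np.any(lo < 0) or np.any(hi >= np.asarray(grid.shape)):
        raise ValueError("region extends beyond the grid")
    ranges = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    idx = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid.index_to_mm(idx) - center_mm) ** 2).sum(axis=1)
    return idx[d2 <= radius_mm**2]


def sphere_mask_3d(roi: SphereROI, grid: GridSpec) -> VoxelMask:
    """Voxels whose centers lie within the nominal sphere radius of the ROI center."""
    idx = _centers_within(roi.center_mm, roi.nominal_diameter_mm / 2.0, grid, clip=False)
    return VoxelMask(indices=idx, grid=grid)


def disk_mask_2d(roi: SphereROI, grid: GridSpec) -> VoxelMask:
    """The 3-D sphere mask restricted to the ROI's central axial plane."""
    mask = sphere_mask_3d(roi, grid)
    idx = mask.indices[mask.indices[:, 2] == roi.central_plane_index]
    return VoxelMask(indices=idx, grid=grid)


def peak_mask(center_voxel, grid: GridSpec) -> VoxelMask:
    """The 1 cm^3 spherical neighbourhood centred on a voxel's center.

    If the ball is clipped by the grid boundary a warning is issued and
    the clipped mask returned.
    """
    center_voxel = np.asarray(center_voxel, dtype=int)
    if not grid.contains_index(center_voxel):
        raise ValueError(f"center voxel {tuple(center_voxel)} outside grid")
    center_mm = grid.index_to_mm(center_voxel)
    full = _centers_within(center_mm, PEAK_RADIUS_MM, grid, clip=True)
    # detect clipping: would any in-ball voxel fall outside the grid?
    r_vox = PEAK_RADIUS_MM / grid.voxel_size_mm
    if np.any(center_voxel - np.floor(r_vox) < 0) or np.any(
        center_voxel + np.floor(r_vox) > np.asarray(grid.shape) - 1
    ):
        warnings.warn(
            f"1 cm^3 peak neighbourhood at voxel {tuple(center_voxel)} clipped by grid boundary",
            stacklevel=2,
        )
    return VoxelMask(indices=full, grid=grid)
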