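"""Phantom geometry, voxel grids and image volumes.

The phantom emulated here is the NEMA NU2 image-quality phantom: a
torso-shaped background compartment, a cold cylindrical insert on the
central axis, and six fillable spheres (10-37 mm diameter) arranged on a
ring around the insert.  All activity concentrations are stored in kBq/ml
and refer to the start of the acquisition.

Coordinate convention: images are indexed ``values[i, j, k]`` with the
axial direction last; voxel ``(i, j, k)`` has its *center* at physical
position ``origin_mm + index * voxel_size_mm`` (0-based indices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "GridSpec",
    "PhantomGeometry",
    "ImageVolume",
    "build_phantom_geometry",
    "rasterize_activity",
    "DEFAULT_SPHERE_DIAMETERS_MM",
]

#: Nominal inner diameters of the six fillable spheres (mm).
DEFAULT_SPHERE_DIAMETERS_MM: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

#: Default activity concentrations at scan start (kBq/ml): 2.10 MBq/ml
#: background, 20.04 MBq/ml spheres (nominal 10:1 sphere:background aim).
DEFAULT_BACKGROUND_KBQ_ML = 2.10e3
DEFAULT_SPHERE_KBQ_ML = 20.04e3

#: Radius of the ring on which sphere centers sit (mm), standard layout.
DEFAULT_RING_RADIUS_MM = 57.2


class ConfigurationError(ValueError):
    """Invalid phantom / grid configuration."""


@dataclass(frozen=True)
class GridSpec:
    """A regular isotropic voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, axial).
    voxel_size_mm : float
        Isotropic voxel pitch in mm.
    origin_mm : tuple of float
        Physical position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int] = (144, 144, 48)
    voxel_size_mm: float = 4.0
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be > 0")
        if any(n < 1 for n in self.shape) or len(self.shape) != 3:
            raise ConfigurationError(f"invalid grid shape {self.shape}")
        if self.origin_mm is None:
            # center the grid on the physical origin
            object.__setattr__(
                self,
                "origin_mm",
                tuple(-(n - 1) / 2.0 * self.voxel_size_mm for n in self.shape),
            )

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1 cm^3)."""
        return (self.voxel_size_mm / 10.0) ** 3

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along ``axis``."""
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(self.shape[axis])

    def index_to_mm(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + self.voxel_size_mm * np.asarray(index, dtype=float)

    def mm_to_index(self, position_mm) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical position."""
        return (np.asarray(position_mm, dtype=float) - np.asarray(self.origin_mm)) / self.voxel_size_mm

    def contains_index(self, index) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))


@dataclass(frozen=True)
class PhantomGeometry:
    """Ground-truth description of the image-quality phantom."""

    sphere_diameters_mm: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS_MM
    sphere_centers_mm: tuple[tuple[float, float, float], ...] = ()
    torso_semiaxes_mm: tuple[float, float] = (150.0, 115.0)
    lung_insert_radius_mm: float = 25.0
    background_activity_kbq_ml: float = DEFAULT_BACKGROUND_KBQ_ML
    sphere_activity_kbq_ml: float = DEFAULT_SPHERE_KBQ_ML

    @property
    def sphere_to_background_ratio(self) -> float:
        """Computed activity ratio (nominal aim is 10:1)."""
        return self.sphere_activity_kbq_ml / self.background_activity_kbq_ml

    def sphere_ids(self) -> tuple[int, ...]:
        """Labels for the spheres: nominal diameter rounded to mm."""
        return tuple(int(round(d)) for d in self.sphere_diameters_mm)


@dataclass
class ImageVolume:
    """A 3-D activity-concentration map with frame timing metadata.

    ``frame_duration_s`` is the reconstruction length (RL) of the frame;
    a duration of 0 marks a noise-free truth image.  Values are kBq/ml,
    decay-corrected to ``decay_corrected_to_s`` (0 = acquisition start).
    """

    values: np.ndarray
    grid: GridSpec
    frame_start_s: float = 0.0
    frame_duration_s: float = 0.0
    decay_corrected_to_s: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.frame_duration_s < 0:
            raise ValueError("frame_duration_s must be >= 0")


def _default_sphere_centers(
    diameters: tuple[float, ...],
    ring_radius_mm: float = DEFAULT_RING_RADIUS_MM,
    axial_mm: float = 0.0,
) -> tuple[tuple[float, float, float], ...]:
    """Place sphere centers on a ring at 60 degree spacing in one axial plane."""
    centers = []
    for k in range(len(diameters)):
        theta = 2.0 * np.pi * k / 6.0
        centers.append(
            (ring_radius_mm * float(np.cos(theta)), ring_radius_mm * float(np.sin(theta)), axial_mm)
        )
    return tuple(centers)


def build_phantom_geometry(config: dict | None = None) -> PhantomGeometry:
    """Build a validated :class:`PhantomGeometry` from a configuration mapping.

    Recognised keys (all optional): ``sphere_diameters_mm``,
    ``sphere_centers_mm``, ``ring_radius_mm``, ``torso_semiaxes_mm``,
    ``lung_insert_radius_mm``, ``background_activity_kbq_ml``,
    ``sphere_activity_kbq_ml``.

    Raises
    ------
    ConfigurationError
        If spheres overlap, lie outside the torso, or activities are negative.
    """
    config = dict(config or {})
    diameters = tuple(float(d) for d in config.pop("sphere_diameters_mm", DEFAULT_SPHERE_DIAMETERS_MM))
    if len(diameters) != 6:
        raise ConfigurationError(f"exactly six spheres required, got {len(diameters)}")
    if any(d <= 0 for d in diameters):
        raise ConfigurationError("sphere diameters must be positive")
    if len(set(diameters)) != 6:
        raise ConfigurationError("sphere diameters must be distinct")

    ring_radius = float(config.pop("ring_radius_mm", DEFAULT_RING_RADIUS_MM))
    centers = config.pop("sphere_centers_mm", None)
    if centers is None:
        centers = _default_sphere_centers(diameters, ring_radius)
    centers = tuple(tuple(float(c) for c in p) for p in centers)
    if len(centers) != 6:
        raise ConfigurationError("six sphere centers required")

    geom = PhantomGeometry(
        sphere_diameters_mm=diameters,
        sphere_centers_mm=centers,
        torso_semiaxes_mm=tuple(float(v) for v in config.pop("torso_semiaxes_mm", (150.0, 115.0))),
        lung_insert_radius_mm=float(config.pop("lung_insert_radius_mm", 25.0)),
        background_activity_kbq_ml=float(
            config.pop("background_activity_kbq_ml", DEFAULT_BACKGROUND_KBQ_ML)
        ),
        sphere_activity_kbq_ml=float(config.pop("sphere_activity_kbq_ml", DEFAULT_SPHERE_KBQ_ML)),
    )
    if config:
        raise ConfigurationError(f"unrecognised phantom config keys: {sorted(config)}")
    validate_geometry(geom)
    return geom


def validate_geometry(geom: PhantomGeometry) -> None:
    """Raise :class:`ConfigurationError` on invariant violations."""
    if geom.background_activity_kbq_ml < 0 or geom.sphere_activity_kbq_ml < 0:
        raise ConfigurationError("activity concentrations must be >= 0")
    if geom.lung_insert_radius_mm < 0:
        raise ConfigurationError("lung insert radius must be >= 0")
    ids = geom.sphere_ids()
    for (i, ci), (j, cj) in itertools.combinations(enumerate(geom.sphere_centers_mm), 2):
        dist = float(np.linalg.norm(np.subtract(ci, cj)))
        min_sep = (geom.sphere_diameters_mm[i] + geom.sphere_diameters_mm[j]) / 2.0
        if dist < min_sep:
            raise ConfigurationError(
                f"spheres {ids[i]} mm and {ids[j]} mm overlap "
                f"(center distance {dist:.1f} mm < {min_sep:.1f} mm)"
            )
    a, b = geom.torso_semiaxes_mm
    for i, (cx, cy, _cz) in enumerate(geom.sphere_centers_mm):
        r = geom.sphere_diameters_mm[i] / 2.0
        # conservative: sphere bounding circle must fit inside the ellipse
        if (abs(cx) + r) ** 2 / a**2 + (abs(cy) + r) ** 2 / b**2 > 1.0:
            raise ConfigurationError(f"sphere {ids[i]} mm extends outside the torso compartment")


def rasterize_activity(
    geom: PhantomGeometry, grid: GridSpec, supersample: int = 5
) -> ImageVolume:
    """Render the noise-free ground-truth activity map on a voxel grid.

    Voxels crossing a sphere boundary get the partial-volume value
    ``background + (sphere - background) * fraction_inside``, where the
    inside fraction is estimated by ``supersample**3`` sub-voxel point
    samples.  Background fills the torso ellipse; the cold central insert
    and the region outside the torso are zero.  Frame metadata is zeroed
    (truth image).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    validate_geometry(geom)

    xs = grid.axis_centers_mm(0)
    ys = grid.axis_centers_mm(1)
    a, b = geom.torso_semiaxes_mm
    torso2d = (xs[:, None] / a) ** 2 + (ys[None, :] / b) ** 2 <= 1.0
    lung2d = xs[:, None] ** 2 + ys[None, :] ** 2 <= geom.lung_insert_radius_mm**2

    values = np.zeros(grid.shape, dtype=float)
    values[torso2d & ~lung2d, :] = geom.background_activity_kbq_ml

    # sub-voxel sample offsets in mm, symmetric about the voxel center
    s = int(supersample)
    off = (np.arange(s) + 0.5) / s - 0.5
    off_mm = off * grid.voxel_size_mm
    ox, oy, oz = np.meshgrid(off_mm, off_mm, off_mm, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)

    bg = geom.background_activity_kbq_ml
    act = geom.sphere_activity_kbq_ml
    for diam, center in zip(geom.sphere_diameters_mm, geom.sphere_centers_mm):
        r = diam / 2.0
        lo = np.floor(grid.mm_to_index(np.subtract(center, r + grid.voxel_size_mm))).astype(int)
        hi = np.ceil(grid.mm_to_index(np.add(center, r + grid.voxel_size_mm))).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(grid.shape) - 1)
        idx = np.stack(
            np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        centers_mm = grid.index_to_mm(idx)  # (n, 3)
        # fraction of sub-voxel sample points inside the sphere
        d2 = ((centers_mm[:, None, :] + offsets[None, :, :] - np.asarray(center)) ** 2).sum(axis=2)
        frac = (d2 <= r * r).mean(axis=1)
        sel = frac > 0
        values[tuple(idx[sel].T)] = bg + (act - bg) * frac[sel]

    return ImageVolume(values=values, grid=grid, frame_start_s=0.0, frame_duration_s=0.0)
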