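"""SUV metric extraction.

Five metrics per sphere per frame, all in kBq/ml (phantom context — no
body-weight normalisation):

* ``Max2D`` / ``Max3D``: maximum voxel value in the central 2-D disk /
  3-D sphere mask;
* ``Mean2D`` / ``Mean3D``: arithmetic mean over the same masks, with no
  thresholding;
* ``Peak``: mean over the 1 cm^3 ball centred on the maximum voxel of the
  3-D sphere mask.

ROIs are detected once on a reference image and reused across all frames
of all reconstruction lengths, so the measured variation reflects
counting statistics only, not segmentation variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import GridSpec, ImageVolume
from .roi import SphereROI, VoxelMask, disk_mask_2d, peak_mask, sphere_mask_3d

__all__ = [
    "METRIC_NAMES",
    "SUVRecord",
    "suv_max_2d",
    "suv_max_3d",
    "suv_mean_2d",
    "suv_mean_3d",
    "suv_peak",
    "measure_frame",
    "compute_all_metrics",
]

METRIC_NAMES: tuple[str, ...] = ("Max2D", "Max3D", "Mean2D", "Mean3D", "Peak")

#: Tidy-table column order for SUV measurement records.
RECORD_COLUMNS = ("sphere_id", "metric", "rl_s", "frame_index", "value_kbq_ml")


@dataclass(frozen=True)
class SUVRecord:
    sphere_id: int
    metric: str
    rl_s: float
    frame_index: int
    value_kbq_ml: float


def _require_nonempty(mask: VoxelMask, what: str) -> None:
    if len(mask) == 0:
        raise ValueError(f"empty {what} mask")


def suv_max_2d(image: ImageVolume, roi: SphereROI) -> float:
    mask = disk_mask_2d(roi, image.grid)
    _require_nonempty(mask, "central-disk")
    return float(mask.extract(image).max())


def suv_max_3d(image: ImageVolume, roi: SphereROI) -> float:
    mask = sphere_mask_3d(roi, image.grid)
    _require_nonempty(mask, "sphere")
    return float(mask.extract(image).max())


def suv_mean_2d(image: ImageVolume, roi: SphereROI) -> float:
    mask = disk_mask_2d(roi, image.grid)
    _require_nonempty(mask, "central-disk")
    return float(mask.extract(image).mean())


def suv_mean_3d(image: ImageVolume, roi: SphereROI) -> float:
    mask = sphere_mask_3d(roi, image.grid)
    _require_nonempty(mask, "sphere")
    return float(mask.extract(image).mean())


def _argmax_voxel(image: ImageVolume, mask: VoxelMask) -> np.ndarray:
    """Index of the maximum voxel in the mask; ties -> lexicographically lowest."""
    vals = mask.extract(image)
    best = vals == vals.max()
    cand = mask.indices[best]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    return cand[order[0]]


def suv_peak(image: ImageVolume, roi: SphereROI) -> float:
    """Mean over the 1 cm^3 ball centred on the hottest voxel of the sphere mask."""
    mask = sphere_mask_3d(roi, image.grid)
    _require_nonempty(mask, "sphere")
    center = _argmax_voxel(image, mask)
    ball = peak_mask(center, image.grid)
    return float(ball.extract(image).mean())


_METRIC_FUNCS = {
    "Max2D": suv_max_2d,
    "Max3D": suv_max_3d,
    "Mean2D": suv_mean_2d,
    "Mean3D": suv_mean_3d,
    "Peak": suv_peak,
}


def measure_frame(
    image: ImageVolume,
    rois: Sequence[SphereROI],
    rl_s: float | None = None,
    frame_index: int = 0,
) -> list[SUVRecord]:
    """All five metrics for all ROIs on a single frame."""
    rl = image.frame_duration_s if rl_s is None else rl_s
    records = []
    for roi in rois:
        for name, func in _METRIC_FUNCS.items():
            try:
                value = func(image, roi)
            except Exception as exc:  # re-raise with context
                raise RuntimeError(
                    f"metric {name} failed for sphere {roi.sphere_id} mm, "
                    f"frame {frame_index} (RL={rl} s): {exc}"
                ) from exc
            records.append(
                SUVRecord(
                    sphere_id=roi.sphere_id,
                    metric=name,
                    rl_s=float(rl),
                    frame_index=int(frame_index),
                    value_kbq_ml=value,
                )
            )
    return records


def records_to_frame(records: Iterable[SUVRecord]) -> pd.DataFrame:
    """Long-format measurement table with one row per (sphere, metric, frame)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return df[list(RECORD_COLUMNS)]


def compute_all_metrics(
    frames: Mapping[float, Sequence[ImageVolume]],
    rois: Sequence[SphereROI],
) -> pd.DataFrame:
    """Measure every frame of every subset with a fixed set of ROIs.

    Returns the tidy table of 5 metrics x len(rois) spheres x total frame
    count rows.
    """
    records: list[SUVRecord] = []
    for rl, frame_list in frames.items():
        for f_idx, image in enumerate(frame_list):
            records.extend(measure_frame(image, rois, rl_s=rl, frame_index=f_idx))
    return records_to_frame(records)
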