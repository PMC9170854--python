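"""NIfTI frame I/O with JSON timing sidecars.

Each frame is one ``.nii`` file plus a sidecar ``<stem>.json`` holding
``frame_start_s``, ``frame_duration_s``, ``decay_corrected_to_s`` and
``voxel_size_mm``; reading groups the frames by duration (the
reconstruction length) and validates grid consistency.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import GridSpec, ImageVolume

__all__ = ["write_frame", "write_frames", "read_frames"]

_SIDECAR_REQUIRED = ("frame_start_s", "frame_duration_s", "voxel_size_mm")


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.voxel_size_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def write_frame(image: ImageVolume, path: str | Path) -> Path:
    """Write one volume as NIfTI plus its JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=np.float64), _affine(image.grid)), path)
    sidecar = {
        "frame_start_s": image.frame_start_s,
        "frame_duration_s": image.frame_duration_s,
        "decay_corrected_to_s": image.decay_corrected_to_s,
        "voxel_size_mm": image.grid.voxel_size_mm,
        "origin_mm": list(image.grid.origin_mm),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_frames(frames: dict[float, list[ImageVolume]], out_dir: str | Path) -> list[Path]:
    """Write every frame of every subset as ``rl<RL>_frame<k>.nii``."""
    out_dir = Path(out_dir)
    paths = []
    for rl, frame_list in frames.items():
        for k, image in enumerate(frame_list):
            paths.append(write_frame(image, out_dir / f"rl{rl:g}_frame{k:03d}.nii"))
    return paths


def _load_one(nii_path: Path) -> ImageVolume:
    sidecar_path = nii_path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {nii_path.name}")
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar_path.name} lacks required keys {missing}")
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = GridSpec(
        shape=tuple(int(n) for n in data.shape),
        voxel_size_mm=float(meta["voxel_size_mm"]),
        origin_mm=tuple(meta["origin_mm"]) if "origin_mm" in meta else None,
    )
    return ImageVolume(
        values=data,
        grid=grid,
        frame_start_s=float(meta["frame_start_s"]),
        frame_duration_s=float(meta["frame_duration_s"]),
        decay_corrected_to_s=float(meta.get("decay_corrected_to_s", 0.0)),
    )


def read_frames(directory: str | Path) -> dict[float, list[ImageVolume]]:
    """Load all NIfTI frames in a directory, grouped by reconstruction length.

    All frames must share one grid (shape and voxel size); frames within a
    group are ordered by frame start time.
    """
    directory = Path(directory)
    nii_paths = sorted(directory.glob("*.nii")) + sorted(directory.glob("*.nii.gz"))
    if not nii_paths:
        raise FileNotFoundError(f"no NIfTI frames in {directory}")
    volumes = [_load_one(p) for p in nii_paths]
    ref = volumes[0].grid
    for p, v in zip(nii_paths, volumes):
        if v.grid.shape != ref.shape or v.grid.voxel_size_mm != ref.voxel_size_mm:
            raise ValueError(
                f"grid mismatch in {p.name}: {v.grid.shape}@{v.grid.voxel_size_mm} mm "
                f"vs {ref.shape}@{ref.voxel_size_mm} mm"
            )
    out: dict[float, list[ImageVolume]] = {}
    for v in volumes:
        out.setdefault(v.frame_duration_s, []).append(v)
    for rl in out:
        out[rl].sort(key=lambda im: im.frame_start_s)
    return out
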