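"""NIfTI import/export for scans, masks and probability stacks."""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import nibabel as nib
import numpy as np

from .errors import InputError
from .synthcohort import ScanRecord
from .uncmask import ProbStack

__all__ = [
    "save_volume",
    "load_volume",
    "save_prob_stack",
    "load_prob_stack",
    "export_cohort",
    "load_scan",
]


def _affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    # arrays are (slices=z, y, x); NIfTI axes are (x, y, z)
    sx, sy, sz = spacing
    return np.diag([sx, sy, sz, 1.0])


def save_volume(path, volume: np.ndarray, spacing) -> None:
    """Write a (slices, H, W) volume as NIfTI with the given (x, y, z)
    spacing; boolean arrays are stored as uint8."""
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), _affine(spacing)), str(path))


def load_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a NIfTI volume back to (slices, H, W) plus its (x, y, z) spacing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.transpose(data, (2, 1, 0)), spacing


def save_prob_stack(path, stack: ProbStack, spacing) -> None:
    """Write the T replicate maps as a 4-D NIfTI (T on the 4th axis)."""
    arr = np.transpose(stack.values, (3, 2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))


def load_prob_stack(path) -> ProbStack:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InputError(f"{path}: expected a 4-D probability stack")
    return ProbStack(np.transpose(data, (3, 2, 1, 0)).astype(float))


def export_cohort(scans: Sequence[ScanRecord], outdir) -> List[str]:
    """One image + one mask NIfTI per scan; returns the filenames written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for s in scans:
        stem = f"{s.subject_id}_rep{s.repeat_index:02d}"
        save_volume(outdir / f"{stem}_image.nii.gz", s.image, s.spacing)
        save_volume(outdir / f"{stem}_mask.nii.gz", s.gt_mask, s.spacing)
        written += [f"{stem}_image.nii.gz", f"{stem}_mask.nii.gz"]
    return written


def load_scan(
    image_path, mask_path, subject_id: str, group: str, repeat_index: int
) -> ScanRecord:
    """Assemble a ScanRecord from user-supplied NIfTI image + mask files."""
    image, spacing = load_volume(image_path)
    mask, mspacing = load_volume(mask_path)
    if not np.allclose(spacing, mspacing, atol=1e-6):
        raise InputError(f"image/mask spacing mismatch: {spacing} vs {mspacing}")
    return ScanRecord(
        subject_id=subject_id,
        group=group,
        repeat_index=repeat_index,
        image=image.astype(float),
        gt_mask=mask > 0,
        spacing=spacing,
    )
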