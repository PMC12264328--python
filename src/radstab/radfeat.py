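"""Radiomic preprocessing and 105-feature extraction.

The extraction protocol mirrors common practice for thick-slice abdominal
MRI radiomics:

1. intensity windowing of the raw volume to [μ − 0.5σ, μ + 4σ] followed by
   linear rescaling to [0, 255];
2. resampling to a common voxel size (default 1.458 × 1.458 × 5.5 mm,
   B-spline for the image, nearest-neighbour for masks), then z-score
   intensity standardization over the volume;
3. gray-level discretization with a fixed bin count (default 64) over the
   ROI intensity range;
4. because through-plane resolution is much coarser than in-plane
   resolution, first-order and texture features are computed slice by
   slice (2-D) and averaged over the slices that intersect the mask, while
   shape descriptors are computed once in 3-D.

The feature roster is pinned to exactly 105 named features — 18 first
order, 14 shape, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM — listed
in :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk

from . import _shape, _texture
from .errors import DegenerateInputError, InputError, ParameterError

__all__ = [
    "RadiomicsConfig",
    "FEATURE_NAMES",
    "CATEGORY_ROSTER",
    "intensity_window",
    "preprocess_for_radiomics",
    "discretize",
    "extract_features",
    "extract_feature_table",
    "feature_manifest",
]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

#: Per-category feature rosters (names without the category prefix).
CATEGORY_ROSTER: Dict[str, tuple] = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": _shape.SHAPE_NAMES,
    "glcm": _texture.GLCM_NAMES,
    "glrlm": _texture.GLRLM_NAMES,
    "glszm": _texture.GLSZM_NAMES,
    "gldm": _texture.GLDM_NAMES,
    "ngtdm": _texture.NGTDM_NAMES,
}

#: The pinned 105-feature manifest, in extraction order.
FEATURE_NAMES: tuple = tuple(
    f"{cat}_{name}"
    for cat in ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
    for name in CATEGORY_ROSTER[cat]
)
assert len(FEATURE_NAMES) == 105


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings: spacing, interpolation, normalization, binning."""

    target_spacing: Tuple[float, float, float] = (1.458, 1.458, 5.5)  # (x, y, z) mm
    interpolator: str = "bspline"
    normalization: bool = True
    n_bins: int = 64
    categories: Tuple[str, ...] = (
        "shape",
        "firstorder",
        "glcm",
        "glrlm",
        "glszm",
        "gldm",
        "ngtdm",
    )
    slicewise: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if any(s <= 0 for s in self.target_spacing):
            raise ParameterError("spacing components must be > 0")
        unknown = set(self.categories) - set(CATEGORY_ROSTER)
        if unknown:
            raise ParameterError(f"unknown feature categories: {sorted(unknown)}")

    @property
    def feature_names(self) -> tuple:
        return tuple(
            f"{cat}_{name}"
            for cat in ("shape", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
            if cat in self.categories
            for name in CATEGORY_ROSTER[cat]
        )


def feature_manifest(cfg: Optional[RadiomicsConfig] = None) -> str:
    """JSON manifest of the feature roster and the extraction settings."""
    cfg = cfg or RadiomicsConfig()
    return json.dumps(
        {
            "n_features": len(cfg.feature_names),
            "features": list(cfg.feature_names),
            "settings": {
                "target_spacing_mm": list(cfg.target_spacing),
                "interpolator": cfg.interpolator,
                "zscore_normalization": cfg.normalization,
                "n_bins": cfg.n_bins,
                "slicewise": cfg.slicewise,
            },
        },
        indent=2,
    )


# --------------------------------------------------------------------------
# preprocessing

def intensity_window(image: np.ndarray) -> np.ndarray:
    """Clamp to [μ − 0.5σ, μ + 4σ] and rescale linearly to [0, 255].

    σ is the population SD of the whole volume.  A constant image has no
    window; by convention it maps to all zeros (and is reported via
    :class:`DegenerateInputError` being *not* raised — callers who need the
    distinction can test ``image.std() == 0`` first).
    """
    x = np.asarray(image, dtype=float)
    if x.size < 2:
        raise InputError("intensity_window needs at least 2 voxels")
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    lo, hi = mu - 0.5 * sd, mu + 4.0 * sd
    x = np.clip(x, lo, hi)
    lo2, hi2 = x.min(), x.max()
    if hi2 <= lo2:
        return np.zeros_like(x)
    return (x - lo2) / (hi2 - lo2) * 255.0


def _resample(
    volume: np.ndarray,
    spacing: Tuple[float, float, float],
    target: Tuple[float, float, float],
    interpolator,
) -> np.ndarray:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume))
    img.SetSpacing(tuple(float(s) for s in spacing))
    size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(img.GetSize(), img.GetSpacing(), target)
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(t) for t in target))
    res.SetSize(size)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    return sitk.GetArrayFromImage(res.Execute(img))


def preprocess_for_radiomics(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: RadiomicsConfig,
    spacing: Tuple[float, float, float],
) -> Tuple[np.ndarray, np.ndarray, Tuple[float, float, float]]:
    """Resample to the target grid and z-score standardize intensities.

    The image is resampled with a B-spline interpolator, the mask with
    nearest-neighbour so it stays binary; both land on the same grid.
    Z-score statistics are computed over the whole resampled volume.
    Returns ``(image, mask, spacing)`` on the target grid.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise InputError("image and mask must share the grid")
    same = np.allclose(spacing, cfg.target_spacing, rtol=0, atol=1e-9)
    if not same:
        interp = sitk.sitkBSpline if cfg.interpolator == "bspline" else sitk.sitkLinear
        image = _resample(image, spacing, cfg.target_spacing, interp)
        mask = (
            _resample(mask.astype(np.uint8), spacing, cfg.target_spacing,
                      sitk.sitkNearestNeighbor)
            > 0
        )
    if not mask.any():
        raise DegenerateInputError("mask is empty after resampling")
    if cfg.normalization:
        sd = image.std()
        if sd == 0:
            raise DegenerateInputError("constant image cannot be z-scored")
        image = (image - image.mean()) / sd
    return image, mask, cfg.target_spacing


def discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-count discretization to integer levels 1..n_bins over the
    value range; a constant input maps to level 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.ones(v.shape, dtype=int)
    lev = np.floor(n_bins * (v - lo) / (hi - lo)).astype(int) + 1
    return np.clip(lev, 1, n_bins)


# --------------------------------------------------------------------------
# first-order features (on one slice ROI)

def _firstorder(values: np.ndarray, disc: np.ndarray, n_bins: int, voxel_volume: float):
    x = values
    n = x.size
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    hist = np.bincount(disc, minlength=n_bins + 1)[1:].astype(float)
    p = hist[hist > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2**2)
    else:
        skew, kurt = 0.0, 0.0
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -float(np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": (
            float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float(np.sum(p**2)),
    }


# --------------------------------------------------------------------------
# extraction

_TEXTURE_FUNCS = {
    "glcm": _texture.glcm_features,
    "glrlm": _texture.glrlm_features,
    "glszm": _texture.glszm_features,
    "gldm": _texture.gldm_features,
    "ngtdm": _texture.ngtdm_features,
}


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: Optional[RadiomicsConfig] = None,
    spacing: Optional[Tuple[float, float, float]] = None,
) -> Dict[str, float]:
    """Compute the full named feature vector for one (image, mask) pair.

    Inputs are assumed already preprocessed (see
    :func:`preprocess_for_radiomics`).  First-order and texture features
    are computed per 2-D slice intersecting the mask and averaged
    (unweighted, over contributing slices; per-slice undefined values are
    excluded from the average); shape features are computed once in 3-D.
    Values a degenerate ROI leaves undefined are NaN, not zero.
    """
    cfg = cfg or RadiomicsConfig()
    spacing = spacing or cfg.target_spacing
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise InputError("image and mask must share the grid")
    if not mask.any():
        raise DegenerateInputError("empty ROI")

    out: Dict[str, float] = {}
    if "shape" in cfg.categories:
        sh = _shape.shape_features(mask, spacing)
        out.update({f"shape_{k}": v for k, v in sh.items()})

    intensity_cats = [c for c in cfg.categories if c != "shape"]
    if intensity_cats:
        sx, sy, sz = spacing
        voxel_volume = sx * sy * sz
        slice_axis = 0  # slices are the first array axis
        per_slice: List[Dict[str, float]] = []
        for k in range(image.shape[slice_axis]):
            m2d = mask[k]
            if not m2d.any():
                continue
            vals = image[k][m2d]
            disc_vals = discretize(vals, cfg.n_bins)
            disc2d = np.zeros(m2d.shape, dtype=int)
            disc2d[m2d] = disc_vals
            row: Dict[str, float] = {}
            if "firstorder" in cfg.categories:
                fo = _firstorder(vals, disc_vals, cfg.n_bins, voxel_volume)
                row.update({f"firstorder_{k2}": v for k2, v in fo.items()})
            for cat in intensity_cats:
                if cat == "firstorder":
                    continue
                feats = _TEXTURE_FUNCS[cat](disc2d)
                row.update({f"{cat}_{k2}": v for k2, v in feats.items()})
            per_slice.append(row)
        if not per_slice:
            raise DegenerateInputError("mask intersects no slice")
        names = per_slice[0].keys()
        with np.errstate(invalid="ignore"):
            for name in names:
                vals = np.array([r[name] for r in per_slice], dtype=float)
                good = ~np.isnan(vals)
                out[name] = float(vals[good].mean()) if good.any() else float("nan")

    return {name: out[name] for name in cfg.feature_names}


def extract_feature_table(
    scans: Sequence,
    masks_by_source: Mapping[str, Sequence[np.ndarray]],
    cfg: Optional[RadiomicsConfig] = None,
    window: bool = True,
) -> pd.DataFrame:
    """Extract features for every scan under every mask source.

    ``scans`` are :class:`~radstab.synthcohort.ScanRecord` objects;
    ``masks_by_source`` maps a source label (``"GT"``, ``"MP"``,
    ``"CL_80"``, ...) to one mask per scan, aligned with ``scans``.  Each
    scan's image is windowed and preprocessed once; all mask sources are
    resampled to the same grid so that feature differences reflect masks
    only.  Returns a tidy DataFrame keyed by
    (subject_id, group, repeat_index, mask_source).
    """
    cfg = cfg or RadiomicsConfig()
    rows = []
    for i, scan in enumerate(scans):
        img = intensity_window(scan.image) if window else scan.image
        same = np.allclose(scan.spacing, cfg.target_spacing, rtol=0, atol=1e-9)
        # the image is resampled and standardized once per scan; every mask
        # source is then resampled to that same grid
        if not same:
            interp = (
                sitk.sitkBSpline if cfg.interpolator == "bspline" else sitk.sitkLinear
            )
            img = _resample(img, scan.spacing, cfg.target_spacing, interp)
        if cfg.normalization:
            sd = img.std()
            if sd == 0:
                raise DegenerateInputError("constant image cannot be z-scored")
            img = (img - img.mean()) / sd
        for source, masks in masks_by_source.items():
            mask = np.asarray(masks[i]).astype(bool)
            if not same:
                mask = (
                    _resample(mask.astype(np.uint8), scan.spacing,
                              cfg.target_spacing, sitk.sitkNearestNeighbor)
                    > 0
                )
            if not mask.any():
                continue  # empty masks yield no row (recorded as missing)
            feats = extract_features(img, mask, cfg, cfg.target_spacing)
            rows.append(
                {
                    "subject_id": scan.subject_id,
                    "group": scan.group,
                    "repeat_index": scan.repeat_index,
                    "mask_source": source,
                    **feats,
                }
            )
    return pd.DataFrame(rows)
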