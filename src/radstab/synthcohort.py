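"""Synthetic scan–rescan cohort generator.

Emulates the statistical structure the stability analysis assumes, without
any real MRI data or trained network:

* two subject groups (``CKD`` vs ``HC``) whose "kidneys" (two textured
  ellipsoids per subject) differ in mean volume and in texture-noise
  amplitude by configurable relative effects;
* ``n_repeats`` repeat acquisitions per subject that share the anatomy but
  differ by a rigid in-plane repositioning (shift + small rotation) and an
  independent intensity-noise draw — the scan–rescan condition;
* for each scan, T stochastic segmentation replicates: probability maps
  that are a sigmoid of the signed distance to the (possibly bias-shifted)
  ground-truth boundary, each replicate perturbed by a smooth random
  displacement field.  A ``calibration`` knob controls whether uncertainty
  concentrates where the replicates actually disagree with ground truth
  (calibration = 1) or is partly wasted on patches placed away from true
  errors (calibration < 1), so that well- and poorly-calibrated model
  behaviours can both be imitated.

Masks are evaluated analytically from the transformed ellipsoids, so they
are exactly binary on every repeat; images are resampled from a per-subject
canonical volume with linear interpolation, mimicking repositioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import ParameterError
from .uncmask import ProbStack

__all__ = [
    "CohortParams",
    "ModelProfile",
    "ScanRecord",
    "simulate_cohort",
    "simulate_prob_stack",
    "signed_distance",
    "PROFILES",
]

GROUPS = ("CKD", "HC")


@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters of a synthetic cohort.

    ``volume_effect`` is the relative shift of mean object volume in the CKD
    group versus HC (−0.2 → CKD kidneys 20% smaller on average);
    ``texture_effect`` is the relative shift of interior texture-noise
    amplitude.  ``reposition_sigma`` is the SD in mm of the rigid in-plane
    shift between repeats (the same number is used as the SD in degrees of
    the in-plane rotation).  ``noise_sigma`` is the SD of additive
    acquisition noise in arbitrary intensity units (images span roughly
    0–160 units).
    """

    n_per_group: int = 5
    n_repeats: int = 5
    grid_shape: Tuple[int, int, int] = (12, 64, 64)
    spacing: Tuple[float, float, float] = (1.458, 1.458, 5.5)  # (x, y, z) mm
    volume_effect: float = -0.2
    texture_effect: float = 0.5
    reposition_sigma: float = 3.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        object.__setattr__(self, "spacing", tuple(self.spacing))
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.n_repeats < 2:
            raise ParameterError("n_repeats must be >= 2")
        if self.reposition_sigma < 0 or self.noise_sigma < 0:
            raise ParameterError("sigmas must be >= 0")
        if any(s <= 0 for s in self.spacing) or any(n < 4 for n in self.grid_shape):
            raise ParameterError("invalid grid_shape or spacing")


@dataclass(frozen=True)
class ModelProfile:
    """Behaviour of the emulated stochastic segmentation model.

    ``band_width``: spatial width (mm) of the uncertain boundary band.
    ``replicate_jitter``: SD (mm) of the smooth per-replicate boundary
    displacement (drives epistemic spread).
    ``calibration`` ∈ [0, 1]: 1 → uncertainty sits where replicates disagree
    with ground truth; 0 → a large share of the uncertainty budget is spent
    on patches away from true errors.
    ``bias``: systematic over- (+) / under- (−) segmentation offset in mm.
    """

    band_width: float = 3.0
    replicate_jitter: float = 1.0
    calibration: float = 1.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.band_width <= 0:
            raise ParameterError("band_width must be > 0")
        if self.replicate_jitter < 0:
            raise ParameterError("replicate_jitter must be >= 0")
        if not 0.0 <= self.calibration <= 1.0:
            raise ParameterError("calibration must lie in [0, 1]")


#: Named profiles imitating the qualitative behaviours of the four
#: stochastic segmentation set-ups contrasted in the study design:
#: narrow risk-taking uncertainty (mcd-like), broader uncertainty
#: (tta-like), and their better-calibrated "plus" variants.
PROFILES: Dict[str, ModelProfile] = {
    "mcd-like": ModelProfile(band_width=2.5, replicate_jitter=1.5, calibration=0.3),
    "tta-like": ModelProfile(band_width=5.0, replicate_jitter=2.5, calibration=0.6),
    "mcd-plus-like": ModelProfile(band_width=3.0, replicate_jitter=1.8, calibration=1.0),
    "tta-plus-like": ModelProfile(band_width=6.0, replicate_jitter=2.5, calibration=0.9),
}


@dataclass(frozen=True)
class ScanRecord:
    """One acquisition: intensity volume plus ground-truth mask."""

    subject_id: str
    group: str
    repeat_index: int  # 1-based
    image: np.ndarray  # (slices, H, W) float
    gt_mask: np.ndarray  # (slices, H, W) bool
    spacing: Tuple[float, float, float]  # (x, y, z) mm

    def __post_init__(self) -> None:
        if self.image.shape != self.gt_mask.shape:
            raise ParameterError("image and gt_mask must share the grid")
        if not self.gt_mask.any():
            raise ParameterError("gt_mask must be nonempty")


# --------------------------------------------------------------------------
# geometry helpers

def _world_coords(grid_shape, spacing):
    """Physical (z, y, x) mm coordinates of every voxel centre."""
    s, h, w = grid_shape
    sx, sy, sz = spacing
    z = np.arange(s) * sz
    y = np.arange(h) * sy
    x = np.arange(w) * sx
    return np.meshgrid(z, y, x, indexing="ij")


@dataclass(frozen=True)
class _Ellipsoid:
    center: np.ndarray  # (z, y, x) mm
    axes: np.ndarray  # semi-axes (z, y, x) mm
    phi: float  # in-plane orientation, radians

    def inside(self, zz, yy, xx):
        dz = zz - self.center[0]
        dy = yy - self.center[1]
        dx = xx - self.center[2]
        c, s = np.cos(self.phi), np.sin(self.phi)
        ry = c * dy + s * dx
        rx = -s * dy + c * dx
        q = (dz / self.axes[0]) ** 2 + (ry / self.axes[1]) ** 2 + (rx / self.axes[2]) ** 2
        return q <= 1.0


@dataclass(frozen=True)
class _SubjectAnatomy:
    ellipsoids: Tuple[_Ellipsoid, ...]
    canonical_image: np.ndarray
    texture_amp: float


def _make_anatomy(params: CohortParams, group: str, rng: np.random.Generator) -> _SubjectAnatomy:
    s, h, w = params.grid_shape
    sx, sy, sz = params.spacing
    extent = np.array([s * sz, h * sy, w * sx])  # (z, y, x) mm

    vol_scale = 1.0 + (params.volume_effect if group == "CKD" else 0.0)
    tex_scale = 1.0 + (params.texture_effect if group == "CKD" else 0.0)
    axis_scale = vol_scale ** (1.0 / 3.0)

    # two laterally placed ellipsoids ("kidneys"); per-subject random axes
    base_axes = np.array([0.30 * extent[0], 0.28 * extent[1], 0.14 * extent[2]])
    ellipsoids = []
    for side in (-1.0, 1.0):
        jitter = rng.uniform(0.95, 1.05, size=3)
        axes = base_axes * jitter * axis_scale
        center = np.array(
            [
                0.5 * extent[0] + rng.normal(0.0, 0.02 * extent[0]),
                0.5 * extent[1] + rng.normal(0.0, 0.03 * extent[1]),
                0.5 * extent[2] + side * 0.24 * extent[2] + rng.normal(0.0, 0.02 * extent[2]),
            ]
        )
        phi = rng.normal(0.0, np.deg2rad(8.0))
        ellipsoids.append(_Ellipsoid(center=center, axes=axes, phi=phi))

    zz, yy, xx = _world_coords(params.grid_shape, params.spacing)
    mask = np.zeros(params.grid_shape, dtype=bool)
    for e in ellipsoids:
        mask |= e.inside(zz, yy, xx)

    # canonical intensities: dim background, brighter organ with a
    # low-frequency gradient plus band-limited texture noise
    texture_amp = 12.0 * tex_scale
    background = 30.0 + 3.0 * rng.standard_normal(params.grid_shape)
    grad = 25.0 * (yy / max(extent[1], 1e-9))  # smooth intensity drift
    tex = rng.standard_normal(params.grid_shape)
    tex = ndimage.gaussian_filter(tex, sigma=(0.6, 1.4, 1.4))
    tex_sd = tex.std()
    if tex_sd > 0:
        tex = tex / tex_sd
    interior = 120.0 + grad + texture_amp * tex
    image = np.where(mask, interior, background)
    return _SubjectAnatomy(
        ellipsoids=tuple(ellipsoids), canonical_image=image, texture_amp=texture_amp
    )


def _rigid_repeat(
    anatomy: _SubjectAnatomy,
    params: CohortParams,
    rng: np.random.Generator,
):
    """Apply one rigid repositioning (3-D shift + in-plane rotation);
    returns (image, mask).  The through-plane shift matters most with
    thick slices: it changes which slices cut the object, the dominant
    scan–rescan effect in this geometry."""
    sx, sy, sz = params.spacing
    if params.reposition_sigma > 0:
        dz, dy, dx = rng.normal(0.0, params.reposition_sigma, size=3)  # mm
        theta = np.deg2rad(rng.normal(0.0, params.reposition_sigma))
    else:
        dz = dy = dx = theta = 0.0

    zz, yy, xx = _world_coords(params.grid_shape, params.spacing)
    c, s = np.cos(theta), np.sin(theta)
    cy = 0.5 * params.grid_shape[1] * sy
    cx = 0.5 * params.grid_shape[2] * sx
    # world point -> canonical frame: undo shift, then rotation about centre
    qz = zz - dz
    py = yy - dy - cy
    px = xx - dx - cx
    qy = c * py + s * px + cy
    qx = -s * py + c * px + cx

    identity = dz == 0.0 and dy == 0.0 and dx == 0.0 and theta == 0.0
    if identity:
        image = anatomy.canonical_image.copy()
    else:
        coords = np.stack([qz / sz, qy / sy, qx / sx])
        image = ndimage.map_coordinates(
            anatomy.canonical_image, coords, order=1, mode="nearest"
        )
    mask = np.zeros(params.grid_shape, dtype=bool)
    for e in anatomy.ellipsoids:
        mask |= e.inside(qz, qy, qx)

    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)
    return image, mask


def simulate_cohort(params: CohortParams) -> List[ScanRecord]:
    """Generate ``2 × n_per_group × n_repeats`` scan records.

    Deterministic given ``params.seed``: the same parameters yield a
    bit-identical cohort.
    """
    root = np.random.SeedSequence(params.seed)
    records: List[ScanRecord] = []
    subj_seeds = root.spawn(2 * params.n_per_group)
    idx = 0
    for group in GROUPS:
        for j in range(params.n_per_group):
            subject_id = f"{group}{j + 1:02d}"
            ss = subj_seeds[idx]
            idx += 1
            anat_rng = np.random.default_rng(ss.spawn(1)[0])
            anatomy = _make_anatomy(params, group, anat_rng)
            rep_seeds = ss.spawn(params.n_repeats)
            for r in range(params.n_repeats):
                rep_rng = np.random.default_rng(rep_seeds[r])
                image, mask = _rigid_repeat(anatomy, params, rep_rng)
                records.append(
                    ScanRecord(
                        subject_id=subject_id,
                        group=group,
                        repeat_index=r + 1,
                        image=image,
                        gt_mask=mask,
                        spacing=params.spacing,
                    )
                )
    return records


# --------------------------------------------------------------------------
# stochastic segmentation replicates

def signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary in mm (< 0 inside).

    The voxel-to-voxel EDT measures distance between voxel *centres*, so the
    first layer on either side of the boundary would sit a full voxel away;
    half the finest voxel pitch is subtracted to place the boundary between
    the two layers, giving sub-voxel distances at the interface.
    """
    sx, sy, sz = spacing
    sampling = (sz, sy, sx)  # arrays are (slices=z, H=y, W=x)
    mask = mask.astype(bool)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    d = outside - inside
    half = 0.5 * min(spacing)
    return d - np.sign(d) * half


def _smooth_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Unit-RMS Gaussian random field with ~corr_mm correlation length."""
    sx, sy, sz = spacing
    sigma_vox = (corr_mm / sz, corr_mm / sy, corr_mm / sx)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    rms = np.sqrt(np.mean(f**2))
    return f / rms if rms > 0 else f


def simulate_prob_stack(
    record: ScanRecord,
    profile: ModelProfile,
    T: int = 50,
    seed: int = 0,
) -> ProbStack:
    """Emulate T stochastic segmentation replicates for one scan.

    Each replicate's probability map is ``sigmoid(−(d + bias + δ_t)/s)``
    where ``d`` is the signed distance to the ground-truth boundary,
    ``δ_t`` a smooth zero-mean displacement field with RMS
    ``replicate_jitter`` (mm) and ``s = band_width / 4`` (so probabilities
    run from ≈0.02 to ≈0.98 across one band width).  With
    ``calibration < 1``, additional uncertainty patches are blended in at
    locations away from the boundary — i.e. away from where replicates can
    actually err — degrading the error/uncertainty correspondence without
    changing the dominant classification.
    """
    if T < 2:
        raise ParameterError(f"T must be >= 2, got {T}")
    rng = np.random.default_rng(seed)  # int or SeedSequence
    d = signed_distance(record.gt_mask, record.spacing)
    scale = profile.band_width / 4.0

    # miscalibration patches: fixed per scan, away from the uncertain band
    n_patch = int(round(6.0 * (1.0 - profile.calibration)))
    patch_w = np.zeros_like(d)
    if n_patch > 0:
        far = np.abs(d + profile.bias) > profile.band_width
        cand = np.argwhere(far)
        if len(cand):
            pick = cand[rng.integers(0, len(cand), size=n_patch)]
            zz, yy, xx = np.meshgrid(
                np.arange(d.shape[0]) * record.spacing[2],
                np.arange(d.shape[1]) * record.spacing[1],
                np.arange(d.shape[2]) * record.spacing[0],
                indexing="ij",
            )
            radius = 2.0 * profile.band_width
            for p in pick:
                pz = p[0] * record.spacing[2]
                py = p[1] * record.spacing[1]
                px = p[2] * record.spacing[0]
                r2 = (zz - pz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2
                patch_w = np.maximum(patch_w, np.exp(-r2 / (2.0 * radius**2)))

    gt = record.gt_mask
    maps = np.empty((T,) + record.gt_mask.shape, dtype=float)
    for t in range(T):
        if profile.replicate_jitter > 0:
            delta = profile.replicate_jitter * _smooth_field(
                d.shape, record.spacing, corr_mm=6.0, rng=rng
            )
        else:
            delta = 0.0
        p = expit(-(d + profile.bias + delta) / scale)
        if n_patch > 0:
            # mostly-correct but noisy probabilities: high aleatoric
            # uncertainty decoupled from actual error locations
            q = np.where(gt, 0.7, 0.3) + rng.normal(0.0, 0.1, size=p.shape)
            q = np.clip(q, 0.02, 0.98)
            p = (1.0 - patch_w) * p + patch_w * q
        maps[t] = np.clip(p, 0.0, 1.0)
    return ProbStack(maps)
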