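"""Segmentation-uncertainty core.

Given a stack of T per-voxel probability maps produced by a stochastic
segmentation model (Monte-Carlo dropout replicates, test-time-augmentation
replicates, or a simulator emulating them), this module computes:

* the voxelwise mean prediction ``p̄_i = (1/T) Σ_t p_it`` and its binarized
  mean-prediction (MP) mask;
* the decomposition of predictive uncertainty into aleatoric and epistemic
  parts,

  ``U_i^(pred) = U_i^(aleat) + U_i^(epist)
              = (1/T) Σ_t p_it (1 − p_it)  +  (1/T) Σ_t (p_it − p̄_i)²``;

* confidence-level masks ``CL_th``: the region of voxels labelled foreground
  by at least ``th`` percent of the T replicates;
* soft Dice and "Dice Plus" losses (the focal-exponent variant that
  penalizes overconfident false positives/negatives and improves model
  calibration), the hard Dice overlap score, and a KL-divergence metric that
  measures how well predictive uncertainty separates misclassified from
  correctly classified voxels.

Note the exact identity ``U^(pred) = p̄ (1 − p̄)`` which follows
algebraically from the decomposition above; it is used as a self-check in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

import numpy as np

from .errors import InputError, ParameterError, UndefinedDivergenceError

__all__ = [
    "ProbStack",
    "MeanPrediction",
    "UncertaintyMaps",
    "ConfidenceMaskSet",
    "mean_prediction",
    "uncertainty_decompose",
    "confidence_masks",
    "dice_score",
    "dice_loss",
    "dice_plus_loss",
    "histogram_kl",
    "kl_uncertainty_separability",
    "DEFAULT_THRESHOLDS",
]

#: Confidence levels scanned by default, in percent.
DEFAULT_THRESHOLDS: tuple = tuple(range(10, 101, 10))

#: Additive smoothing constant for the soft-Dice losses (defines the
#: all-empty limit as zero loss).
DICE_EPS = 1e-6


@dataclass(frozen=True)
class ProbStack:
    """T replicate probability maps for one scan, shape ``(T, *grid)``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim < 2:
            raise InputError("ProbStack needs shape (T, *grid)")
        if v.shape[0] < 2:
            raise InputError(f"ProbStack needs T >= 2 replicates, got {v.shape[0]}")
        if np.isnan(v).any() or v.min() < 0.0 or v.max() > 1.0:
            raise InputError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[1:]


@dataclass(frozen=True)
class MeanPrediction:
    """Voxelwise mean probability and the binarized MP mask."""

    pbar: np.ndarray
    mp_mask: np.ndarray
    binarize_at: float = 0.5


@dataclass(frozen=True)
class UncertaintyMaps:
    """Voxelwise aleatoric, epistemic and predictive uncertainty."""

    aleatoric: np.ndarray
    epistemic: np.ndarray
    predictive: np.ndarray


@dataclass(frozen=True)
class ConfidenceMaskSet:
    """CL_th masks keyed by confidence level th (percent) plus the per-voxel
    fraction of replicates voting foreground.  Masks are nested:
    ``CL_th2 ⊆ CL_th1`` whenever ``th1 < th2``."""

    masks: Dict[float, np.ndarray]
    vote_fraction: np.ndarray
    classify_at: float = 0.5

    def __getitem__(self, th: float) -> np.ndarray:
        return self.masks[th]

    @property
    def thresholds(self) -> tuple:
        return tuple(sorted(self.masks))


def _as_stack(stack) -> ProbStack:
    if isinstance(stack, ProbStack):
        return stack
    return ProbStack(np.asarray(stack, dtype=float))


def mean_prediction(stack, binarize_at: float = 0.5) -> MeanPrediction:
    """Average the T replicate probabilities voxelwise and binarize.

    The tie ``p̄ == binarize_at`` maps to foreground (deterministic
    convention).
    """
    stack = _as_stack(stack)
    pbar = stack.values.mean(axis=0)
    return MeanPrediction(pbar=pbar, mp_mask=pbar >= binarize_at, binarize_at=binarize_at)


def uncertainty_decompose(stack) -> UncertaintyMaps:
    """Split predictive uncertainty into aleatoric and epistemic parts.

    Aleatoric: mean of the per-replicate Bernoulli variances p(1−p).
    Epistemic: population (1/T) variance of the replicate probabilities.
    Predictive: their sum, which equals p̄(1−p̄) exactly.
    """
    stack = _as_stack(stack)
    p = stack.values
    pbar = p.mean(axis=0)
    aleatoric = np.mean(p * (1.0 - p), axis=0)
    epistemic = np.mean((p - pbar) ** 2, axis=0)
    return UncertaintyMaps(
        aleatoric=aleatoric, epistemic=epistemic, predictive=aleatoric + epistemic
    )


def confidence_masks(
    stack,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    classify_at: float = 0.5,
) -> ConfidenceMaskSet:
    """Build CL_th masks from classified replicates.

    Each replicate is binarized at ``classify_at`` first; a voxel belongs to
    ``CL_th`` iff it is foreground in at least ``th`` percent of the T
    replicates (inclusive: with T = 50, 5 foreground votes put a voxel in
    CL_10 but not CL_20).
    """
    stack = _as_stack(stack)
    thresholds = tuple(float(t) for t in thresholds)
    for th in thresholds:
        if not 0.0 < th <= 100.0:
            raise ParameterError(f"confidence level must lie in (0, 100], got {th}")
    votes = (stack.values >= classify_at).sum(axis=0)
    frac = votes / stack.T
    masks = {th: (100.0 * votes) >= (th * stack.T) for th in thresholds}
    return ConfidenceMaskSet(masks=masks, vote_fraction=frac, classify_at=classify_at)


def dice_score(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Hard Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(gt_mask).astype(bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _check_probs(pred_prob: np.ndarray, gt: np.ndarray):
    p = np.asarray(pred_prob, dtype=float)
    y = np.asarray(gt, dtype=float)
    if p.shape != y.shape:
        raise InputError(f"grid shapes differ: {p.shape} vs {y.shape}")
    if p.min() < 0.0 or p.max() > 1.0:
        raise InputError("predicted probabilities must lie in [0, 1]")
    return p.ravel(), y.ravel()


def dice_loss(pred_prob: np.ndarray, gt: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss ``1 − 2Σpy / (Σp + Σy)`` with additive smoothing."""
    p, y = _check_probs(pred_prob, gt)
    inter = float(p @ y)
    return 1.0 - (2.0 * inter + eps) / (p.sum() + y.sum() + eps)


def dice_plus_loss(
    pred_prob: np.ndarray, gt: np.ndarray, gamma: float = 2.0, eps: float = DICE_EPS
) -> float:
    """Soft Dice loss with focal exponent γ on the error terms.

    ``1 − 2Σpy / (2Σpy + Σ[p(1−y)]^γ + Σ[(1−p)y]^γ)``; for γ = 1 the
    denominator collapses to Σp + Σy and the loss reduces to :func:`dice_loss`.
    """
    if gamma <= 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    p, y = _check_probs(pred_prob, gt)
    inter = float(p @ y)
    fp = float(np.sum((p * (1.0 - y)) ** gamma))
    fn = float(np.sum(((1.0 - p) * y) ** gamma))
    return 1.0 - (2.0 * inter + eps) / (2.0 * inter + fp + fn + eps)


def histogram_kl(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P‖Q) in nats between two discrete distributions on shared bins."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputError("histograms must share bin edges")
    p = p / p.sum()
    q = q / q.sum()
    nz = p > 0
    if np.any(q[nz] == 0):
        raise InputError("KL undefined: q has empty bins where p has mass")
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def kl_uncertainty_separability(
    predictive: np.ndarray,
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    n_bins: int = 20,
) -> float:
    """KL divergence between uncertainty distributions of wrong vs right voxels.

    Predictive-uncertainty values are split by whether the predicted mask
    agrees with ground truth at that voxel; each group's distribution is a
    normalized histogram over shared bin edges spanning the pooled range,
    with one count of additive (Laplace) smoothing per bin.  Returns
    KL(incorrect ‖ correct) in nats; large values mean the model is more
    uncertain exactly where it is wrong.
    """
    u = np.asarray(predictive, dtype=float).ravel()
    pm = np.asarray(pred_mask).astype(bool).ravel()
    gm = np.asarray(gt_mask).astype(bool).ravel()
    if not (u.shape == pm.shape == gm.shape):
        raise InputError("predictive map and masks must share the grid")
    wrong = pm != gm
    if not wrong.any():
        raise UndefinedDivergenceError("no misclassified voxels: KL separability undefined")
    if wrong.all():
        raise UndefinedDivergenceError("no correctly classified voxels: KL separability undefined")
    lo, hi = u.min(), u.max()
    if hi <= lo:  # all uncertainties equal: identical one-bin histograms
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h_wrong, _ = np.histogram(u[wrong], bins=edges)
    h_right, _ = np.histogram(u[~wrong], bins=edges)
    return histogram_kl(h_wrong + 1.0, h_right + 1.0)
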