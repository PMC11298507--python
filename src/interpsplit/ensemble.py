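"""Pluggable 2D segmenter backends, prediction workflow and mask ensembling.

A backend maps one normalized tile to a same-shape probability map in
[0, 1].  Prediction runs per slice: bilinear up-sample by ``ir``, split into
tiles, predict each tile, merge, nearest-neighbour down-sample back to
source resolution.  The ensemble binarizes each ratio's prediction, takes
the voxelwise union over ratios, and keeps the largest 3D connected
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from . import metrics
from .tiling import TileSet, reconstruct_prediction, split_tiles, upsample_image

__all__ = [
    "SegmenterBackend",
    "EnsembleConfig",
    "TrainingConfig",
    "NNUNET_TRAINING_DEFAULTS",
    "threshold_opening_backend",
    "trainable_backend",
    "predict_volume",
    "binarize",
    "ensemble_union",
    "largest_connected_component",
    "run_interpolation_split",
    "EnsembleResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmenterBackend:
    """Contract: ``predict`` maps a T x T tile to probabilities in [0, 1]."""

    name: str
    predict: Callable[[np.ndarray], np.ndarray]
    deterministic: bool = True


@dataclass(frozen=True)
class EnsembleConfig:
    irs: tuple[int, ...] = (1, 2, 4, 8)
    binarize_threshold: float = 0.5
    connectivity: int = 26
    tile_size: int = 512

    def __post_init__(self) -> None:
        if not self.irs:
            raise ValueError("irs must be nonempty")
        if any(ir < 1 for ir in self.irs):
            raise ValueError(f"every ir must be >= 1, got {self.irs}")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError(
                f"binarize_threshold must lie in (0, 1), got {self.binarize_threshold}"
            )
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.tile_size < 8:
            raise ValueError(f"tile_size must be >= 8, got {self.tile_size}")


# Recorded defaults of the two training recipes used with this pipeline:
# nnU-Net style (SGD + Nesterov, poly LR schedule) and the Adam recipe
# mirrored by TrainingConfig below.
NNUNET_TRAINING_DEFAULTS = {
    "optimizer": "sgd-nesterov",
    "momentum": 0.99,
    "learning_rate": 0.01,
    "lr_schedule": "poly",
    "epochs": 1000,
    "minibatches_per_epoch": 250,
}


@dataclass(frozen=True)
class TrainingConfig:
    """Adam training recipe (plateau LR decay + early stopping)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 200
    reduce_lr_factor: float = 0.1
    reduce_lr_patience: int = 3
    min_lr: float = 1e-5
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


def threshold_opening_backend(tau: float, opening_radius: int) -> SegmenterBackend:
    """Deterministic scale-sensitive backend: threshold dark voxels, open.

    The probability map is the morphological opening (disk of the given
    radius) of ``image < tau``, cast to {0, 1}.  Structures narrower than
    the structuring element vanish, so a branch invisible at ir=1 becomes
    detectable once magnification widens it past the element's diameter.
    """
    if not 0.0 <= tau <= 255.0:
        raise ValueError(f"tau must lie in [0, 255], got {tau}")
    if opening_radius < 0:
        raise ValueError(f"opening_radius must be >= 0, got {opening_radius}")
    footprint = disk(opening_radius) if opening_radius > 0 else None

    def predict(tile: np.ndarray) -> np.ndarray:
        binary = np.asarray(tile) < tau
        if footprint is not None:
            binary = ndi.binary_opening(binary, structure=footprint)
        return binary.astype(np.float64)

    return SegmenterBackend(
        name=f"threshold-opening(tau={tau},r={opening_radius})",
        predict=predict,
        deterministic=True,
    )


def _tile_features(tile: np.ndarray) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    x = np.asarray(tile, dtype=np.float64) / 255.0
    feats = [
        np.ones_like(x),
        x,
        gaussian_filter(x, 1.0),
        gaussian_filter(x, 2.0),
        gaussian_filter(x, 4.0),
        x * x,
    ]
    return np.stack([f.ravel() for f in feats], axis=1)


def trainable_backend(
    train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig = TrainingConfig(),
    checkpoint_path=None,
) -> SegmenterBackend:
    """Train a small per-pixel logistic segmenter on (image, mask) tile pairs.

    A reference trainable backend that honours the contract without any deep
    learning framework: per-pixel logistic regression on multi-scale
    intensity features, optimised with Adam on the 0.5*BCE + 0.5*Dice-loss
    objective, with plateau LR decay and early stopping per the config.
    Seeded and deterministic.  Returns the trained backend; training-history
    is attached as ``predict.history``.
    """
    pairs = list(train_pairs)
    if not pairs:
        raise ValueError("empty training set")
    X = np.concatenate([_tile_features(img) for img, _ in pairs], axis=0)
    y = np.concatenate([np.asarray(m, dtype=np.float64).ravel() for _, m in pairs])
    # standardize non-constant features for optimisation conditioning
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0  # keep the bias column
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    rng = np.random.default_rng(config.seed)
    w = rng.normal(0.0, 0.01, size=X.shape[1])

    m_t = np.zeros_like(w)
    v_t = np.zeros_like(w)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    best_loss, best_w = np.inf, w.copy()
    plateau = stall = 0
    history: list[float] = []
    n = y.size
    for epoch in range(config.epochs):
        z = X @ w
        p = 1.0 / (1.0 + np.exp(-z))
        loss = metrics.combined_loss(y, np.clip(p, 0.0, 1.0))
        history.append(loss)
        if loss < best_loss - 1e-9:
            best_loss, best_w = loss, w.copy()
            plateau = stall = 0
        else:
            plateau += 1
            stall += 1
        if stall >= config.early_stopping_patience:
            break
        if plateau >= config.reduce_lr_patience:
            lr = max(lr * config.reduce_lr_factor, config.min_lr)
            plateau = 0
        # gradient of 0.5*BCE + 0.5*(1 - soft Dice) w.r.t. logits
        num = 2.0 * float(np.sum(y * p))
        den = float(np.sum(y) + np.sum(p))
        if den > 0:
            g_dice = -(2.0 * y * den - num) / (den * den)
        else:
            g_dice = np.zeros_like(p)
        g_z = 0.5 * (p - y) / n + 0.5 * g_dice * p * (1.0 - p)
        grad = X.T @ g_z
        m_t = beta1 * m_t + (1 - beta1) * grad
        v_t = beta2 * v_t + (1 - beta2) * grad * grad
        mhat = m_t / (1 - beta1 ** (epoch + 1))
        vhat = v_t / (1 - beta2 ** (epoch + 1))
        w = w - lr * mhat / (np.sqrt(vhat) + adam_eps)

    w = best_w
    if checkpoint_path is not None:
        np.savez(checkpoint_path, weights=w, best_loss=best_loss)

    def predict(tile: np.ndarray) -> np.ndarray:
        F = (_tile_features(tile) - mu) / sd
        p = 1.0 / (1.0 + np.exp(-(F @ w)))
        return p.reshape(np.asarray(tile).shape)

    predict.history = history  # type: ignore[attr-defined]
    predict.best_loss = best_loss  # type: ignore[attr-defined]
    return SegmenterBackend(name="logistic-trainable", predict=predict, deterministic=True)


def predict_volume(
    volume: np.ndarray,
    backend: SegmenterBackend,
    ir: int,
    tile_size: int,
) -> np.ndarray:
    """Run the tile-level backend over every axial slice at one ratio.

    ``volume`` is a normalized (axial, row, col) array in [0, 255]; the
    result is a probability volume at source resolution.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    out = np.empty(volume.shape, dtype=np.float64)
    for k in range(volume.shape[0]):
        up = upsample_image(volume[k], ir)
        ts = split_tiles(up, tile_size, ir=ir, slice_index=k)
        preds = []
        for i, tile in enumerate(ts.tiles):
            p = np.asarray(backend.predict(tile), dtype=np.float64)
            if p.shape != tile.shape:
                raise ValueError(
                    f"backend output shape {p.shape} != tile shape {tile.shape}"
                )
            if p.min() < 0.0 or p.max() > 1.0:
                raise ValueError(f"backend output outside [0, 1] on tile {i}")
            preds.append(p)
        out[k] = reconstruct_prediction(TileSet(preds, ts.grid, slice_index=k), ir)
    return out


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict thresholding: foreground iff probability > threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(prob) > threshold).astype(np.uint8)


def ensemble_union(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise logical OR of binary masks."""
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("no masks to union")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError(f"shape mismatch among masks: {[m.shape for m in masks]}")
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        out |= m.astype(bool)
    return out.astype(np.uint8)


def _structure(connectivity: int, ndim: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity] if ndim == 3 else {6: 1, 18: 2, 26: 2}[connectivity]
    return ndi.generate_binary_structure(ndim, rank)


def largest_connected_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component.

    Size ties are broken deterministically by the smallest raster-order
    (lexicographic) seed voxel.  An empty input returns an empty mask with a
    logged warning.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndi.label(mask, structure=_structure(connectivity, mask.ndim))
    if n == 0:
        log.warning("largest_connected_component: input mask is empty")
        return np.zeros_like(mask, dtype=np.uint8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    max_size = sizes.max()
    candidates = np.flatnonzero(sizes == max_size)
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first = np.flatnonzero(np.isin(flat, candidates))[0]
        keep = flat[first]
    return (labels == keep).astype(np.uint8)


@dataclass
class EnsembleResult:
    """Per-ratio masks and (optionally) DSC bookkeeping for one case."""

    final_mask: np.ndarray
    per_ir_masks: dict[int, np.ndarray]
    union_mask: np.ndarray
    case_result: "metrics.CaseResult | None" = None


def run_interpolation_split(
    volume: np.ndarray,
    backend: SegmenterBackend,
    config: EnsembleConfig = EnsembleConfig(),
    gt_mask: np.ndarray | None = None,
    case_id: str = "case",
) -> EnsembleResult:
    """Full pipeline: per-ratio predict + binarize, union, largest component.

    When a ground-truth mask is supplied, the result carries per-ratio DSC,
    the ensemble DSC and gains over the smallest-ratio baseline (percent).
    """
    per_ir: dict[int, np.ndarray] = {}
    for ir in config.irs:
        prob = predict_volume(volume, backend, ir, config.tile_size)
        per_ir[ir] = binarize(prob, config.binarize_threshold)
    union = ensemble_union(list(per_ir.values()))
    final = largest_connected_component(union, config.connectivity)

    case_result = None
    if gt_mask is not None:
        baseline_ir = min(config.irs)
        dsc_cfg = {
            f"ir{ir}": metrics.evaluate_case(
                largest_connected_component(m, config.connectivity), gt_mask
            )
            for ir, m in per_ir.items()
        }
        dsc_cfg["ensemble"] = metrics.evaluate_case(final, gt_mask)
        case_result = metrics.CaseResult(
            case_id=case_id,
            dsc_per_config=dsc_cfg,
            baseline_config=f"ir{baseline_ir}",
        )
    return EnsembleResult(
        final_mask=final, per_ir_masks=per_ir, union_mask=union, case_result=case_result
    )
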