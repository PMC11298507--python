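"""Segmentation losses and evaluation metrics.

Binary cross-entropy, Dice similarity coefficient (soft and binary), the
equal-weight combined loss used for training, volume-level case evaluation
in percent, performance gain, and mean +/- SD aggregation for nested
configuration subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabelPair",
    "CaseResult",
    "bce_loss",
    "dsc",
    "dsc_loss",
    "combined_loss",
    "evaluate_case",
    "performance_gain",
    "ablation_summary",
    "DEFAULT_EPS",
]

log = logging.getLogger(__name__)

DEFAULT_EPS = 1e-7


@dataclass
class LabelPair:
    """Ground-truth labels in {0,1} paired with predictions in [0,1]."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64)
        if self.y.shape != self.y_hat.shape:
            raise ValueError(f"shape mismatch: y {self.y.shape} vs y_hat {self.y_hat.shape}")
        if self.y.size < 1:
            raise ValueError("empty label pair")
        if not np.isin(np.unique(self.y), (0.0, 1.0)).all():
            raise ValueError("ground truth must be binary")
        if np.min(self.y_hat) < 0.0 or np.max(self.y_hat) > 1.0:
            raise ValueError("predictions must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.y.size


def _as_arrays(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, LabelPair):
        return y.y, y.y_hat
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    return y, y_hat


def bce_loss(y, y_hat=None, eps: float = DEFAULT_EPS) -> float:
    """Mean binary cross-entropy; predictions are clamped to [eps, 1-eps]."""
    y, y_hat = _as_arrays(y, y_hat)
    p = np.clip(y_hat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dsc(y, y_hat=None) -> float:
    """Dice similarity coefficient, ``2*sum(y*y_hat) / (sum(y) + sum(y_hat))``.

    Soft predictions are allowed (the sum form); when both operands are
    empty the result is 1.0 by convention (perfect agreement on absence),
    with a logged notice so the convention can be audited.
    """
    y, y_hat = _as_arrays(y, y_hat)
    num = 2.0 * float(np.sum(y * y_hat))
    den = float(np.sum(y)) + float(np.sum(y_hat))
    if den == 0.0:
        log.warning("both masks empty; DSC defined as 1.0 by convention")
        return 1.0
    return num / den


def dsc_loss(y, y_hat=None) -> float:
    """``1 - DSC``."""
    return 1.0 - dsc(y, y_hat)


def combined_loss(y, y_hat=None, eps: float = DEFAULT_EPS) -> float:
    """Equal-weight sum: ``0.5 * BCE + 0.5 * (1 - DSC)``."""
    return 0.5 * bce_loss(y, y_hat, eps=eps) + 0.5 * dsc_loss(y, y_hat)


def evaluate_case(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Volume-level DSC in percent over all voxels of one case."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: pred {pred_mask.shape} vs gt {gt_mask.shape}")
    for name, m in (("pred_mask", pred_mask), ("gt_mask", gt_mask)):
        if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    return 100.0 * dsc(gt_mask.astype(np.float64), pred_mask.astype(np.float64))


def performance_gain(dsc_method: float, dsc_baseline: float) -> float:
    """Percentage-point difference, method minus baseline (may be negative)."""
    return dsc_method - dsc_baseline


@dataclass
class CaseResult:
    """Per-case DSC (%) across configurations plus gains over a baseline."""

    case_id: str
    dsc_per_config: dict[str, float] = field(default_factory=dict)
    baseline_config: str | None = None

    def gain(self, config: str) -> float:
        if self.baseline_config is None:
            raise ValueError("no baseline configuration recorded")
        return performance_gain(
            self.dsc_per_config[config], self.dsc_per_config[self.baseline_config]
        )

    def to_frame(self) -> pd.DataFrame:
        row: dict[str, float | str] = {"case": self.case_id}
        row.update(self.dsc_per_config)
        if self.baseline_config is not None:
            for cfg in self.dsc_per_config:
                if cfg != self.baseline_config:
                    row[f"gain_{cfg}"] = self.gain(cfg)
        return pd.DataFrame([row])


def ablation_summary(per_case_dsc: pd.DataFrame, ir_subsets: list[str]) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of per-case DSC for each subset column.

    ``per_case_dsc`` holds one row per case and one column per configuration
    subset; ``ir_subsets`` lists the columns in ascending subset size.  With
    a single case the SD is reported as NaN (not applicable).
    """
    if per_case_dsc.empty:
        raise ValueError("empty per-case table")
    missing = [c for c in ir_subsets if c not in per_case_dsc.columns]
    if missing:
        raise KeyError(f"unknown subset columns: {missing}")
    rows = []
    for col in ir_subsets:
        vals = per_case_dsc[col].to_numpy(dtype=np.float64)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append({"subset": col, "mean": float(vals.mean()), "sd": sd, "n": len(vals)})
    return pd.DataFrame(rows).set_index("subset")
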