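"""Weak-label masking: deriving incomplete observed matrices from full ones.

The weak-label ratio (W.L.R.) of a label column is the fraction of its true
positives retained in the observed matrix, ‖Ŷ·,l‖₁ / ‖Y·,l‖₁. Masking is
per column: each column keeps round(r·p) of its p positives (round half to
even), never fewer than ``min_keep`` so no label vanishes from training.
Observed zeros are unknowns, not negatives — masking only removes positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import LabelMatrix, check_weak_consistency


@dataclass(frozen=True)
class MaskingConfig:
    ratio: float
    seed: int = 0
    min_keep: int = 1

    def __post_init__(self):
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError(f"ratio must be in (0, 1], got {self.ratio}")
        if self.min_keep < 0:
            raise ValueError("min_keep must be >= 0")


def mask_labels(Y: LabelMatrix, cfg: MaskingConfig) -> LabelMatrix:
    """Mask a full matrix to the target weak-label ratio, per column.

    Column l with p_l positives keeps k_l = max(min_keep, round(r·p_l))
    positives chosen uniformly at random from the seeded generator.
    """
    if Y.role != "full":
        raise ValueError(f"masking expects a full matrix, got role={Y.role!r}")
    values = Y.values
    if np.any(values.sum(axis=0) == 0):
        raise ValueError("full matrix has a column with no positives")
    rng = np.random.default_rng(cfg.seed)
    out = np.zeros_like(values)
    for l in range(values.shape[1]):
        pos = np.flatnonzero(values[:, l])
        p = pos.size
        k = int(max(cfg.min_keep, np.round(cfg.ratio * p)))
        k = min(k, p)
        keep = rng.choice(pos, size=k, replace=False)
        out[keep, l] = 1
    return LabelMatrix(out, "observed")


def realized_wlr(Y_hat: LabelMatrix, Y: LabelMatrix):
    """Per-label realized weak-label ratios and their mean.

    Columns with zero positives in Y are undefined (NaN) and excluded from
    the mean. Returns ``(ratios, mean)``.
    """
    check_weak_consistency(Y_hat, Y)
    full_sums = Y.values.sum(axis=0).astype(float)
    obs_sums = Y_hat.values.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(full_sums > 0, obs_sums / full_sums, np.nan)
    defined = ratios[~np.isnan(ratios)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return ratios, mean
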