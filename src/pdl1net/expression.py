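"""Microarray validation stage: log transform, quantile normalization, and
fold-change computation on a probe×sample expression matrix.

The validation design mirrors an ALK-amplified neuroblastoma cell line
cultured in 2D and 3D and treated with DMSO or an ALK inhibitor
(crizotinib or alectinib): probes are log2-transformed, quantile-normalized
across samples, and the PD-L1 probe's fold *reduction* (control mean over
treated mean, on the linear scale) is compared between arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "log2_transform",
    "quantile_normalize",
    "fold_change",
]


@dataclass
class ExpressionMatrix:
    """Probe×sample expression values plus per-sample group labels.

    ``values``: DataFrame indexed by probe id, one column per sample.
    ``samples``: DataFrame indexed by sample id with ``culture`` (2D/3D) and
    ``treatment`` (DMSO/crizotinib/alectinib) columns, aligned with the
    value columns.  ``scale`` flags whether values are linear or log2.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        for col in ("culture", "treatment"):
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation lacks {col!r} column")
            if self.samples[col].isna().any():
                raise ValueError(f"missing {col!r} label")
        if self.scale == "linear" and (self.values.values < 0).any():
            raise ValueError("linear-scale matrix contains negative values")

    def group_columns(self, culture: str | None, treatment: str | None) -> list[str]:
        """Sample ids matching the given culture and/or treatment."""
        mask = pd.Series(True, index=self.samples.index)
        if culture is not None:
            mask &= self.samples["culture"] == culture
        if treatment is not None:
            mask &= self.samples["treatment"] == treatment
        keep = set(self.samples.index[mask])
        return [c for c in self.values.columns if c in keep]

    def linear_values(self) -> pd.DataFrame:
        return 2.0 ** self.values if self.scale == "log2" else self.values


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform a linear-scale matrix; flips the scale flag.

    Already-log2 input is returned unchanged with a warning.  Non-positive
    values cannot be logged and raise.
    """
    if m.scale == "log2":
        warnings.warn("matrix is already on the log2 scale; returning unchanged",
                      stacklevel=2)
        return replace(m, values=m.values.copy())
    if (m.values.values <= 0).any():
        raise ValueError("cannot log2-transform non-positive values")
    return replace(m, values=np.log2(m.values), scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column to share the same value distribution.

    Each column's sorted values are replaced by the row-wise means of the
    sorted columns; ties within a column receive the average of the quantile
    values they span (the standard convention).  Idempotent, and preserves
    within-column rank order.
    """
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    X = m.values.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        # average ranks for ties -> average of the tied quantile values
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(len(col))
        normalized = reference[ranks.astype(int)]
        # resolve ties: group equal input values, assign their mean quantile
        vals, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=normalized)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values)


def fold_change(
    m: ExpressionMatrix,
    probe: str | list[str],
    control: dict[str, str],
    treated: dict[str, str],
    summarize: str = "mean",
) -> float:
    """Fold *reduction* of a probe between two sample groups.

    Defined as mean linear-scale control over mean linear-scale treated
    (log2 matrices are de-logged first), so values > 1 mean the treatment
    lowered expression.  ``control``/``treated`` select samples by
    ``{"culture": ..., "treatment": ...}`` (either key may be omitted).
    Multiple probes (e.g. several probes mapping to PD-L1/CD274) are
    averaged after normalization.
    """
    probes = [probe] if isinstance(probe, str) else list(probe)
    missing = [p for p in probes if p not in m.values.index]
    if missing:
        raise KeyError(f"probe(s) not in matrix: {missing}")
    if summarize not in ("mean", "geometric"):
        raise ValueError(f"unknown summarizer {summarize!r}")

    ctrl_cols = m.group_columns(control.get("culture"), control.get("treatment"))
    trt_cols = m.group_columns(treated.get("culture"), treated.get("treatment"))
    if not ctrl_cols or not trt_cols:
        raise ValueError("control and treated groups must both be non-empty")

    linear = m.linear_values().loc[probes]
    if summarize == "mean":
        ctrl = float(linear[ctrl_cols].to_numpy().mean())
        trt = float(linear[trt_cols].to_numpy().mean())
    else:
        ctrl = float(np.exp(np.log(linear[ctrl_cols].to_numpy()).mean()))
        trt = float(np.exp(np.log(linear[trt_cols].to_numpy()).mean()))
    if trt == 0:
        raise ZeroDivisionError("treated group mean is zero")
    return ctrl / trt
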