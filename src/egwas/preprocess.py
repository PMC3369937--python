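"""Expression preprocessing: detection filtering, variance-stabilizing
transform, quantile normalization.

The raw chip-level steps (background correction, bead models) are out of
scope; a monotone ``log2(x + c)`` stands in for the model-based
variance-stabilizing transform, which is sufficient for the rank-preserving
statistics downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ExpressionMatrix

__all__ = ["detection_filter", "DetectionFilterResult", "vst", "quantile_normalize",
           "detection_from_pvalues"]


@dataclass
class DetectionFilterResult:
    expression: ExpressionMatrix
    n_kept: int
    n_dropped: int
    dropped_probes: pd.Index


def detection_filter(
    expr: ExpressionMatrix, threshold: float = 0.75
) -> DetectionFilterResult:
    """Keep probes detected in strictly more than ``threshold`` of samples.

    A probe with detectable signal in >75% of samples is regarded as
    informative (the default).  ``threshold=0`` bypasses the filter entirely,
    reproducing the unrestricted supplementary analyses.
    """
    if expr.values.size == 0:
        raise ValueError("cannot filter an empty expression matrix")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if threshold == 0.0:
        keep = pd.Series(True, index=expr.probes)
    else:
        keep = expr.detection_rate() > threshold
    kept = expr.subset_probes(expr.probes[keep])
    return DetectionFilterResult(
        expression=kept,
        n_kept=int(keep.sum()),
        n_dropped=int((~keep).sum()),
        dropped_probes=expr.probes[~keep],
    )


def detection_from_pvalues(detection_p: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Adapter for chip exports that report a detection p-value per
    measurement: detected iff p < alpha."""
    return detection_p < alpha


def vst(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Monotone variance-stabilizing transform ``log2(x + offset)``.

    Rank order within each sample is preserved.  Raises if any shifted value
    is non-positive.
    """
    shifted = expr.values + offset
    if (shifted <= 0).any().any():
        raise ValueError(
            f"vst domain violation: values <= {-offset} present; "
            "increase the offset"
        )
    return dataclasses.replace(expr, values=np.log2(shifted))


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean) quantile profile.

    The value at rank r in each sample is replaced by the mean, across
    samples, of the rank-r values.  Ties receive the mean of their tied-rank
    targets, so the transform is well defined and idempotent.  Requires a
    complete matrix (detection is handled separately).
    """
    vals = expr.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n_probes, n_samples = vals.shape
    if n_samples < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return dataclasses.replace(expr, normalized=True)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        # average ranks map ties onto the mean of their tied reference slots
        ranks = rankdata(vals[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return dataclasses.replace(
        expr,
        values=pd.DataFrame(out, index=expr.probes, columns=expr.samples),
        normalized=True,
    )
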