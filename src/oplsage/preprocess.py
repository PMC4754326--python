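"""Mean-centering and unit-variance (UV) scaling.

Parameters are always estimated on training data and applied unchanged to
unseen rows; the sample standard deviation (n-1 denominator) is used, the
usual convention in chemometrics-style UV scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError, SchemaError


@dataclass(frozen=True)
class ScalingParams:
    """Per-column mean and sample SD, with the column names they belong to."""

    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            c: {"mean": float(m), "sd": float(s)}
            for c, m, s in zip(self.columns, self.mean, self.sd)
        }


def _as_matrix(
    X: np.ndarray | pd.DataFrame, columns: Sequence[str] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SchemaError("expected a 2-D matrix")
    if columns is None:
        columns = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(columns)


def fit_scaling(
    X: np.ndarray | pd.DataFrame, columns: Sequence[str] | None = None
) -> ScalingParams:
    """Estimate per-column mean and sample SD on training data.

    Raises :class:`DegenerateFeatureError` naming the first column whose SD
    is zero (a constant feature cannot be unit-variance scaled).
    """
    M, cols = _as_matrix(X, columns)
    if M.shape[0] < 2:
        raise SchemaError("need at least 2 rows to estimate a sample SD")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    # a relative threshold: rounding can leave a numerically constant
    # column with a tiny nonzero SD
    zero = np.flatnonzero(sd < 1e-10 * np.maximum(1.0, np.abs(mean)))
    if zero.size:
        raise DegenerateFeatureError(
            f"column {cols[zero[0]]!r} has zero variance"
        )
    return ScalingParams(columns=cols, mean=mean, sd=sd)


def apply_scaling(
    params: ScalingParams,
    X: np.ndarray | pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> np.ndarray:
    """(x - mean) / sd elementwise with training-set parameters."""
    M, cols = _as_matrix(X, columns)
    if isinstance(X, pd.DataFrame) or columns is not None:
        if cols != params.columns:
            raise SchemaError(
                f"column mismatch: expected {params.columns}, got {cols}"
            )
    elif M.shape[1] != len(params.columns):
        raise SchemaError(
            f"expected {len(params.columns)} columns, got {M.shape[1]}"
        )
    return (M - params.mean) / params.sd
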