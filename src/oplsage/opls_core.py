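"""Two-class OPLS discriminant engine.

Orthogonal projections to latent structures (OPLS) separates the
systematic variation of the descriptor matrix into a single predictive
component, correlated with the class response, and a chosen number of
components orthogonal to the response. For a two-class problem with the
response coded 0/1, the predictive score of a subject plays the role of a
class-membership estimate: values near 1 indicate an AD-like pattern,
values near 0 a control-like pattern.

With ``n_ortho = 0`` the algorithm coincides with single-component NIPALS
PLS; with ``k`` orthogonal components its training predictions match those
of a (1+k)-component PLS model, the classical equivalence of the
orthogonal-filtering formulation.

The input matrix must already be column-centered (normally UV-scaled via
:mod:`oplsage.preprocess`); predictions add back the training class
prevalence, so a row at the training grand mean scores exactly ``y_bar``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import RankError, SchemaError, ValidationError
from .preprocess import ScalingParams

_EPS = 1e-12


@dataclass
class OplsModel:
    """Fitted two-class OPLS model (one predictive + n_ortho orthogonal)."""

    weights: np.ndarray  # predictive weight w, unit norm, (p,)
    loading: np.ndarray  # predictive loading p, (p,)
    c: float  # regression of y on the predictive score t
    y_mean: float  # training class prevalence (y coded CTL=0, AD=1)
    ortho_weights: np.ndarray  # (n_ortho, p), unit rows
    ortho_loadings: np.ndarray  # (n_ortho, p)
    column_names: tuple[str, ...]
    scaling: ScalingParams | None = field(default=None, repr=False)

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "columns": list(self.column_names),
            "weights": self.weights.tolist(),
            "loading": self.loading.tolist(),
            "c": self.c,
            "y_mean": self.y_mean,
            "ortho_weights": self.ortho_weights.tolist(),
            "ortho_loadings": self.ortho_loadings.tolist(),
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class FitQuality:
    """Goodness of fit, R^2 = 1 - RSS/SS, at most 1."""

    r2: float

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValidationError("R^2 cannot exceed 1")


def _check_columns(model: OplsModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.column_names):
        raise SchemaError(
            f"expected {len(model.column_names)} columns, got {X.shape[1]}"
        )
    return X


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    column_names: Sequence[str] | None = None,
    scaling: ScalingParams | None = None,
) -> OplsModel:
    """Fit a two-class OPLS model on a column-centered matrix.

    Algorithm (single response, deterministic, no iteration needed):
    ``w ∝ X'y`` normalized; then for each orthogonal component, with
    ``t = Xw``: ``p = X't/(t't)``, ``w_o ∝ p - (w'p)w`` normalized,
    ``t_o = Xw_o``, ``p_o = X't_o/(t_o't_o)`` and ``X ← X - t_o p_o'``.
    Finally ``t = Xw`` and ``c = y't/(t't)``.

    The sign of ``w`` is oriented so the class coded 1 has the higher mean
    predictive score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise SchemaError("X and y must align")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("both classes must be present in y")
    if n_ortho < 0:
        raise ValidationError("n_ortho must be >= 0")
    n, p = X.shape
    names = (
        tuple(column_names)
        if column_names is not None
        else tuple(f"x{i}" for i in range(p))
    )
    if len(names) != p:
        raise SchemaError("column_names length mismatch")

    scale0 = float(np.abs(X).max()) or 1.0
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < _EPS * scale0:
        raise RankError("X carries no covariance with y")
    w = w / nw

    Xd = X.copy()
    W_o = np.zeros((n_ortho, p))
    P_o = np.zeros((n_ortho, p))
    for j in range(n_ortho):
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise RankError(f"deflation degenerate at orthogonal component {j}")
        pl = Xd.T @ t / tt
        w_o = pl - float(w @ pl) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-10 * max(1.0, np.linalg.norm(pl)):
            raise RankError(
                f"no orthogonal variation left for component {j} "
                f"(requested n_ortho={n_ortho} too large for rank of X)"
            )
        w_o = w_o / norm_o
        t_o = Xd @ w_o
        tto = float(t_o @ t_o)
        if tto < _EPS:
            raise RankError(f"degenerate orthogonal score at component {j}")
        p_o = Xd.T @ t_o / tto
        Xd = Xd - np.outer(t_o, p_o)
        W_o[j] = w_o
        P_o[j] = p_o

    t = Xd @ w
    tt = float(t @ t)
    if tt < _EPS:
        raise RankError("predictive score collapsed after deflation")
    c = float(y @ t) / tt
    loading = Xd.T @ t / tt

    # orient the predictive direction so class 1 scores higher
    if np.mean(t[y == classes.max()]) < np.mean(t[y == classes.min()]):
        w, c, loading = -w, -c, -loading

    return OplsModel(
        weights=w,
        loading=loading,
        c=c,
        y_mean=float(y.mean()),
        ortho_weights=W_o,
        ortho_loadings=P_o,
        column_names=names,
        scaling=scaling,
    )


def predict_scores(model: OplsModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted class scores for rows scaled with the model's parameters.

    Each orthogonal component is removed from the new data
    (``t_o = X w_o``; ``X ← X - t_o p_o'``) before projecting on the
    predictive weight. Scores are unbounded reals, typically near [0, 1].
    """
    X = _check_columns(model, X_new).copy()
    for w_o, p_o in zip(model.ortho_weights, model.ortho_loadings):
        t_o = X @ w_o
        X -= np.outer(t_o, p_o)
    return model.y_mean + model.c * (X @ model.weights)


def r2(model: OplsModel, X: np.ndarray, y: np.ndarray) -> FitQuality:
    """Goodness of fit of the model's predictions on (X, y)."""
    y = np.asarray(y, dtype=float).ravel()
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0.0:
        raise ValidationError("y has zero variance; R^2 undefined")
    yhat = predict_scores(model, X)
    rss = float(np.sum((y - yhat) ** 2))
    return FitQuality(r2=1.0 - rss / ss)
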