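"""Sevenfold cross-validation, Q², and orthogonal-component selection.

Q² ("goodness of prediction") is ``1 - PRESS/SS`` where PRESS accumulates
squared errors of cross-validated predictions: each subject is predicted
exactly once, by a model whose training folds exclude it. Everything that
is estimated from data — UV scaling and, when requested, the control-based
age detrender — is refit inside each training fold so that Q² is an honest
out-of-sample quantity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .age_correction import AgeDetrendModel, Correction, apply_detrend, fit_detrend
from .exceptions import RankError, SchemaError, ValidationError
from .opls_core import OplsModel, fit_opls, predict_scores
from .preprocess import ScalingParams, apply_scaling, fit_scaling

log = logging.getLogger(__name__)


@dataclass
class FittedStage:
    """One fully fitted prediction stage: optional detrender, scaling, OPLS."""

    opls: OplsModel
    scaling: ScalingParams
    detrender: AgeDetrendModel | None = None

    def predict(self, X_raw: np.ndarray, ages: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X_raw, dtype=float)
        if self.detrender is not None:
            if ages is None:
                raise SchemaError("ages required for a detrended stage")
            X = apply_detrend(self.detrender, X, ages)
        return predict_scores(self.opls, apply_scaling(self.scaling, X))


@dataclass
class CvResult:
    """Per-subject cross-validated scores with Q² and full-refit R²."""

    y_cv: np.ndarray  # cross-validated predicted score per subject
    folds: np.ndarray  # fold id per subject
    q2: float
    r2: float
    n_ortho: int
    seed: int | None
    model: FittedStage = field(repr=False)


def make_folds(
    n: int, k: int = 7, labels: np.ndarray | None = None, seed: int = 0
) -> np.ndarray:
    """Stratified partition of ``range(n)`` into ``k`` folds.

    Fold sizes differ by at most one overall and per class. If a class has
    fewer than ``k`` members, stratification is impossible; a warning is
    emitted and a plain shuffled partition is used instead.
    """
    if n < k:
        raise ValidationError(f"need n >= k, got n={n}, k={k}")
    labels = np.asarray(labels) if labels is not None else np.zeros(n, dtype=int)
    if labels.shape[0] != n:
        raise SchemaError("labels length must equal n")
    assignment = np.empty(n, dtype=int)
    counts = np.bincount(labels.astype(int)) if labels.dtype != object else None
    stratify = counts is not None and counts.min() >= k and counts.size >= 2
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), labels)
    else:
        if counts is None or counts.size >= 2:
            warnings.warn(
                "a class has fewer members than folds; using unstratified folds",
                stacklevel=2,
            )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    for fold_id, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold_id
    return assignment


def _fit_stage(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int,
    correction: Correction,
    ages: np.ndarray | None,
    ctl_mask: np.ndarray | None,
) -> FittedStage:
    detrender = None
    if correction is Correction.DETREND:
        if ages is None:
            raise SchemaError("detrend correction requires ages")
        mask = ctl_mask if ctl_mask is not None else (y == 0)
        if mask.sum() < 3:
            raise ValidationError("too few control subjects to fit the detrender")
        detrender = fit_detrend(X[mask], ages[mask])
        X = apply_detrend(detrender, X, ages)
    scaling = fit_scaling(X)
    model = fit_opls(apply_scaling(scaling, X), y, n_ortho, scaling=scaling)
    return FittedStage(opls=model, scaling=scaling, detrender=detrender)


def cv_scores(
    X_raw: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 0,
    correction: Correction | str = Correction.NONE,
    ages: np.ndarray | None = None,
    ctl_mask: np.ndarray | None = None,
    k: int = 7,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> CvResult:
    """Cross-validated prediction of every subject, plus Q² and refit R².

    The ``covariate`` strategy is not handled here: age joins the model
    matrix at the top hierarchical level (see :mod:`oplsage.pipeline`),
    so base-model CV only distinguishes raw vs detrended inputs.
    """
    correction = Correction.coerce(correction)
    if correction is Correction.COVARIATE:
        raise ValidationError(
            "covariate correction is applied at the pipeline level; "
            "cv_scores accepts 'none' or 'detrend'"
        )
    X = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, k=k, labels=y.astype(int), seed=seed)
    folds = np.asarray(folds)

    y_cv = np.empty(n, dtype=float)
    for fold_id in np.unique(folds):
        test = folds == fold_id
        train = ~test
        stage = _fit_stage(
            X[train],
            y[train],
            n_ortho,
            correction,
            ages[train] if ages is not None else None,
            ctl_mask[train] if ctl_mask is not None else None,
        )
        y_cv[test] = stage.predict(X[test], ages[test] if ages is not None else None)

    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - float(np.sum((y - y_cv) ** 2)) / ss

    full = _fit_stage(X, y, n_ortho, correction, ages, ctl_mask)
    yhat = full.predict(X, ages)
    r2_full = 1.0 - float(np.sum((y - yhat) ** 2)) / ss

    return CvResult(
        y_cv=y_cv,
        folds=folds,
        q2=q2,
        r2=r2_full,
        n_ortho=n_ortho,
        seed=seed,
        model=full,
    )


def select_n_ortho(
    X_raw: np.ndarray,
    y: np.ndarray,
    correction: Correction | str = Correction.NONE,
    seed: int = 0,
    max_ortho: int = 5,
    tol: float = 0.01,
    ages: np.ndarray | None = None,
    ctl_mask: np.ndarray | None = None,
    k: int = 7,
    folds: np.ndarray | None = None,
) -> int:
    """Pick the number of orthogonal components by cross-validated Q².

    Q² is evaluated for ``n_ortho = 0 .. max_ortho`` and the smallest count
    whose Q² lies within ``tol`` of the maximum is returned (parsimony
    rule). Complexities the data's rank cannot support are skipped.
    """
    q2s: dict[int, float] = {}
    for m in range(max_ortho + 1):
        try:
            res = cv_scores(
                X_raw, y, m, correction, ages, ctl_mask, k=k, seed=seed, folds=folds
            )
        except RankError:
            log.debug("n_ortho=%d unsupported by data rank; stopping search", m)
            break
        q2s[m] = res.q2
    if not q2s:
        raise RankError("no model complexity could be fitted")
    best = max(q2s.values())
    chosen = min(m for m, q in q2s.items() if q >= best - tol)
    log.debug("select_n_ortho: q2 by complexity %s -> %d", q2s, chosen)
    return chosen
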