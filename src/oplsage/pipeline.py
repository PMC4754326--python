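"""End-to-end hierarchical modelling and evaluation.

The discriminant model is built hierarchically: volumetric and thickness
measures are modelled separately by two base OPLS models, and their output
scores feed a final (top) OPLS model. Under the ``covariate`` strategy the
subject's age joins the top model matrix alongside the two base scores;
under ``detrend`` every feature is age-corrected with control-estimated
slopes before modelling.

During training the top model consumes the base models' *cross-validated*
scores (fitted scores would leak training information upward and inflate
the top-level Q²); at prediction time the fully fitted base models'
ordinary predicted scores are used. A fixed cut-off of 0.5 on the
predicted score assigns class membership (score >= 0.5 -> AD-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .age_correction import Correction
from .crossval import CvResult, FittedStage, cv_scores, make_folds, select_n_ortho
from .data_model import CohortTable
from .exceptions import ValidationError
from .manifest import FeatureManifest

log = logging.getLogger(__name__)

TOP_COLUMNS = ("volume_score", "thickness_score")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used for reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with accuracy/sensitivity/specificity (positive = AD-like)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    def rounded(self) -> dict[str, float]:
        """Percentages rounded half-up to one decimal, for reporting."""
        return {
            "accuracy": round_half_up(self.accuracy),
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
        }

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            **{f"{k}_rounded": v for k, v in self.rounded().items()},
        }


@dataclass
class HierarchicalModel:
    """Two base OPLS models (volumes; thicknesses) under a top OPLS model."""

    correction: Correction
    volume_stage: FittedStage
    thickness_stage: FittedStage
    top_stage: FittedStage
    volume_columns: tuple[str, ...]
    thickness_columns: tuple[str, ...]
    cutoff: float = 0.5
    n_ortho: dict[str, int] = field(default_factory=dict)

    def top_inputs(self, cohort: CohortTable) -> np.ndarray:
        """Base-model predicted scores (plus age under ``covariate``)."""
        ages = cohort.ages
        vol = self.volume_stage.predict(cohort.features(self.volume_columns), ages)
        thick = self.thickness_stage.predict(
            cohort.features(self.thickness_columns), ages
        )
        cols = [vol, thick]
        if self.correction is Correction.COVARIATE:
            cols.append(ages)
        return np.column_stack(cols)

    def predict_scores(self, cohort: CohortTable) -> np.ndarray:
        return self.top_stage.predict(self.top_inputs(cohort))


def classify(scores: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """0/1 labels from predicted scores; score >= cutoff is AD-like (1)."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def metrics_from_labels(
    predicted: np.ndarray, truth: np.ndarray
) -> ConfusionMetrics:
    """Confusion counts and rates; positive class is AD / AD-like truth."""
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and truth must have equal length")
    if np.unique(truth).size < 2:
        raise ValidationError(
            "truth contains a single class; sensitivity or specificity undefined"
        )
    return ConfusionMetrics(
        tp=int(np.sum((predicted == 1) & (truth == 1))),
        fn=int(np.sum((predicted == 0) & (truth == 1))),
        tn=int(np.sum((predicted == 0) & (truth == 0))),
        fp=int(np.sum((predicted == 1) & (truth == 0))),
    )


def fit_hierarchical(
    cohort: CohortTable,
    correction: Correction | str = Correction.NONE,
    seed: int = 0,
    k: int = 7,
    max_ortho: int = 5,
    tol: float = 0.01,
    manifest: FeatureManifest | None = None,
) -> tuple[HierarchicalModel, CvResult]:
    """Fit the three-level model on the AD+CTL rows of a cohort.

    Returns the fitted hierarchy and the top-level cross-validation result
    whose Q²/R² and cross-validated score vector are the reported model
    quality and classification scores. The number of orthogonal components
    of every sub-model is chosen by the parsimonious Q² rule.
    """
    correction = Correction.coerce(correction)
    manifest = manifest or cohort.manifest
    train = cohort.subset(cohort.mask("CTL", "AD"))
    y = (train.diagnosis == "AD").astype(int)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValidationError("need at least 2 subjects per class")
    ages = train.ages
    folds = make_folds(train.n_subjects, k=k, labels=y, seed=seed)
    base_corr = (
        Correction.DETREND if correction is Correction.DETREND else Correction.NONE
    )

    blocks = {
        "volume": manifest.volume_names,
        "thickness": manifest.thickness_names,
    }
    base_cv: dict[str, CvResult] = {}
    n_ortho: dict[str, int] = {}
    for name, cols in blocks.items():
        X = train.features(cols)
        m = select_n_ortho(
            X, y, base_corr, seed=seed, max_ortho=max_ortho, tol=tol,
            ages=ages, folds=folds,
        )
        base_cv[name] = cv_scores(
            X, y, m, base_corr, ages=ages, folds=folds, seed=seed
        )
        n_ortho[name] = m
        log.info("base %s model: n_ortho=%d Q2=%.3f", name, m, base_cv[name].q2)

    top_X = np.column_stack(
        [base_cv["volume"].y_cv, base_cv["thickness"].y_cv]
        + ([ages] if correction is Correction.COVARIATE else [])
    )
    max_top = min(max_ortho, top_X.shape[1] - 1)
    m_top = select_n_ortho(
        top_X, y, Correction.NONE, seed=seed, max_ortho=max_top, tol=tol, folds=folds
    )
    top_cv = cv_scores(top_X, y, m_top, Correction.NONE, folds=folds, seed=seed)
    n_ortho["top"] = m_top
    log.info(
        "top model (%s): n_ortho=%d Q2=%.3f R2=%.3f",
        correction.value, m_top, top_cv.q2, top_cv.r2,
    )

    model = HierarchicalModel(
        correction=correction,
        volume_stage=base_cv["volume"].model,
        thickness_stage=base_cv["thickness"].model,
        top_stage=top_cv.model,
        volume_columns=tuple(blocks["volume"]),
        thickness_columns=tuple(blocks["thickness"]),
        n_ortho=n_ortho,
    )
    return model, top_cv


def predict_mci(
    model: HierarchicalModel, mci: CohortTable
) -> tuple[np.ndarray, np.ndarray]:
    """Score MCI subjects as unseen data and label them CTL-like/AD-like.

    Age correction reuses the control-derived detrender from training; the
    base models contribute their ordinary predicted scores.
    """
    if mci.n_subjects == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if not np.all(mci.diagnosis == "MCI"):
        raise ValidationError("predict_mci expects an MCI-only table")
    scores = model.predict_scores(mci)
    return scores, classify(scores, model.cutoff)


def evaluate_prediction_at_month(
    predictions: np.ndarray, cohort: CohortTable, month: int
) -> tuple[ConfusionMetrics, int]:
    """Confusion metrics against progressed-by-month truth.

    Subjects whose status at the month is unknown are excluded; the count
    of exclusions is returned alongside the metrics.
    """
    status = cohort.progression_at(month)
    known = np.isin(status, ("stable", "progressed"))
    n_excluded = int(np.sum(~known))
    if not known.any():
        raise ValidationError(f"no subject has known status at month {month}")
    truth = (status[known] == "progressed").astype(int)
    predicted = np.asarray(predictions).astype(int)[known]
    return metrics_from_labels(predicted, truth), n_excluded
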