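"""Age correction of MRI measures.

Two strategies are supported by the analysis pipeline:

* ``covariate`` — age enters the discriminant model as an additional
  variable (handled by :mod:`oplsage.pipeline`; nothing to fit here);
* ``detrend`` — a per-feature linear model of feature on age is estimated
  by ordinary least squares **in the control group only**, and the fitted
  slope is then used to remove the age-related drift from all subjects
  (CTL, MCI and AD alike).

The rationale for fitting on controls only: age-related change in controls
reflects aging alone, whereas in patients it is confounded with
disease-related change; removing a patient-estimated slope would remove
disease signal too.

Corrected values are anchored at the control-group mean age,
``x' = x - beta1 * (age - reference_age)``, so features stay in their
natural units and a zero slope is the exact identity.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import DegenerateDataError, SchemaError


class Correction(str, enum.Enum):
    """Age-correction strategy for a discriminant model."""

    NONE = "none"
    COVARIATE = "covariate"
    DETREND = "detrend"

    @classmethod
    def coerce(cls, value: "Correction | str") -> "Correction":
        return value if isinstance(value, Correction) else cls(str(value))


@dataclass(frozen=True)
class AgeDetrendModel:
    """Per-feature linear age drift (intercept, slope) estimated on controls."""

    feature_names: tuple[str, ...]
    beta0: np.ndarray  # feature units
    beta1: np.ndarray  # feature units per year
    reference_age: float  # mean age of the control training sample

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "reference_age": self.reference_age,
            "features": {
                n: {"beta0": float(b0), "beta1": float(b1)}
                for n, b0, b1 in zip(self.feature_names, self.beta0, self.beta1)
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "AgeDetrendModel":
        payload = json.loads(text)
        names = tuple(payload["features"])
        return cls(
            feature_names=names,
            beta0=np.array([payload["features"][n]["beta0"] for n in names]),
            beta1=np.array([payload["features"][n]["beta1"] for n in names]),
            reference_age=float(payload["reference_age"]),
        )


def fit_detrend(
    ctl_features: np.ndarray,
    ctl_ages: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> AgeDetrendModel:
    """OLS fit of each feature on age, control subjects only.

    Callers are responsible for passing control rows exclusively; the
    reference age is the mean age of the sample provided.
    """
    X = np.asarray(ctl_features, dtype=float)
    ages = np.asarray(ctl_ages, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ages.shape[0]:
        raise SchemaError("feature rows and age vector must align")
    if X.shape[0] < 3:
        raise DegenerateDataError("need at least 3 control subjects")
    ref = float(ages.mean())
    a = ages - ref
    denom = float(a @ a)
    if denom == 0.0:
        raise DegenerateDataError("zero age variance in control sample")
    beta1 = (a @ (X - X.mean(axis=0))) / denom
    beta0 = X.mean(axis=0) - beta1 * ref
    names = (
        tuple(feature_names)
        if feature_names is not None
        else tuple(f"x{i}" for i in range(X.shape[1]))
    )
    if len(names) != X.shape[1]:
        raise SchemaError("feature_names length mismatch")
    return AgeDetrendModel(
        feature_names=names, beta0=beta0, beta1=beta1, reference_age=ref
    )


def apply_detrend(
    model: AgeDetrendModel,
    features: np.ndarray,
    ages: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Remove the control-estimated linear drift from any subjects' features.

    ``x' = x - beta1 * (age - reference_age)``; applied identically to all
    diagnostic groups, keeping values in original feature units.
    """
    X = np.asarray(features, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise SchemaError("feature name mismatch with detrend model")
    if X.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    ages = np.asarray(ages, dtype=float)
    corrected = X - np.outer(ages - model.reference_age, model.beta1)
    return corrected[:, 0] if squeeze else corrected
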