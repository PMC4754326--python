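"""Synthetic cohort generator.

Generates tabular cohorts with the statistical structure the analysis
assumes, so every downstream stage is testable without access-restricted
clinical data:

* four diagnostic groups (CTL, stable MCI, progressive MCI, AD) with
  configurable counts and demographic distributions;
* per-feature linear age drift (thickness declines, ventricles enlarge),
  composed of a nonspecific background plus an AD-pattern-aligned
  component: normal aging preferentially affects the same medial-temporal
  structures the disease does, which is what makes old controls and young
  patients hard to classify without age correction;
* graded disease effects expressed in units of residual SD, largest in
  medial-temporal measures (hippocampus, amygdala, entorhinal cortex) and
  intermediate across the temporal lobe, with MCI groups receiving a
  configurable fraction of the full AD shift;
* a two-factor residual correlation structure (a global atrophy factor and
  a temporal-lobe/AD-pattern factor) so the 55 measures are realistically
  collinear rather than independent;
* a latent disease severity per MCI subject, drawn around the group's
  fraction of the full AD effect, that drives both the subject's feature
  shift and the follow-up month at which a stable-MCI subject converts;
  progression therefore tracks latent severity, and longer follow-up
  yields truth labels increasingly aligned with the structural pattern.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.stats import truncnorm

from .data_model import CohortTable, METADATA_COLUMNS, PROGRESSION_MONTHS
from .exceptions import ValidationError
from .manifest import FeatureManifest, default_manifest

import pandas as pd

GROUPS = ("CTL", "MCI-s", "MCI-p", "AD")

# Per-feature generative defaults: baseline at the reference age in natural
# units (mm for thickness, mm^3 for volumes), age slope (units/year),
# residual SD (units), signed AD effect (in residual-SD units; negative =
# atrophy/thinning, positive = enlargement), and effect class driving the
# factor loadings: mtl (medial-temporal), temporal, other, ventricle,
# fluid (slow CSF-space/lesion growth), none.
_FEATURE_DEFAULTS: dict[str, tuple[float, float, float, float, str]] = {
    "bankssts_thickness": (2.45, -0.009, 0.13, -1.0, "temporal"),
    "caudalanteriorcingulate_thickness": (2.65, -0.010, 0.16, -0.3, "other"),
    "caudalmiddlefrontal_thickness": (2.55, -0.009, 0.13, -0.3, "other"),
    "cuneus_thickness": (1.85, -0.007, 0.11, -0.3, "other"),
    "entorhinal_thickness": (3.35, -0.017, 0.28, -1.5, "mtl"),
    "fusiform_thickness": (2.70, -0.009, 0.14, -1.0, "temporal"),
    "inferiorparietal_thickness": (2.45, -0.008, 0.12, -0.3, "other"),
    "inferiortemporal_thickness": (2.75, -0.009, 0.14, -1.0, "temporal"),
    "isthmuscingulate_thickness": (2.40, -0.009, 0.15, -0.3, "other"),
    "lateraloccipital_thickness": (2.20, -0.007, 0.11, -0.3, "other"),
    "lateralorbitofrontal_thickness": (2.65, -0.008, 0.13, -0.3, "other"),
    "lingual_thickness": (2.00, -0.007, 0.11, -0.3, "other"),
    "medialorbitofrontal_thickness": (2.45, -0.008, 0.13, -0.3, "other"),
    "middletemporal_thickness": (2.80, -0.009, 0.14, -1.0, "temporal"),
    "parahippocampal_thickness": (2.70, -0.014, 0.22, -1.5, "mtl"),
    "paracentral_thickness": (2.40, -0.008, 0.13, -0.3, "other"),
    "parsopercularis_thickness": (2.60, -0.008, 0.13, -0.3, "other"),
    "parsorbitalis_thickness": (2.65, -0.009, 0.15, -0.3, "other"),
    "parstriangularis_thickness": (2.50, -0.008, 0.13, -0.3, "other"),
    "pericalcarine_thickness": (1.60, -0.006, 0.11, -0.3, "other"),
    "postcentral_thickness": (2.05, -0.007, 0.11, -0.3, "other"),
    "posteriorcingulate_thickness": (2.45, -0.009, 0.14, -0.3, "other"),
    "precentral_thickness": (2.55, -0.008, 0.13, -0.3, "other"),
    "precuneus_thickness": (2.30, -0.008, 0.12, -0.3, "other"),
    "rostralanteriorcingulate_thickness": (2.80, -0.010, 0.17, -0.3, "other"),
    "rostralmiddlefrontal_thickness": (2.40, -0.008, 0.12, -0.3, "other"),
    "superiorfrontal_thickness": (2.70, -0.009, 0.13, -0.3, "other"),
    "superiorparietal_thickness": (2.20, -0.007, 0.11, -0.3, "other"),
    "superiortemporal_thickness": (2.75, -0.009, 0.13, -1.0, "temporal"),
    "supramarginal_thickness": (2.50, -0.008, 0.12, -0.3, "other"),
    "frontalpole_thickness": (2.75, -0.012, 0.18, -0.3, "other"),
    "temporalpole_thickness": (3.70, -0.016, 0.25, -1.0, "temporal"),
    "transversetemporal_thickness": (2.35, -0.010, 0.16, -1.0, "temporal"),
    "insula_thickness": (2.95, -0.010, 0.15, -0.3, "other"),
    "Lateral-Ventricle_volume": (15000.0, 550.0, 6500.0, 0.5, "ventricle"),
    "Inf-Lat-Vent_volume": (550.0, 22.0, 280.0, 0.5, "ventricle"),
    "Cerebellum-White-Matter_volume": (14000.0, -110.0, 1800.0, -0.3, "other"),
    "Cerebellum-Cortex_volume": (52000.0, -330.0, 5200.0, -0.3, "other"),
    "Thalamus-Proper_volume": (6800.0, -48.0, 700.0, -0.3, "other"),
    "Caudate_volume": (3600.0, -28.0, 450.0, -0.3, "other"),
    "Putamen_volume": (4900.0, -42.0, 600.0, -0.3, "other"),
    "Pallidum_volume": (1550.0, -16.0, 250.0, -0.3, "other"),
    "Hippocampus_volume": (3600.0, -30.0, 420.0, -1.5, "mtl"),
    "Amygdala_volume": (1500.0, -14.0, 210.0, -1.5, "mtl"),
    "Accumbens-area_volume": (550.0, -7.0, 100.0, -0.3, "other"),
    "VentralDC_volume": (3800.0, -26.0, 400.0, -0.3, "other"),
    "vessel_volume": (45.0, 0.0, 25.0, 0.0, "none"),
    "choroid-plexus_volume": (800.0, 18.0, 290.0, 0.3, "fluid"),
    "3rd-Ventricle_volume": (1500.0, 38.0, 520.0, 0.5, "ventricle"),
    "4th-Ventricle_volume": (1800.0, 20.0, 540.0, 0.5, "ventricle"),
    "Brain-Stem_volume": (20500.0, -130.0, 2100.0, -0.3, "other"),
    "CSF_volume": (1000.0, 20.0, 310.0, 0.5, "ventricle"),
    "WM-hypointensities_volume": (2500.0, 110.0, 1600.0, 0.3, "fluid"),
    "Optic-Chiasm_volume": (180.0, 0.0, 55.0, 0.0, "none"),
    "Corpus-Callosum_volume": (3000.0, -27.0, 420.0, -0.3, "other"),
}

# Factor loadings (SD units) by effect class: (global factor, AD-pattern
# factor); signs follow the feature's disease direction.
_FACTOR_LOADINGS: dict[str, tuple[float, float]] = {
    "mtl": (0.60, 0.55),
    "temporal": (0.60, 0.44),
    "ventricle": (0.60, 0.26),
    "fluid": (0.60, 0.10),
    "none": (0.60, 0.05),
    "other": (0.60, 0.14),
}


def _group_dict(ctl, mci_s, mci_p, ad) -> dict[str, float]:
    return {"CTL": ctl, "MCI-s": mci_s, "MCI-p": mci_p, "AD": ad}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the reference cohort
    structure (340 CTL / 360 MCI-s / 85 MCI-p / 297 AD, ages ~75 +/- 6-7 y)."""

    n_ctl: int = 340
    n_mci_s: int = 360
    n_mci_p: int = 85
    n_ad: int = 297
    age_mean: dict[str, float] = field(
        default_factory=lambda: _group_dict(75.0, 75.0, 74.3, 75.7)
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: _group_dict(5.7, 6.9, 6.5, 7.0)
    )
    age_range: tuple[float, float] = (55.0, 95.0)
    reference_age: float = 75.0
    feature_names: tuple[str, ...] = ()
    feature_baseline: np.ndarray | None = None
    age_slope: np.ndarray | None = None
    disease_effect_ad: np.ndarray | None = None  # residual-SD units, signed
    residual_sd: np.ndarray | None = None
    factor_loadings: np.ndarray | None = None  # (p, n_factors), SD units
    # fraction of the full AD pattern expressed per year of normal aging;
    # folded into the default age slopes so that aging partially mimics the
    # disease signature (the structural basis of age-related misclassification)
    aging_similarity: float = 0.03
    mci_s_fraction_of_ad_effect: float = 0.3
    mci_p_fraction_of_ad_effect: float = 0.7
    sex_male_prob: dict[str, float] = field(
        default_factory=lambda: _group_dict(168 / 340, 219 / 360, 50 / 85, 132 / 297)
    )
    apoe4_prob: dict[str, float] = field(
        default_factory=lambda: _group_dict(92 / 334, 158 / 340, 52 / 83, 178 / 288)
    )
    adni_prob: dict[str, float] = field(
        default_factory=lambda: _group_dict(227 / 340, 260 / 360, 62 / 85, 175 / 297)
    )
    education_mean: dict[str, float] = field(
        default_factory=lambda: _group_dict(14.3, 13.9, 13.8, 12.0)
    )
    education_sd: dict[str, float] = field(
        default_factory=lambda: _group_dict(4.3, 4.7, 4.2, 4.9)
    )
    mmse_mean: dict[str, float] = field(
        default_factory=lambda: _group_dict(29.1, 27.1, 26.5, 22.2)
    )
    mmse_sd: dict[str, float] = field(
        default_factory=lambda: _group_dict(1.1, 1.7, 1.8, 3.7)
    )
    cdr_ad_mean: float = 0.92
    cdr_ad_sd: float = 0.43
    # cumulative fraction of MCI-s subjects (ranked by latent severity) that
    # have progressed by each later follow-up month
    extra_progression_by_month: dict[int, float] = field(
        default_factory=lambda: {18: 0.11, 24: 0.25, 36: 0.34}
    )
    # SD of the latent per-subject severity around its component mean
    # (truncated to [0, 1]); controls MCI heterogeneity and how strongly
    # progression tracks the structural pattern
    mci_severity_sd: float = 0.13
    # mean severity of the prodromal sub-population of stable MCI (the
    # subjects who eventually convert after month 12); their structural
    # pattern matches that of month-12 progressors, they just convert
    # later. The never-converting component's mean is solved so the MCI-s
    # group mean stays at mci_s_fraction_of_ad_effect.
    prodromal_severity: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_names:
            man = default_manifest()
            self.feature_names = man.names
        p = len(self.feature_names)
        if self.feature_baseline is None:
            missing = [n for n in self.feature_names if n not in _FEATURE_DEFAULTS]
            if missing:
                raise ValidationError(
                    f"no generative defaults for features {missing}; "
                    "provide explicit per-feature arrays"
                )
            tab = [_FEATURE_DEFAULTS[n] for n in self.feature_names]
            self.feature_baseline = np.array([t[0] for t in tab])
            if self.residual_sd is None:
                self.residual_sd = np.array([t[2] for t in tab])
            if self.disease_effect_ad is None:
                self.disease_effect_ad = np.array([t[3] for t in tab])
            if self.age_slope is None:
                # nonspecific background drift plus the AD-pattern-aligned
                # component of normal aging
                self.age_slope = (
                    np.array([t[1] for t in tab])
                    + self.aging_similarity
                    * np.asarray(self.disease_effect_ad, dtype=float)
                    * np.asarray(self.residual_sd, dtype=float)
                )
            if self.factor_loadings is None:
                signs = np.sign(self.disease_effect_ad)
                signs[signs == 0] = 1.0
                self.factor_loadings = np.column_stack(
                    [
                        np.array([_FACTOR_LOADINGS[t[4]][0] for t in tab]) * signs,
                        np.array([_FACTOR_LOADINGS[t[4]][1] for t in tab]) * signs,
                    ]
                )
        for name in ("feature_baseline", "age_slope", "disease_effect_ad", "residual_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValidationError(f"{name} must have length {p}")
            setattr(self, name, arr)
        if self.factor_loadings is None:
            self.factor_loadings = np.zeros((p, 0))
        self.factor_loadings = np.atleast_2d(
            np.asarray(self.factor_loadings, dtype=float)
        )
        if self.factor_loadings.shape[0] != p:
            raise ValidationError("factor_loadings must have one row per feature")
        if (np.sum(self.factor_loadings**2, axis=1) >= 1.0).any():
            raise ValidationError("factor loadings imply non-positive unique variance")
        if min(self.n_ctl, self.n_mci_s, self.n_mci_p, self.n_ad) < 0:
            raise ValidationError("group counts must be >= 0")
        if not (0 <= self.mci_s_fraction_of_ad_effect <= 1):
            raise ValidationError("mci_s fraction must be in [0, 1]")
        if not (0 <= self.mci_p_fraction_of_ad_effect <= 1):
            raise ValidationError("mci_p fraction must be in [0, 1]")
        if self.mci_p_fraction_of_ad_effect < self.mci_s_fraction_of_ad_effect:
            raise ValidationError("mci_p fraction must be >= mci_s fraction")
        if (self.residual_sd <= 0).any():
            raise ValidationError("residual_sd must be positive")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationConfig":
        payload = dict(payload)
        for k in ("feature_baseline", "age_slope", "disease_effect_ad",
                  "residual_sd", "factor_loadings"):
            if payload.get(k) is not None:
                payload[k] = np.asarray(payload[k], dtype=float)
        if "feature_names" in payload:
            payload["feature_names"] = tuple(payload["feature_names"])
        if "age_range" in payload:
            payload["age_range"] = tuple(payload["age_range"])
        if "extra_progression_by_month" in payload:
            payload["extra_progression_by_month"] = {
                int(k): float(v)
                for k, v in payload["extra_progression_by_month"].items()
            }
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def group_counts(self) -> dict[str, int]:
        return _group_dict(self.n_ctl, self.n_mci_s, self.n_mci_p, self.n_ad)

    def effect_fraction(self, group: str) -> float:
        return {
            "CTL": 0.0,
            "MCI-s": self.mci_s_fraction_of_ad_effect,
            "MCI-p": self.mci_p_fraction_of_ad_effect,
            "AD": 1.0,
        }[group]


def confounded_scenario(
    base: SimulationConfig, ad_age_shift: float
) -> SimulationConfig:
    """Copy of ``base`` whose AD group is younger by ``ad_age_shift`` years.

    This creates the age-diagnosis confound (young patients, old controls
    on the decision boundary) that the correction methods must neutralize.
    """
    age_mean = dict(base.age_mean)
    age_mean["AD"] = age_mean["AD"] - ad_age_shift
    return replace(base, age_mean=age_mean)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SimulationConfig, manifest: FeatureManifest | None = None
) -> CohortTable:
    """Draw a cohort from the configured generative model.

    Feature j of a subject at age a is
    ``baseline_j + slope_j * (a - reference_age) + phi * effect_j * sd_j
    + sd_j * (L_j f + u_j e)`` with ``f`` standard-normal shared factors,
    ``e`` unique noise and ``u_j^2 = 1 - |L_j|^2``, so the residual has
    unit variance in SD units. ``phi`` is the subject's expressed fraction
    of the full AD effect: exactly 0 for CTL and 1 for AD, and for MCI
    subjects a latent severity drawn around the group's configured
    fraction (truncated normal on [0, 1]), so group means match the
    configured fractions while individuals are graded. Stable-MCI
    conversions at later follow-up months are assigned in decreasing order
    of that same latent severity.
    """
    manifest = manifest or default_manifest()
    if manifest.names != tuple(config.feature_names):
        raise ValidationError("manifest does not match config feature names")
    rng = np.random.default_rng(config.seed)
    p = len(config.feature_names)
    L = config.factor_loadings
    n_factors = L.shape[1]
    unique_sd = np.sqrt(1.0 - np.sum(L**2, axis=1))
    lo, hi = config.age_range

    frames: list[pd.DataFrame] = []
    severity_mci: dict[str, np.ndarray] = {}
    d = config.disease_effect_ad

    for gi, group in enumerate(GROUPS):
        n = config.group_counts()[group]
        if n == 0:
            continue
        ages = _truncated_normal(
            rng, config.age_mean[group], config.age_sd[group], lo, hi, n
        )
        factors = rng.standard_normal((n, n_factors))
        eps = factors @ L.T + rng.standard_normal((n, p)) * unique_sd
        group_phi = config.effect_fraction(group)
        if group == "MCI-s" and config.mci_severity_sd > 0:
            # mixture: a prodromal fraction (sized by the eventual
            # conversion rate) near MCI-p severity, the rest low
            f_conv = max(config.extra_progression_by_month.values(), default=0.0)
            mu_low = (
                (group_phi - f_conv * config.prodromal_severity)
                / max(1.0 - f_conv, 1e-9)
                if f_conv < 1.0
                else group_phi
            )
            mu_low = float(np.clip(mu_low, 0.0, 1.0))
            prodromal = rng.random(n) < f_conv
            phi = np.where(
                prodromal,
                _truncated_normal(
                    rng, config.prodromal_severity, config.mci_severity_sd,
                    0.0, 1.0, n,
                ),
                _truncated_normal(rng, mu_low, config.mci_severity_sd, 0.0, 1.0, n),
            )
        elif group == "MCI-p" and config.mci_severity_sd > 0:
            phi = _truncated_normal(
                rng, group_phi, config.mci_severity_sd, 0.0, 1.0, n
            )
        else:
            phi = np.full(n, group_phi)
        X = (
            config.feature_baseline
            + np.outer(ages - config.reference_age, config.age_slope)
            + np.outer(phi, d * config.residual_sd)
            + eps * config.residual_sd
        )
        sex = np.where(
            rng.random(n) < config.sex_male_prob[group], "M", "F"
        )
        apoe = np.where(
            rng.random(n) < config.apoe4_prob[group], "positive", "negative"
        )
        cohort_lab = np.where(rng.random(n) < config.adni_prob[group], "ADNI", "ANM")
        education = np.clip(
            rng.normal(config.education_mean[group], config.education_sd[group], n),
            0.0,
            30.0,
        )
        mmse = np.clip(
            np.rint(rng.normal(config.mmse_mean[group], config.mmse_sd[group], n)),
            0,
            30,
        ).astype(int)
        if group == "CTL":
            cdr = np.zeros(n)
        elif group == "AD":
            cdr = np.maximum(
                0.5,
                np.rint(rng.normal(config.cdr_ad_mean, config.cdr_ad_sd, n) * 2) / 2,
            )
        else:
            cdr = np.full(n, 0.5)

        diagnosis = "MCI" if group.startswith("MCI") else group
        frame = pd.DataFrame(
            {
                "subject_id": [f"{group}-{i:04d}" for i in range(n)],
                "diagnosis": diagnosis,
                "age": ages,
                "sex": sex,
                "education": education,
                "mmse": mmse,
                "cdr": cdr,
                "apoe4": apoe,
                "cohort": cohort_lab,
            }
        )
        for m in PROGRESSION_MONTHS:
            frame[f"prog_m{m}"] = "" if diagnosis != "MCI" else "unknown"
        for j, name in enumerate(config.feature_names):
            frame[name] = X[:, j]
        frame["_group"] = group
        if diagnosis == "MCI":
            severity_mci[group] = np.asarray(phi, dtype=float)
        frames.append(frame)

    full = pd.concat(frames, ignore_index=True)

    # progression labels
    is_mci_p = (full["_group"] == "MCI-p").to_numpy()
    is_mci_s = (full["_group"] == "MCI-s").to_numpy()
    full.loc[is_mci_p, [f"prog_m{m}" for m in PROGRESSION_MONTHS]] = "progressed"
    full.loc[is_mci_s, [f"prog_m{m}" for m in PROGRESSION_MONTHS]] = "stable"
    if is_mci_s.any() and config.extra_progression_by_month:
        sev = severity_mci.get("MCI-s", np.zeros(int(is_mci_s.sum())))
        order = np.argsort(-sev)  # most AD-like first
        idx_s = np.flatnonzero(is_mci_s)
        for month, frac in sorted(config.extra_progression_by_month.items()):
            n_conv = int(np.floor(frac * len(idx_s)))
            conv = idx_s[order[:n_conv]]
            for m in PROGRESSION_MONTHS:
                if m >= month:
                    col = f"prog_m{m}"
                    full.loc[conv, col] = "progressed"
    # follow-up beyond month 12 is only observed in the ADNI sub-cohort
    is_mci = is_mci_p | is_mci_s
    not_adni = is_mci & (full["cohort"] != "ADNI").to_numpy()
    for m in PROGRESSION_MONTHS:
        if m > 12:
            full.loc[not_adni, f"prog_m{m}"] = "unknown"

    full = full.drop(columns="_group")
    return CohortTable(manifest, full)
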