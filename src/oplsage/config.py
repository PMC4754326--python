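"""Experiment configuration and the three-model experiment driver.

``run_experiment`` wires every stage together: for each requested
correction strategy it fits the hierarchical model on the AD+CTL subjects,
reports Q²/R² and 0.5-cutoff classification metrics, predicts the MCI
subjects as unseen data (overall and per follow-up month, the latter
restricted to the ADNI sub-cohort beyond month 12), and emits the
correct-vs-incorrect characterization tables. A single top-level seed
governs simulation and fold construction through named substreams, so one
number reproduces a whole report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_correction import Correction
from .characterize import compare_subgroups
from .data_model import CohortTable, read_cohort, write_cohort
from .exceptions import ValidationError
from .pipeline import (
    classify,
    evaluate_prediction_at_month,
    fit_hierarchical,
    metrics_from_labels,
    predict_mci,
)
from .synthetic_cohort import SimulationConfig, confounded_scenario, generate_cohort

log = logging.getLogger(__name__)

FOLLOW_UP_MONTHS = (12, 18, 24, 36)


def derive_seed(seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one three-model experiment."""

    cohort_path: str | None = None  # CSV cohort; if None, simulate
    simulation: SimulationConfig | None = None
    ad_age_shift: float = 0.0  # >0 simulates an age-diagnosis confound
    corrections: tuple[str, ...] = ("none", "covariate", "detrend")
    seed: int = 0
    k_folds: int = 7
    max_ortho: int = 5
    tol: float = 0.01
    cutoff: float = 0.5
    months: tuple[int, ...] = FOLLOW_UP_MONTHS
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if not (0.0 < self.cutoff < 1.0):
            raise ValidationError("cutoff must lie in (0, 1)")
        if not self.corrections:
            raise ValidationError("at least one correction strategy required")
        self.corrections = tuple(Correction.coerce(c).value for c in self.corrections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in payload and payload["simulation"] is not None:
            payload["simulation"] = SimulationConfig.from_dict(payload["simulation"])
        for key in ("corrections", "months"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def manifest_dict(self) -> dict:
        """Reproducibility manifest: config hash, seed, package version."""
        sim = self.simulation.to_dict() if self.simulation else None
        body = {
            "cohort_path": self.cohort_path,
            "simulation": sim,
            "ad_age_shift": self.ad_age_shift,
            "corrections": list(self.corrections),
            "seed": self.seed,
            "k_folds": self.k_folds,
            "max_ortho": self.max_ortho,
            "tol": self.tol,
            "cutoff": self.cutoff,
            "months": list(self.months),
        }
        digest = hashlib.sha256(
            json.dumps(body, sort_keys=True).encode()
        ).hexdigest()
        return {"config": body, "config_sha256": digest, "version": __version__}


def load_or_simulate(config: ExperimentConfig) -> CohortTable:
    if config.cohort_path is not None:
        log.info("reading cohort from %s", config.cohort_path)
        return read_cohort(config.cohort_path)
    sim = config.simulation or SimulationConfig(
        seed=derive_seed(config.seed, "simulate")
    )
    if config.ad_age_shift:
        sim = confounded_scenario(sim, config.ad_age_shift)
    log.info(
        "simulating cohort (seed=%d, ad_age_shift=%.1f)", sim.seed, config.ad_age_shift
    )
    return generate_cohort(sim)


def run_strategy(
    cohort: CohortTable, correction: str, config: ExperimentConfig
) -> dict:
    """Fit, classify, predict MCI and characterize for one strategy."""
    fold_seed = derive_seed(config.seed, "folds")
    model, cv = fit_hierarchical(
        cohort,
        correction,
        seed=fold_seed,
        k=config.k_folds,
        max_ortho=config.max_ortho,
        tol=config.tol,
    )
    model.cutoff = config.cutoff
    train = cohort.subset(cohort.mask("CTL", "AD"))
    y = (train.diagnosis == "AD").astype(int)
    labels = classify(cv.y_cv, config.cutoff)
    cls_metrics = metrics_from_labels(labels, y)
    log.info(
        "[%s] AD/CTL: Q2=%.3f R2=%.3f acc=%.1f", correction, cv.q2, cv.r2,
        cls_metrics.accuracy,
    )

    block: dict = {
        "correction": correction,
        "q2": cv.q2,
        "r2": cv.r2,
        "n_ortho": model.n_ortho,
        "classification": cls_metrics.to_dict(),
    }

    mci = cohort.subset(cohort.mask("MCI"))
    scores_tbl = {
        "train": pd.DataFrame(
            {
                "subject_id": train.frame["subject_id"],
                "fold": cv.folds,
                "y": y,
                "y_cv": cv.y_cv,
                "predicted": labels,
            }
        )
    }
    charac = {
        "classification": compare_subgroups(train, labels == y, group_by="diagnosis")
    }
    if mci.n_subjects:
        mci_scores, mci_labels = predict_mci(model, mci)
        m12, _ = evaluate_prediction_at_month(mci_labels, mci, 12)
        block["mci"] = m12.to_dict()
        log.info("[%s] MCI month-12 acc=%.1f", correction, m12.accuracy)
        # the per-month table is scoped to the ADNI sub-cohort, the only one
        # followed past month 12; the overall block above uses all MCI
        by_month = {}
        sub_mask = (mci.frame["cohort"] == "ADNI").to_numpy()
        sub = mci.subset(sub_mask)
        for month in config.months:
            try:
                metrics, n_excl = evaluate_prediction_at_month(
                    mci_labels[sub_mask], sub, month
                )
            except ValidationError as exc:
                log.warning("[%s] month %d not evaluable: %s", correction, month, exc)
                continue
            by_month[str(month)] = {**metrics.to_dict(), "n_unknown": n_excl}
        block["mci_by_month"] = by_month
        scores_tbl["mci"] = pd.DataFrame(
            {
                "subject_id": mci.frame["subject_id"],
                "score": mci_scores,
                "predicted": mci_labels,
            }
        )
        m12_status = mci.progression_at(12)
        known = np.isin(m12_status, ("stable", "progressed"))
        correct = np.zeros(mci.n_subjects, dtype=bool)
        correct[known] = mci_labels[known] == (
            m12_status[known] == "progressed"
        ).astype(int)
        charac["mci"] = compare_subgroups(
            mci.subset(known), correct[known], group_by="progression", month=12
        )

    block["_tables"] = charac
    block["_scores"] = scores_tbl
    return block


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full multi-strategy experiment; optionally write artifacts."""
    cohort = load_or_simulate(config)
    log.info(
        "cohort: %d subjects (%d CTL / %d MCI / %d AD)",
        cohort.n_subjects,
        int(cohort.mask("CTL").sum()),
        int(cohort.mask("MCI").sum()),
        int(cohort.mask("AD").sum()),
    )
    report: dict = {"manifest": config.manifest_dict(), "strategies": {}}
    for correction in config.corrections:
        report["strategies"][correction] = run_strategy(cohort, correction, config)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        metrics = {
            "manifest": report["manifest"],
            "strategies": {
                name: {k: v for k, v in blk.items() if not k.startswith("_")}
                for name, blk in report["strategies"].items()
            },
        }
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        for name, blk in report["strategies"].items():
            for which, tbl in blk["_tables"].items():
                tbl.to_csv(outdir / f"comparison_{name}_{which}.csv", index=False)
            for which, tbl in blk["_scores"].items():
                tbl.to_csv(outdir / f"scores_{name}_{which}.csv", index=False)
        (outdir / "report.txt").write_text(render_report(report))
        log.info("artifacts written to %s", outdir)
    return report


def render_report(report: dict) -> str:
    """Human-readable summary of a run_experiment report."""
    lines = [
        "Age-corrected OPLS classification report",
        f"config sha256: {report['manifest']['config_sha256'][:16]}…",
        "",
    ]
    for name, blk in report["strategies"].items():
        c = blk["classification"]
        lines.append(f"== {name} model ==")
        lines.append(f"  Q2={blk['q2']:.3f}  R2={blk['r2']:.3f}  n_ortho={blk['n_ortho']}")
        lines.append(
            f"  AD/CTL: acc={c['accuracy_rounded']} sens={c['sensitivity_rounded']} "
            f"spec={c['specificity_rounded']} (tp={c['tp']} fn={c['fn']} "
            f"tn={c['tn']} fp={c['fp']})"
        )
        if "mci" in blk:
            m = blk["mci"]
            lines.append(
                f"  MCI (month 12): acc={m['accuracy_rounded']} "
                f"sens={m['sensitivity_rounded']} spec={m['specificity_rounded']}"
            )
            for month, mm in blk.get("mci_by_month", {}).items():
                lines.append(
                    f"    month {month}: acc={mm['accuracy_rounded']} "
                    f"sens={mm['sensitivity_rounded']} spec={mm['specificity_rounded']}"
                )
        lines.append("")
    lines.append("Note: characterization p-values are unadjusted for multiplicity.")
    return "\n".join(lines)
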