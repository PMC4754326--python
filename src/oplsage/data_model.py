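"""Cohort data structures and delimited-text I/O.

A cohort is one row per subject: diagnosis (CTL/MCI/AD), demographic and
clinical metadata, MCI progression status at each follow-up month, and an
ordered vector of numeric MRI measures defined by a
:class:`~oplsage.manifest.FeatureManifest`. The in-memory container wraps a
pandas DataFrame; all downstream stages consume :class:`CohortTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError, ValidationError
from .manifest import FeatureManifest, default_manifest

DIAGNOSES = ("CTL", "MCI", "AD")
SEXES = ("M", "F")
APOE_LEVELS = ("negative", "positive", "unknown")
COHORT_LABELS = ("ADNI", "ANM")
PROGRESSION_LEVELS = ("stable", "progressed", "unknown")
PROGRESSION_MONTHS = (12, 18, 24, 36)

#: metadata columns expected in every cohort CSV, in canonical order
METADATA_COLUMNS = (
    "subject_id",
    "diagnosis",
    "age",
    "sex",
    "education",
    "mmse",
    "cdr",
    "apoe4",
    "cohort",
) + tuple(f"prog_m{m}" for m in PROGRESSION_MONTHS)


@dataclass
class SubjectRecord:
    """One subject's metadata plus the ordered feature vector.

    ``progression`` maps follow-up month to {stable, progressed, unknown}
    and is meaningful only for MCI subjects.
    """

    subject_id: str
    diagnosis: str
    age: float
    sex: str
    education: float
    mmse: int
    cdr: float
    apoe4: str
    cohort: str
    features: np.ndarray
    progression: dict[int, str] = field(default_factory=dict)

    def validate(self, manifest: FeatureManifest) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"bad diagnosis {self.diagnosis!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"bad sex {self.sex!r}")
        if self.apoe4 not in APOE_LEVELS:
            raise ValidationError(f"bad apoe4 {self.apoe4!r}")
        if self.cohort not in COHORT_LABELS:
            raise ValidationError(f"bad cohort {self.cohort!r}")
        if not (self.age > 0):
            raise ValidationError("age must be positive")
        if not (0 <= self.mmse <= 30):
            raise ValidationError("mmse must be in [0, 30]")
        if self.cdr < 0:
            raise ValidationError("cdr must be >= 0")
        if len(self.features) != len(manifest):
            raise ValidationError(
                f"feature vector length {len(self.features)} != manifest {len(manifest)}"
            )
        if self.diagnosis != "MCI" and any(
            v != "unknown" for v in self.progression.values()
        ):
            raise ValidationError("progression defined only for MCI subjects")
        for m, v in self.progression.items():
            if m not in PROGRESSION_MONTHS or v not in PROGRESSION_LEVELS:
                raise ValidationError(f"bad progression entry {m}: {v!r}")


@dataclass
class CohortTable:
    """Subjects x (metadata + features); the universal exchange object.

    ``frame`` holds one row per subject with the columns of
    ``METADATA_COLUMNS`` followed by the manifest's feature columns.
    """

    manifest: FeatureManifest
    frame: pd.DataFrame
    rejected_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        missing += [c for c in self.manifest.names if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        # canonical column order
        cols = list(METADATA_COLUMNS) + list(self.manifest.names)
        self.frame = self.frame.loc[:, cols].reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.manifest.names

    def features(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Feature matrix (subjects x features), optionally a column subset."""
        names = list(names) if names is not None else list(self.manifest.names)
        return self.frame.loc[:, names].to_numpy(dtype=float)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def diagnosis(self) -> np.ndarray:
        return self.frame["diagnosis"].to_numpy(dtype=object)

    def mask(self, *diagnoses: str) -> np.ndarray:
        return np.isin(self.diagnosis, diagnoses)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.manifest, self.frame.loc[np.asarray(mask)].copy())

    def progression_at(self, month: int) -> np.ndarray:
        """Progression status vector at a follow-up month (object array)."""
        if month not in PROGRESSION_MONTHS:
            raise ValueError(f"month must be one of {PROGRESSION_MONTHS}")
        return self.frame[f"prog_m{month}"].to_numpy(dtype=object)

    # -- record interface ------------------------------------------------
    def iter_subjects(self) -> Iterator[SubjectRecord]:
        feats = self.features()
        for i, row in enumerate(self.frame.itertuples(index=False)):
            prog = {
                m: getattr(row, f"prog_m{m}")
                for m in PROGRESSION_MONTHS
                if isinstance(getattr(row, f"prog_m{m}"), str)
                and getattr(row, f"prog_m{m}") != ""
            }
            yield SubjectRecord(
                subject_id=row.subject_id,
                diagnosis=row.diagnosis,
                age=float(row.age),
                sex=row.sex,
                education=float(row.education),
                mmse=int(row.mmse),
                cdr=float(row.cdr),
                apoe4=row.apoe4,
                cohort=row.cohort,
                features=feats[i],
                progression=prog,
            )

    @classmethod
    def from_subjects(
        cls, subjects: Sequence[SubjectRecord], manifest: FeatureManifest
    ) -> "CohortTable":
        rows = []
        for s in subjects:
            s.validate(manifest)
            row: dict = {
                "subject_id": s.subject_id,
                "diagnosis": s.diagnosis,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                "mmse": s.mmse,
                "cdr": s.cdr,
                "apoe4": s.apoe4,
                "cohort": s.cohort,
            }
            for m in PROGRESSION_MONTHS:
                row[f"prog_m{m}"] = s.progression.get(m, "")
            row.update(dict(zip(manifest.names, s.features)))
            rows.append(row)
        frame = pd.DataFrame(
            rows, columns=list(METADATA_COLUMNS) + list(manifest.names)
        )
        dtypes: dict = {c: float for c in ("age", "education", "cdr")}
        dtypes.update({c: float for c in manifest.names})
        dtypes["mmse"] = int
        frame = frame.astype(dtypes)
        for col in ("subject_id", "diagnosis", "sex", "apoe4", "cohort"):
            frame[col] = frame[col].astype(object)
        for m in PROGRESSION_MONTHS:
            frame[f"prog_m{m}"] = frame[f"prog_m{m}"].astype(object)
        return cls(manifest, frame)

    def validate(self) -> None:
        """Run per-subject invariant checks over the whole table."""
        for s in self.iter_subjects():
            s.validate(self.manifest)


def read_cohort(
    path: str | Path, manifest: FeatureManifest | None = None
) -> CohortTable:
    """Read a cohort CSV, validating it against the feature manifest.

    Rows with any missing (empty or non-numeric-NA) feature value are
    rejected; their subject ids are reported on ``CohortTable.rejected_ids``.
    A missing column raises :class:`SchemaError`; a non-numeric feature cell
    that is not an NA marker raises :class:`ParseError` with row/column
    context.
    """
    manifest = manifest or default_manifest()
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)

    missing = [
        c
        for c in list(METADATA_COLUMNS) + list(manifest.names)
        if c not in frame.columns
    ]
    if missing:
        raise SchemaError(f"cohort file {path} lacks columns: {missing}")

    na_markers = {"", "NA", "NaN", "nan", "N/A"}
    feat_cols = list(manifest.names)
    rejected: list[str] = []
    keep = np.ones(len(frame), dtype=bool)
    for col in feat_cols:
        raw = frame[col].astype(str)
        is_na = raw.isin(na_markers)
        parsed = pd.to_numeric(frame[col].where(~is_na), errors="coerce")
        bad = parsed.isna() & ~is_na
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"non-numeric value {frame[col].iloc[i]!r} in column {col!r}, "
                f"row {i} (subject {frame['subject_id'].iloc[i]})"
            )
        keep &= ~is_na.to_numpy()
        frame[col] = parsed.astype(float)

    if not keep.all():
        rejected = frame.loc[~keep, "subject_id"].tolist()
        frame = frame.loc[keep].reset_index(drop=True)

    for col in ("age", "education", "cdr"):
        frame[col] = pd.to_numeric(frame[col]).astype(float)
    frame["mmse"] = pd.to_numeric(frame["mmse"]).astype(int)
    table = CohortTable(manifest, frame, rejected_ids=rejected)
    table.validate()
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV that round-trips exactly through :func:`read_cohort`.

    Floats are serialized with 17 significant digits so binary values
    survive the text round trip bit-exactly.
    """
    table.frame.to_csv(path, index=False, float_format="%.17g")
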