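"""Statistical characterization of correctly vs incorrectly classified subjects.

Continuous variables (age, education, MMSE) are compared with the
independent-samples t test (pooled variance by default; Welch available);
categorical variables (sex, ApoE-e4, cohort) with the Pearson chi-square
test without continuity correction. Significance is flagged at 0.05,
unadjusted for multiplicity — reports carry a note to that effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable
from .exceptions import ValidationError

CONTINUOUS_VARIABLES = ("age", "education", "mmse")
CATEGORICAL_VARIABLES = ("sex", "apoe4", "cohort")
DEFAULT_VARIABLES = CONTINUOUS_VARIABLES + CATEGORICAL_VARIABLES

#: displayed level order per categorical variable (first/second in summaries)
_LEVELS = {"sex": ("M", "F"), "apoe4": ("negative", "positive"), "cohort": ("ADNI", "ANM")}

MULTIPLICITY_NOTE = (
    "p-values are unadjusted for multiple comparisons; the 0.05 flag is "
    "descriptive, not confirmatory"
)


def _summary(values: np.ndarray, continuous: bool, levels=None) -> str:
    if continuous:
        return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"
    counts = [int(np.sum(values == lv)) for lv in levels]
    return "/".join(str(c) for c in counts)


def compare_groups(
    frame: pd.DataFrame,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    variables=DEFAULT_VARIABLES,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Rows with an ``unknown`` level are dropped per categorical variable; a
    group that is empty for a variable yields a "not computable" row rather
    than an error.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    rows = []
    for var in variables:
        continuous = var in CONTINUOUS_VARIABLES
        col = frame[var]
        if continuous:
            a = col.to_numpy(dtype=float)[mask_a]
            b = col.to_numpy(dtype=float)[mask_b]
            levels = None
        else:
            levels = _LEVELS.get(var, tuple(sorted(set(col) - {"unknown"})))
            known = col.isin(levels).to_numpy()
            a = col.to_numpy(dtype=object)[mask_a & known]
            b = col.to_numpy(dtype=object)[mask_b & known]
        row = {
            "variable": var,
            "test": "t" if continuous else "chi2",
            "group_a": _summary(a, continuous, levels) if len(a) else "n/a",
            "group_b": _summary(b, continuous, levels) if len(b) else "n/a",
            "n_a": len(a),
            "n_b": len(b),
        }
        if len(a) < 2 or len(b) < 2:
            row.update(statistic=np.nan, p=np.nan, significant=False,
                       note="not computable")
        elif continuous:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            row.update(statistic=float(t), p=float(p), significant=p < 0.05, note="")
        else:
            table = np.array(
                [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]]
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                row.update(statistic=np.nan, p=np.nan, significant=False,
                           note="not computable")
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                row.update(statistic=float(chi2), p=float(p),
                           significant=p < 0.05, note="")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_subgroups(
    cohort: CohortTable,
    correct_mask: np.ndarray,
    variables=DEFAULT_VARIABLES,
    group_by: str = "diagnosis",
    month: int = 12,
    equal_var: bool = True,
) -> pd.DataFrame:
    """The three comparisons of correctly vs incorrectly classified subjects.

    For ``group_by='diagnosis'`` (AD vs CTL classification): correct vs
    incorrect within CTL, within AD, and incorrect-CTL vs incorrect-AD.
    For ``group_by='progression'`` (MCI prediction): the analogous
    comparisons within MCI-s and MCI-p defined by progression status at
    ``month``. Returns a long table with a ``comparison`` column.
    """
    correct_mask = np.asarray(correct_mask, dtype=bool)
    if correct_mask.shape[0] != cohort.n_subjects:
        raise ValidationError("correct_mask must align with the cohort")
    frame = cohort.frame
    if group_by == "diagnosis":
        g0 = cohort.mask("CTL")
        g1 = cohort.mask("AD")
        names = ("CTL", "AD")
    elif group_by == "progression":
        status = cohort.progression_at(month)
        g0 = status == "stable"
        g1 = status == "progressed"
        names = ("MCI-s", "MCI-p")
    else:
        raise ValidationError("group_by must be 'diagnosis' or 'progression'")

    pieces = []
    for gmask, gname in ((g0, names[0]), (g1, names[1])):
        t = compare_groups(
            frame, gmask & correct_mask, gmask & ~correct_mask, variables, equal_var
        )
        t.insert(0, "comparison", f"{gname}: correct vs incorrect")
        pieces.append(t)
    t = compare_groups(
        frame, g0 & ~correct_mask, g1 & ~correct_mask, variables, equal_var
    )
    t.insert(0, "comparison", f"incorrect {names[0]} vs incorrect {names[1]}")
    pieces.append(t)
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["note"] = MULTIPLICITY_NOTE
    return out


def age_correlation_table(
    cohort: CohortTable, corrected: CohortTable
) -> pd.DataFrame:
    """Pearson r of every feature with age, per diagnostic group,
    before and after age correction.

    Groups with fewer than 3 subjects get NaN markers.
    """
    if cohort.feature_names != corrected.feature_names:
        raise ValidationError("cohorts must share a feature manifest")
    if cohort.n_subjects != corrected.n_subjects:
        raise ValidationError("cohorts must contain the same subjects")
    out = {}
    for group in ("CTL", "MCI", "AD"):
        mask = cohort.mask(group)
        for label, table in (("before", cohort), ("after", corrected)):
            ages = table.ages[mask]
            X = table.features()[mask]
            if mask.sum() < 3:
                r = np.full(len(cohort.feature_names), np.nan)
            else:
                a = ages - ages.mean()
                Xc = X - X.mean(axis=0)
                # degenerate columns (numerically constant) are undefined
                col_ss = np.sum(Xc**2, axis=0)
                tiny = (len(ages) * (1e-12 * np.maximum(1.0, np.abs(X).max(axis=0)))**2)
                ok = (a @ a > 0) & (col_ss > tiny)
                denom = np.sqrt((a @ a) * col_ss)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.where(ok, (a @ Xc) / denom, np.nan)
            out[(group, label)] = r
    return pd.DataFrame(out, index=list(cohort.feature_names))
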