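from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oplsage.age_correction import apply_detrend, fit_detrend
from oplsage.characterize import (
    age_correlation_table,
    compare_groups,
    compare_subgroups,
)
from oplsage.data_model import CohortTable
from oplsage.synthetic_cohort import SimulationConfig, generate_cohort


def _frame_with_categorical(counts_a, counts_b, var="apoe4", levels=("negative", "positive")):
    rows = []
    for grp, counts in (("a", counts_a), ("b", counts_b)):
        for level, c in zip(levels, counts):
            rows += [{"group": grp, var: level}] * c
    frame = pd.DataFrame(rows)
    frame["age"] = 70.0
    frame["education"] = 12.0
    frame["mmse"] = 28
    frame["sex"] = "M"
    frame["cohort"] = "ADNI"
    return frame


class TestTests:
    def test_chi_square_on_printed_apoe_table(self):
        # 26/5 vs 24/29 negative/positive carriers: Pearson chi-square
        # without continuity correction ~ 12.1, p rounds to 0.001
        frame = _frame_with_categorical((26, 5), (24, 29))
        out = compare_groups(
            frame, (frame["group"] == "a").to_numpy(), (frame["group"] == "b").to_numpy(),
            variables=("apoe4",),
        )
        row = out.iloc[0]
        assert row["statistic"] == pytest.approx(12.088, abs=0.01)
        assert round(row["p"], 3) == 0.001
        assert bool(row["significant"])

    def test_identical_subgroups_give_t_zero_p_one(self):
        frame = pd.DataFrame(
            {
                "age": [70.0, 72.0, 74.0, 70.0, 72.0, 74.0],
                "education": 12.0,
                "mmse": 28,
                "sex": "M",
                "apoe4": "negative",
                "cohort": "ADNI",
            }
        )
        mask_a = np.array([True] * 3 + [False] * 3)
        out = compare_groups(frame, mask_a, ~mask_a, variables=("age",))
        assert out.iloc[0]["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_t_test_matches_summary_statistic_oracle(self):
        # groups constructed to have exactly mean 74.5 sd 5.6 (n=309) and
        # 79.1 sd 5.2 (n=31): pooled t must match the closed-form
        # summary-statistics computation, p < 0.001
        rng = np.random.default_rng(0)

        def exact_sample(n, mean, sd):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        a = exact_sample(309, 74.5, 5.6)
        b = exact_sample(31, 79.1, 5.2)
        frame = pd.DataFrame(
            {
                "age": np.concatenate([a, b]),
                "education": 12.0,
                "mmse": 28,
                "sex": "M",
                "apoe4": "negative",
                "cohort": "ADNI",
            }
        )
        mask_a = np.arange(340) < 309
        out = compare_groups(frame, mask_a, ~mask_a, variables=("age",))
        t_ref, p_ref = stats.ttest_ind_from_stats(
            74.5, 5.6, 309, 79.1, 5.2, 31, equal_var=True
        )
        assert out.iloc[0]["statistic"] == pytest.approx(t_ref, abs=1e-8)
        assert out.iloc[0]["p"] == pytest.approx(p_ref, rel=1e-6)
        assert out.iloc[0]["p"] < 0.001

    def test_unknown_levels_dropped_per_variable(self):
        frame = _frame_with_categorical((10, 10), (10, 10))
        frame.loc[0, "apoe4"] = "unknown"
        mask_a = (frame["group"] == "a").to_numpy()
        out = compare_groups(frame, mask_a, ~mask_a, variables=("apoe4",))
        assert out.iloc[0]["n_a"] == 19

    def test_empty_subgroup_marked_not_computable(self):
        frame = _frame_with_categorical((5, 5), (5, 5))
        mask_a = (frame["group"] == "a").to_numpy()
        out = compare_groups(frame, mask_a, np.zeros(len(frame), bool), variables=("age",))
        assert out.iloc[0]["note"] == "not computable"
        assert np.isnan(out.iloc[0]["p"])


class TestCompareSubgroups:
    def test_three_comparisons_emitted(self, default_cohort):
        train = default_cohort.subset(default_cohort.mask("CTL", "AD"))
        rng = np.random.default_rng(0)
        correct = rng.random(train.n_subjects) < 0.85
        out = compare_subgroups(train, correct, group_by="diagnosis")
        assert set(out["comparison"]) == {
            "CTL: correct vs incorrect",
            "AD: correct vs incorrect",
            "incorrect CTL vs incorrect AD",
        }
        assert (out.loc[out.variable == "age", "test"] == "t").all()
        assert (out.loc[out.variable == "sex", "test"] == "chi2").all()

    def test_progression_grouping(self, default_cohort):
        mci = default_cohort.subset(default_cohort.mask("MCI"))
        rng = np.random.default_rng(1)
        correct = rng.random(mci.n_subjects) < 0.6
        out = compare_subgroups(mci, correct, group_by="progression", month=12)
        assert any("MCI-s" in c for c in out["comparison"])
        assert any("MCI-p" in c for c in out["comparison"])


class TestAgeCorrelationTable:
    def test_same_sample_fit_removal_zeroes_ctl_correlation(self, small_manifest):
        # the detrender is the CTL least-squares fit, so corrected CTL
        # residuals are orthogonal to age: r after correction is 0 to 1e-10
        from .conftest import make_small_cohort

        table = make_small_cohort(small_manifest, n=30, seed=2)
        frame = table.frame.copy()
        ages = frame["age"].to_numpy()
        rng = np.random.default_rng(5)
        for j, name in enumerate(small_manifest.names):
            frame[name] = 2.0 + (j + 1) * 0.1 * ages + rng.normal(0, 0.5, len(ages))
        cohort = CohortTable(small_manifest, frame)
        ctl = cohort.mask("CTL")
        dm = fit_detrend(cohort.features()[ctl], cohort.ages[ctl])
        corrected_frame = cohort.frame.copy()
        corrected = apply_detrend(dm, cohort.features(), cohort.ages)
        corrected_frame[list(small_manifest.names)] = corrected
        out = age_correlation_table(cohort, CohortTable(small_manifest, corrected_frame))
        assert np.all(np.abs(out[("CTL", "after")].to_numpy()) < 1e-10)

    def test_default_slopes_give_strong_before_weak_after(self):
        cfg = SimulationConfig(n_ctl=1000, n_mci_s=0, n_mci_p=0, n_ad=0, seed=12)
        cohort = generate_cohort(cfg)
        ctl = cohort.mask("CTL")
        dm = fit_detrend(cohort.features()[ctl], cohort.ages[ctl])
        corrected_frame = cohort.frame.copy()
        corrected_frame[list(cohort.feature_names)] = apply_detrend(
            dm, cohort.features(), cohort.ages
        )
        out = age_correlation_table(
            cohort, CohortTable(cohort.manifest, corrected_frame)
        )
        before = out[("CTL", "before")].to_numpy()
        after = out[("CTL", "after")].to_numpy()
        assert np.median(np.abs(before)) > 0.3
        assert np.all(np.abs(after) < 0.05)

    def test_zero_slope_feature_unchanged_by_correction(self):
        cfg = SimulationConfig(n_ctl=1000, n_mci_s=0, n_mci_p=0, n_ad=0, seed=13)
        zero_j = list(cfg.feature_names).index("vessel_volume")
        assert cfg.age_slope[zero_j] == 0.0
        cohort = generate_cohort(cfg)
        ctl = cohort.mask("CTL")
        dm = fit_detrend(cohort.features()[ctl], cohort.ages[ctl])
        corrected_frame = cohort.frame.copy()
        corrected_frame[list(cohort.feature_names)] = apply_detrend(
            dm, cohort.features(), cohort.ages
        )
        out = age_correlation_table(
            cohort, CohortTable(cohort.manifest, corrected_frame)
        )
        r_b = out[("CTL", "before")].loc["vessel_volume"]
        r_a = out[("CTL", "after")].loc["vessel_volume"]
        assert abs(r_b - r_a) < 0.05

    def test_small_group_marked_nan(self, small_manifest):
        from .conftest import make_small_cohort

        table = make_small_cohort(small_manifest, n=4, seed=3)
        out = age_correlation_table(table, table)
        # with n=4 rows, at most two per diagnosis: all groups under 3
        assert out.isna().any().any()
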