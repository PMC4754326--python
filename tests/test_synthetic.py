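from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oplsage.age_correction import apply_detrend, fit_detrend
from oplsage.exceptions import ValidationError
from oplsage.synthetic_cohort import (
    SimulationConfig,
    confounded_scenario,
    generate_cohort,
)

from ._oracles import two_sample_mean_diff_se


class TestConfigValidation:
    def test_default_counts_match_reference_cohort(self):
        cfg = SimulationConfig()
        assert cfg.group_counts() == {"CTL": 340, "MCI-s": 360, "MCI-p": 85, "AD": 297}

    def test_mci_fraction_ordering_enforced(self):
        with pytest.raises(ValidationError):
            SimulationConfig(
                mci_s_fraction_of_ad_effect=0.8, mci_p_fraction_of_ad_effect=0.2
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_ad=-1)

    def test_round_trip_through_dict(self):
        cfg = SimulationConfig(seed=5)
        back = SimulationConfig.from_dict(cfg.to_dict())
        assert np.allclose(back.age_slope, cfg.age_slope)
        assert back.group_counts() == cfg.group_counts()


class TestGenerateCohort:
    def test_group_counts_exact(self, default_cohort):
        diag = default_cohort.diagnosis
        assert int((diag == "CTL").sum()) == 340
        assert int((diag == "MCI").sum()) == 445
        assert int((diag == "AD").sum()) == 297
        prog12 = default_cohort.progression_at(12)
        assert int((prog12 == "progressed").sum()) == 85
        assert int((prog12 == "stable").sum()) == 360

    def test_seeded_determinism_bit_identical(self):
        cfg = SimulationConfig(n_ctl=30, n_mci_s=20, n_mci_p=10, n_ad=30, seed=9)
        t1 = generate_cohort(cfg)
        t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_null_disease_effect_gives_null_group_difference(self):
        # with no disease effect, the age-detrended AD-CTL mean difference
        # is within 4 analytic SEs of zero for every feature
        base = SimulationConfig(seed=21)
        cfg = SimulationConfig(
            n_ctl=340,
            n_mci_s=0,
            n_mci_p=0,
            n_ad=297,
            disease_effect_ad=np.zeros(55),
            seed=21,
        )
        table = generate_cohort(cfg)
        ctl = table.mask("CTL")
        ad = table.mask("AD")
        X = table.features()
        ages = table.ages
        dm = fit_detrend(X[ctl], ages[ctl])
        Xc = apply_detrend(dm, X, ages)
        diff = Xc[ad].mean(axis=0) - Xc[ctl].mean(axis=0)
        se = two_sample_mean_diff_se(cfg.residual_sd, int(ad.sum()), int(ctl.sum()))
        assert np.all(np.abs(diff) < 4 * se)

    def test_ctl_age_slope_recovery(self):
        # refitting the per-feature age model on generated controls recovers
        # the configured slopes at n = 1000. The shared residual factors
        # correlate the 55 slope errors, so per-feature z-scores are judged
        # jointly: whitened by the known residual covariance they are iid
        # standard normal, and their chi-square sum must be consistent with
        # that null (0.999 quantile); the typical per-feature error stays
        # within 3 SE.
        cfg = SimulationConfig(n_ctl=1000, n_mci_s=0, n_mci_p=0, n_ad=0, seed=33)
        table = generate_cohort(cfg)
        X = table.features()
        ages = table.ages
        dm = fit_detrend(X, ages)
        a = ages - ages.mean()
        sxx = float(a @ a)
        err = dm.beta1 - cfg.age_slope
        # exact sampling covariance of the slope vector under the generator
        L = cfg.factor_loadings
        corr = L @ L.T + np.diag(1.0 - np.sum(L**2, axis=1))
        cov = corr * np.outer(cfg.residual_sd, cfg.residual_sd) / sxx
        t_stat = float(err @ np.linalg.solve(cov, err))
        from scipy.stats import chi2

        assert t_stat < chi2.ppf(0.999, df=55)
        se = cfg.residual_sd / np.sqrt(sxx)
        assert np.median(np.abs(err) / se) < 3.0

    def test_group_feature_means_ordered_by_severity(self):
        # for features with negative effects, means decrease along
        # CTL -> MCI-s -> MCI-p -> AD at large n
        cfg = SimulationConfig(
            n_ctl=2000, n_mci_s=2000, n_mci_p=2000, n_ad=2000, seed=17
        )
        table = generate_cohort(cfg)
        X = table.features()
        ages = table.ages
        dm = fit_detrend(X[table.mask("CTL")], ages[table.mask("CTL")])
        Xc = apply_detrend(dm, X, ages)
        prog = table.progression_at(12)
        groups = [
            table.mask("CTL"),
            table.mask("MCI") & (prog == "stable"),
            table.mask("MCI") & (prog == "progressed"),
            table.mask("AD"),
        ]
        neg = cfg.disease_effect_ad < -0.5  # strong negative effects
        means = np.array([Xc[g].mean(axis=0) for g in groups])
        for j in np.flatnonzero(neg):
            assert np.all(np.diff(means[:, j]) < 0)

    def test_progression_labels_consistent(self, default_cohort):
        mci = default_cohort.subset(default_cohort.mask("MCI"))
        p12 = mci.progression_at(12)
        adni = (mci.frame["cohort"] == "ADNI").to_numpy()
        # month-12 progressors stay progressed at every later month (ADNI)
        for m in (18, 24, 36):
            pm = mci.progression_at(m)
            assert np.all(pm[(p12 == "progressed") & adni] == "progressed")
            # non-ADNI subjects are not followed past month 12
            assert np.all(pm[~adni] == "unknown")
        # conversions are nested over time among ADNI subjects
        prev = mci.progression_at(18)[adni] == "progressed"
        for m in (24, 36):
            cur = mci.progression_at(m)[adni] == "progressed"
            assert np.all(cur[prev])
            prev = cur

    def test_non_mci_have_blank_progression(self, default_cohort):
        non_mci = default_cohort.subset(~default_cohort.mask("MCI"))
        for m in (12, 18, 24, 36):
            assert np.all(non_mci.progression_at(m) == "")

    def test_mmse_within_instrument_range(self, default_cohort):
        mmse = default_cohort.frame["mmse"]
        assert mmse.between(0, 30).all()

    def test_ages_within_support(self, default_cohort):
        assert default_cohort.ages.min() >= 55.0
        assert default_cohort.ages.max() <= 95.0


class TestConfoundedScenario:
    def test_zero_shift_is_identity(self):
        base = SimulationConfig(seed=1)
        assert confounded_scenario(base, 0.0).age_mean == base.age_mean

    def test_shift_lowers_only_ad_age_mean(self):
        base = SimulationConfig(seed=1)
        shifted = confounded_scenario(base, 5.0)
        assert shifted.age_mean["AD"] == base.age_mean["AD"] - 5.0
        for g in ("CTL", "MCI-s", "MCI-p"):
            assert shifted.age_mean[g] == base.age_mean[g]
        assert shifted.age_sd == base.age_sd

    def test_realized_ad_ages_track_the_shift(self):
        base = SimulationConfig(n_ctl=0, n_mci_s=0, n_mci_p=0, n_ad=1000, seed=2)
        shifted = confounded_scenario(base, 5.0)
        ages = generate_cohort(shifted).ages
        se = base.age_sd["AD"] / np.sqrt(1000)
        # truncation at [55, 95] pulls the realized mean slightly upward
        from scipy.stats import truncnorm

        lo, hi = base.age_range
        mu, sd = shifted.age_mean["AD"], base.age_sd["AD"]
        expected = truncnorm.mean((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
        assert abs(ages.mean() - expected) < 3 * se
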