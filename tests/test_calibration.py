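import numpy as np
import pandas as pd
import pytest

from actimet.calibration import (
    REGRESSION_BANK,
    fit_activity_regression,
    loso_calibrate,
    met_from_kcal,
    sleeping_hr,
    stationary_fixed_values,
)
from actimet.protocol import Activity, DYNAMIC_ACTIVITIES


def synthetic_bout_table(rng, n_subjects=14, amp_sd=0.06, see_scale=1.0):
    """Bout-level cohort table generated straight from the reference thigh
    regression bank (CPM anchored where the bank maps the study group METs)."""
    anchors = {
        "walking": [729, 986, 1313],
        "running": [1574, 1927, 2244],
        "cycling": [1538, 1861, 2211],
        "stairs": [847, 1222, 1657],
    }
    bank = REGRESSION_BANK["thigh"]
    rows = []
    for s in range(n_subjects):
        sex = 1 if s < (n_subjects + 1) // 2 else 2
        amp = 1 + amp_sd * rng.standard_normal()
        for act, cpms in anchors.items():
            reg = bank[Activity(act)]
            for c in cpms:
                cpm = c * amp
                met = (
                    reg.slope * cpm + reg.sex_coefficient * sex + reg.intercept
                    + rng.normal(0, reg.see * see_scale)
                )
                rows.append(dict(subject=f"S{s:02d}", sex=sex, activity=act,
                                 cpm=cpm, met=met))
        for act, m in (("lying", 1.27), ("sitting", 1.16), ("standing", 1.30)):
            rows.append(dict(subject=f"S{s:02d}", sex=sex, activity=act,
                             cpm=np.nan, met=m))
    return pd.DataFrame(rows)


class TestFitActivityRegression:
    def test_exact_line_recovery(self):
        cpm = np.array([500.0, 900.0, 1300.0, 1700.0])
        pts = pd.DataFrame({"cpm": cpm, "met": 0.003 * cpm + 1.282})
        reg = fit_activity_regression(pts, "walking")
        assert reg.slope == pytest.approx(0.003, abs=1e-12)
        assert reg.intercept == pytest.approx(1.282, abs=1e-9)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.see == pytest.approx(0.0, abs=1e-9)

    def test_two_point_line(self):
        pts = pd.DataFrame({"cpm": [0.0, 1000.0], "met": [1.0, 4.0]})
        reg = fit_activity_regression(pts, "walking")
        assert reg.slope == pytest.approx(0.003)
        assert reg.intercept == pytest.approx(1.0)

    def test_sex_covariate_recovery(self):
        rng = np.random.default_rng(0)
        cpm = rng.uniform(1000, 2500, 30)
        sex = rng.integers(1, 3, 30)
        met = 0.003 * cpm + 1.094 * sex - 1.132
        pts = pd.DataFrame({"cpm": cpm, "met": met, "sex": sex})
        reg = fit_activity_regression(pts, "cycling", with_sex_term=True)
        assert reg.slope == pytest.approx(0.003, abs=1e-12)
        assert reg.sex_coefficient == pytest.approx(1.094, abs=1e-9)
        assert reg.intercept == pytest.approx(-1.132, abs=1e-9)

    def test_matches_statsmodels_on_random_designs(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for i in range(100):
            n = int(rng.integers(4, 25))
            with_sex = bool(rng.integers(0, 2))
            pts = pd.DataFrame(
                {
                    "cpm": rng.uniform(0, 3000, n),
                    "met": rng.uniform(1, 12, n),
                    "sex": rng.integers(1, 3, n),
                }
            )
            cols = ["cpm"] + (["sex"] if with_sex else [])
            X = sm.add_constant(pts[cols].to_numpy())
            fit = sm.OLS(pts["met"].to_numpy(), X).fit()
            reg = fit_activity_regression(pts, "walking", with_sex_term=with_sex)
            assert reg.intercept == pytest.approx(fit.params[0], abs=1e-9)
            assert reg.slope == pytest.approx(fit.params[1], abs=1e-9)
            if with_sex:
                assert reg.sex_coefficient == pytest.approx(fit.params[2], abs=1e-9)
            assert reg.r2 == pytest.approx(fit.rsquared, abs=1e-9)
            assert reg.see == pytest.approx(
                np.sqrt(fit.ssr / fit.df_resid), abs=1e-9
            )

    def test_slope_coverage_under_noise(self):
        """With the study's residual scatter injected, the fitted slope lands
        within ±3 standard errors of the truth in ≥95% of replicates."""
        rng = np.random.default_rng(7)
        true_slope, true_icpt, see = 0.003, 1.282, 0.53
        hits = 0
        reps = 500
        for _ in range(reps):
            cpm = rng.uniform(700, 1400, 42)
            met = true_slope * cpm + true_icpt + rng.normal(0, see, 42)
            pts = pd.DataFrame({"cpm": cpm, "met": met})
            reg = fit_activity_regression(pts, "walking")
            sxx = ((cpm - cpm.mean()) ** 2).sum()
            se = reg.see / np.sqrt(sxx)
            hits += abs(reg.slope - true_slope) <= 3 * se
        assert hits / reps >= 0.95

    def test_degenerate_designs_rejected(self):
        pts = pd.DataFrame({"cpm": [5.0, 5.0, 5.0], "met": [1, 2, 3]})
        with pytest.raises(ValueError):
            fit_activity_regression(pts, "walking")
        with pytest.raises(ValueError):
            fit_activity_regression(pts.iloc[:1], "walking")


class TestLoso:
    def test_two_identical_subjects_give_identical_models(self):
        rng = np.random.default_rng(1)
        table = synthetic_bout_table(rng, n_subjects=1)
        other = table.copy()
        other["subject"] = "S99"
        both = pd.concat([table, other], ignore_index=True)
        models = loso_calibrate(both, "thigh")
        a, b = models["S00"], models["S99"]
        for act in a.regressions:
            assert a.regressions[act].slope == b.regressions[act].slope
            assert a.regressions[act].intercept == b.regressions[act].intercept

    def test_held_out_subject_never_influences_own_model(self):
        rng = np.random.default_rng(2)
        table = synthetic_bout_table(rng, n_subjects=6)
        models = loso_calibrate(table, "thigh", stationary_mode="loso_group_mean")
        corrupted = table.copy()
        mask = corrupted["subject"] == "S00"
        corrupted.loc[mask, "met"] = 999.0
        corrupted.loc[mask & corrupted["cpm"].notna(), "cpm"] = 0.0
        models2 = loso_calibrate(corrupted, "thigh",
                                 stationary_mode="loso_group_mean")
        r1, r2 = models["S00"].regressions, models2["S00"].regressions
        for act in r1:
            assert r1[act] == r2[act]
        assert models["S00"].fixed_mets == models2["S00"].fixed_mets

    def test_fewer_than_two_subjects_rejected(self):
        rng = np.random.default_rng(3)
        table = synthetic_bout_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            loso_calibrate(table, "thigh")

    def test_noiseless_cohort_recovers_bank_exactly(self, noiseless_cohort):
        """Full-pipeline parameter recovery: signals → counts → bout CPM →
        LOSO regressions reproduce the generating lines to ≤1e-6."""
        _, _, table = noiseless_cohort
        models = loso_calibrate(table, "thigh")
        bank = REGRESSION_BANK["thigh"]
        for model in models.values():
            for act in DYNAMIC_ACTIVITIES:
                got, truth = model.regressions[act.value], bank[act]
                assert abs(got.slope - truth.slope) <= 1e-6
                assert abs(got.intercept - truth.intercept) <= 1e-6
                assert abs(got.sex_coefficient - truth.sex_coefficient) <= 1e-6

    def test_separate_sex_cycling_switch(self):
        rng = np.random.default_rng(5)
        table = synthetic_bout_table(rng, n_subjects=8, see_scale=0.0)
        models = loso_calibrate(table, "thigh", cycling_sex_term=False)
        # each sex's points lie exactly on slope·CPM + (sex_coef·sex + b)
        bank = REGRESSION_BANK["thigh"][Activity.CYCLING]
        m_f = models["S00"]  # female subject: trained on other females' line
        assert m_f.regressions["cycling"].sex_coefficient == 0.0
        assert m_f.regressions["cycling"].intercept == pytest.approx(
            bank.sex_coefficient * 1 + bank.intercept, abs=1e-9
        )
        m_m = models["S07"]
        assert m_m.regressions["cycling"].intercept == pytest.approx(
            bank.sex_coefficient * 2 + bank.intercept, abs=1e-9
        )

    def test_study_scale_slope_recovery(self):
        """Median relative slope error over 200 seeded 14-subject cohorts
        with the study's residual scatter stays below 10%."""
        rng = np.random.default_rng(42)
        bank = REGRESSION_BANK["thigh"]
        errs = []
        for _ in range(200):
            table = synthetic_bout_table(rng)
            models = loso_calibrate(table, "thigh")
            for m in models.values():
                for act in DYNAMIC_ACTIVITIES:
                    truth = bank[act].slope
                    errs.append(abs(m.regressions[act.value].slope - truth) / truth)
        assert np.median(errs) < 0.10


class TestStationaryFixedValues:
    def _table(self):
        return pd.DataFrame(
            {
                "subject": ["A"] * 3 + ["B"] * 3,
                "activity": ["lying", "sitting", "standing"] * 2,
                "met": [1.2, 1.1, 1.3, 1.4, 1.2, 1.35],
            }
        )

    def test_own_subject_mode(self):
        out = stationary_fixed_values(self._table(), "A", "own_subject")
        assert out == {"lying": 1.2, "sitting": 1.1, "standing": 1.3}

    def test_loso_group_mean_mode(self):
        out = stationary_fixed_values(self._table(), "A", "loso_group_mean")
        assert out == {"lying": 1.4, "sitting": 1.2, "standing": 1.35}

    def test_modes_agree_on_homogeneous_cohort(self):
        t = self._table()
        t.loc[t["subject"] == "B", "met"] = [1.2, 1.1, 1.3]
        own = stationary_fixed_values(t, "A", "own_subject")
        loso = stationary_fixed_values(t, "A", "loso_group_mean")
        assert own == pytest.approx(loso)

    def test_missing_posture_rejected(self):
        t = self._table()
        t = t[t["activity"] != "standing"]
        with pytest.raises(ValueError):
            stationary_fixed_values(t, "A", "own_subject")


class TestHrAndUnits:
    def test_sleeping_hr_printed_drop(self):
        # 64 bpm resting → ~59 bpm predicted sleeping (−8%)
        assert sleeping_hr(np.full(720, 64.0)) == pytest.approx(58.88)
        assert round(sleeping_hr(np.full(720, 64.0))) == 59

    def test_sleeping_hr_uses_lowest_epoch(self):
        hr = np.concatenate([np.full(60, 70.0), np.full(60, 65.0),
                             np.full(60, 80.0)])
        assert sleeping_hr(hr) == pytest.approx(65 * 0.92)
        assert sleeping_hr(np.full(60, 100.0)) == pytest.approx(92.0)

    def test_sleeping_hr_short_series_rejected(self):
        with pytest.raises(ValueError):
            sleeping_hr(np.full(59, 64.0))

    def test_met_from_kcal(self):
        assert met_from_kcal(140.0, 68.4) == pytest.approx(2.0)
        assert met_from_kcal(70.0, 68.4) == pytest.approx(1.0)
        assert met_from_kcal(0.0, 80.0) == 0.0
        with pytest.raises(ValueError):
            met_from_kcal(100.0, 0.0)
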