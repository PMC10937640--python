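"""Survival statistics against brute-force oracles and generator recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from pericfat import riskstats as rs
from pericfat import simcohort as sc


def _toy_cohort(times, events):
    return pd.DataFrame(
        {
            "time_years": times,
            "event": [
                sc.EVENT_OTHER if e else sc.EVENT_CENSORED for e in events
            ],
        }
    )


class TestCox:
    def test_null_covariate_hr_near_one(self, small_cohort):
        df = small_cohort.copy()
        rng = np.random.default_rng(0)
        df["noise"] = rng.standard_normal(len(df))
        r = rs.fit_cox(df, ["noise"], "allcause")
        lo, hi = r.ci("noise")
        assert lo < 1.0 < hi
        assert r.hr("noise") == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_partial_likelihood_scan(self):
        # four subjects, binary covariate, all events, distinct times:
        # the Efron/Breslow partial likelihood has no ties and can be
        # maximized by a dense 1-D scan
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = [1, 1, 1, 1]
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_log_pl(beta):
            ll = 0.0
            for i in range(4):
                risk = [j for j in range(4) if times[j] >= times[i]]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-4, 4, 20001)
        beta_scan = grid[np.argmin([neg_log_pl(b) for b in grid])]

        df = _toy_cohort(times, events)
        df["xc"] = x
        r = rs.fit_cox(df, ["xc"], "allcause")
        assert np.log(r.hr("xc")) == pytest.approx(beta_scan, abs=1e-3)
        assert r.log_likelihood == pytest.approx(-neg_log_pl(beta_scan), abs=1e-6)

    def test_cv_endpoint_censors_other_deaths(self):
        df = pd.DataFrame(
            {
                "time_years": [1.0, 2.0, 3.0, 4.0],
                "event": [sc.EVENT_CV, sc.EVENT_OTHER, sc.EVENT_CENSORED, sc.EVENT_CV],
                "xc": [1.0, 0.0, 1.0, 0.0],
            }
        )
        r = rs.fit_cox(df, ["xc"], "cv")
        assert r.events == 2

    def test_zero_events_rejected(self):
        df = _toy_cohort([1.0, 2.0], [0, 0])
        df["xc"] = [0.0, 1.0]
        with pytest.raises(rs.CoxFitError):
            rs.fit_cox(df, ["xc"], "allcause")

    def test_univariable_equals_conditional_without_correlation(self):
        # with independent volume and density the univariable volume HR
        # equals the mutually adjusted one (no confounding path)
        import dataclasses

        p0 = dataclasses.replace(sc.DEFAULT_PARAMS, spearman_vol_dens=0.0)
        df = sc.simulate_cohort(p0, mode="allcause", n=40_000, seed=21)
        uni = rs.univariable_cox(df, "eat_vol", "allcause")
        adj = rs.fit_cox(df, ["eat_vol", "eat_dens"], "allcause")
        assert uni.hr("eat_vol_per10") == pytest.approx(
            adj.hr("eat_vol_per10"), abs=0.02
        )

    def test_univariable_attenuation_from_omitted_density(self):
        # omitted-variable algebra: beta_uni ~ beta_vol + beta_dens * slope
        # of density-per-10 on volume-per-10 under the default correlation
        df = sc.simulate_cohort(mode="allcause", n=100_000, seed=22)
        uni = rs.univariable_cox(df, "eat_vol", "allcause")
        slope = np.polyfit(df["eat_vol"] / 10, df["eat_dens"] / 10, 1)[0]
        expected = np.log(1.19) + np.log(1.66) * slope
        assert np.log(uni.hr("eat_vol_per10")) == pytest.approx(expected, abs=0.02)


class TestKaplanMeierLogrank:
    def test_km_steps_match_hand_calculation(self):
        # 6 subjects: events at 1, 3, censor at 2, events at 4, censor 5, 6
        df = _toy_cohort([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 0])
        res = rs.km_logrank(df, ["a", "a", "a", "b", "b", "b"], "allcause")
        ta, sa = res.curves["a"]
        # group a: n=3; S(1)=2/3; censor at 2; S(3)= 2/3 * (1-1/1) = 0
        assert sa[np.searchsorted(ta, 1.0)] == pytest.approx(2 / 3)
        assert sa[np.searchsorted(ta, 3.0)] == pytest.approx(0.0)
        tb, sb = res.curves["b"]
        # group b: n=3; event at 4 -> 2/3, censors after
        assert sb[np.searchsorted(tb, 4.0)] == pytest.approx(2 / 3)

    def test_identical_groups_null_statistic(self):
        df = _toy_cohort([1, 2, 3, 4, 1, 2, 3, 4], [1, 0, 1, 0, 1, 0, 1, 0])
        res = rs.km_logrank(df, ["a"] * 4 + ["b"] * 4, "allcause")
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.df == 1

    def test_single_group_rejected(self):
        df = _toy_cohort([1, 2], [1, 0])
        with pytest.raises(ValueError):
            rs.km_logrank(df, ["a", "a"], "allcause")

    def test_event_rate_rises_across_volume_quartiles(self):
        df = sc.simulate_cohort(mode="composite", n=60_000, seed=23)
        labels, _ = rs.quartile_categorize(df["eat_vol"])
        fr = [df.loc[labels == q, "death"].mean() for q in (2, 3, 4)]
        assert fr[0] < fr[1] < fr[2]
        res = rs.km_logrank(df, labels, "allcause")
        assert res.p < 1e-10


class TestCategorization:
    def test_cac_category_boundaries(self):
        out = rs.cac_categorize([0.0, 1.0, 100.0, 100.5, 101.0, 300.0, 300.5, 1000.0])
        assert list(out) == ["0", "1-100", "1-100", "101-300", "101-300", "101-300", ">300", ">300"]

    def test_uniform_quartiles(self):
        rng = np.random.default_rng(0)
        labels, bounds = rs.quartile_categorize(rng.random(200_000))
        np.testing.assert_allclose(bounds, [0.25, 0.5, 0.75], atol=0.01)
        counts = np.bincount(labels)[1:]
        assert counts.min() > 0.24 * 200_000

    def test_ln_cac_offset(self):
        np.testing.assert_allclose(rs.ln_cac([0.0, np.e - 1]), [0.0, 1.0])


def _brute_force_c(risk, times, events):
    conc = comp = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if events[i] and times[i] < times[j]:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / comp


class TestHarrellsC:
    def test_perfect_ranking_no_censoring(self):
        t = np.array([5.0, 3.0, 8.0, 1.0])
        assert rs.harrells_c(-t, t, np.ones(4)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 3000)
        e = rng.random(3000) < 0.6
        assert rs.harrells_c(rng.random(3000), t, e) == pytest.approx(0.5, abs=0.03)

    def test_censored_toy_matches_exhaustive_enumeration(self):
        risk = np.array([2.0, 1.0, 2.0, 0.5, 3.0])
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 0, 1, 1, 0])
        assert rs.harrells_c(risk, times, events) == pytest.approx(
            _brute_force_c(risk, times, events), rel=1e-12
        )

    def test_no_comparable_pairs_flagged(self):
        with pytest.raises(ValueError):
            rs.harrells_c([1.0, 2.0], [3.0, 4.0], [0, 0])

    def test_monotone_degradation_under_noise(self):
        df = sc.simulate_cohort(mode="allcause", n=4_000, seed=24)
        lp = (
            np.log(1.19) * df["eat_vol"] / 10 + np.log(1.66) * df["eat_dens"] / 10
        ).to_numpy()
        ev = df["death"].to_numpy()
        t = df["time_years"].to_numpy()
        rng = np.random.default_rng(0)
        c_true = rs.harrells_c(lp, t, ev)
        sd = lp.std()
        for scale in (1.0, 4.0):
            noisy = lp + scale * sd * rng.standard_normal(len(lp))
            assert c_true >= rs.harrells_c(noisy, t, ev) - 1e-9


class TestLikelihoodRatio:
    def test_identical_models_zero(self, small_cohort):
        a = rs.fit_cox(small_cohort, ["eat_vol"], "allcause")
        chi2, df, p = rs.lr_test(a, a)
        assert chi2 == 0.0 and df == 0

    def test_noise_covariate_null_distribution(self, small_cohort):
        df = small_cohort.copy()
        rng = np.random.default_rng(1)
        df["noise"] = rng.standard_normal(len(df))
        base = rs.fit_cox(df, ["eat_vol"], "allcause")
        full = rs.fit_cox(df, ["eat_vol", "noise"], "allcause")
        chi2, dof, p = rs.lr_test(base, full)
        assert dof == 1
        assert chi2 < spstats.chi2.ppf(0.999, 1)  # not a significant gain

    def test_true_signal_dominates(self, small_cohort):
        rng = np.random.default_rng(2)
        df = small_cohort.copy()
        df["noise"] = rng.standard_normal(len(df))
        base = rs.fit_cox(df, ["noise"], "allcause")
        full = rs.fit_cox(df, ["noise", "eat_vol", "eat_dens"], "allcause")
        chi2, dof, p = rs.lr_test(base, full)
        assert dof == 2
        assert chi2 > spstats.chi2.ppf(0.999999, 2)

    def test_non_nested_rejected(self, small_cohort):
        a = rs.fit_cox(small_cohort, ["eat_vol"], "allcause")
        b = rs.fit_cox(small_cohort, ["eat_dens"], "allcause")
        with pytest.raises(ValueError):
            rs.lr_test(a, b)

    def test_named_models_structurally_nested(self):
        m1 = set(rs.MODEL_COVARIATES["model1"])
        m2 = set(rs.MODEL_COVARIATES["model2"])
        m3 = set(rs.MODEL_COVARIATES["model3"])
        assert m1 < m2 < m3

    def test_fully_adjusted_model_fits_with_categoricals(self, small_cohort):
        sub = small_cohort.sample(6000, random_state=1)
        m2 = rs.fit_model(sub, "model2", "allcause")
        m3 = rs.fit_model(sub, "model3", "allcause")
        # dummy-coded race/ethnicity/education are in the design
        assert any(c.startswith("race_") for c in m3.table.index)
        assert any(c.startswith("education_") for c in m3.table.index)
        assert len(m3.table) == len(m2.table) + 1  # + ln-CAC
        # null-effect adjusters leave the true EAT signal intact
        assert m2.hr("eat_vol_per10") == pytest.approx(1.19, abs=0.07)


def _brute_force_cnri(old, new, events):
    ev = [i for i, e in enumerate(events) if e]
    ne = [i for i, e in enumerate(events) if not e]
    up_e = sum(new[i] > old[i] for i in ev)
    dn_e = sum(new[i] < old[i] for i in ev)
    up_n = sum(new[i] > old[i] for i in ne)
    dn_n = sum(new[i] < old[i] for i in ne)
    return (up_e - dn_e) / len(ev) + (dn_n - up_n) / len(ne)


class TestContinuousNRI:
    def test_identical_scores_zero(self):
        r = rs.continuous_nri([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 0, 1])
        assert r.cnri_total == 0.0

    def test_perfect_reclassification_is_two(self):
        old = [1.0, 1.0, 1.0, 1.0]
        new = [2.0, 2.0, 0.0, 0.0]
        r = rs.continuous_nri(old, new, [1, 1, 0, 0])
        assert r.cnri_total == 2.0
        assert r.cnri_events == 1.0 and r.cnri_nonevents == 1.0

    def test_eight_subject_toy_matches_enumeration(self):
        old = np.array([0.1, 0.4, 0.35, 0.8, 0.5, 0.9, 0.05, 0.6])
        new = np.array([0.2, 0.3, 0.35, 0.9, 0.4, 0.8, 0.15, 0.7])
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        r = rs.continuous_nri(old, new, events)
        assert r.cnri_total == pytest.approx(
            _brute_force_cnri(old, new, events), rel=1e-12
        )

    def test_all_same_class_rejected(self):
        with pytest.raises(ValueError):
            rs.continuous_nri([1.0, 2.0], [2.0, 1.0], [1, 1])

    def test_uninformative_addition_centers_on_zero(self):
        # replicated small cohorts: adding noise to the score produces
        # cNRI values centered on zero
        rng = np.random.default_rng(5)
        vals = []
        for rep in range(20):
            df = sc.simulate_cohort(mode="allcause", n=800, seed=100 + rep)
            old = (df["eat_vol"] / 10).to_numpy()
            new = old + 0.5 * rng.standard_normal(len(df))
            vals.append(rs.continuous_nri(old, new, df["death"]).cnri_total)
        assert abs(np.mean(vals)) < 0.05


class TestPredictedRisk:
    def test_risk_calibrated_to_event_rate(self, small_cohort):
        r = rs.fit_cox(small_cohort, ["eat_vol", "eat_dens"], "allcause")
        risk = rs.predicted_risk(small_cohort, r, horizon_years=13.2)
        assert risk.mean() == pytest.approx(small_cohort["death"].mean(), abs=0.02)
        assert ((0 <= risk) & (risk <= 1)).all()

    def test_informative_addition_gives_positive_cnri(self, small_cohort):
        base = rs.fit_cox(small_cohort, ["age"], "allcause")  # null covariate
        full = rs.fit_cox(small_cohort, ["age", "eat_vol", "eat_dens"], "allcause")
        rb = rs.predicted_risk(small_cohort, base, 12.3)
        rf = rs.predicted_risk(small_cohort, full, 12.3)
        nri = rs.continuous_nri(rb, rf, small_cohort["death"])
        assert nri.cnri_total > 0.1


class TestDiscriminationHelper:
    def test_linear_predictor_concordance(self, small_cohort):
        r = rs.fit_cox(small_cohort, ["eat_vol", "eat_dens"], "allcause")
        base = rs.fit_cox(small_cohort, ["eat_vol"], "allcause")
        d = rs.discrimination(small_cohort.sample(4000, random_state=0), r, nested=base)
        assert 0.5 < d.harrells_c < 1.0
        assert d.lr_chi2 is not None and d.df == 1
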