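"""Cox fitting, risk stratification, KM/log-rank, contributions."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from kinsig.survival import (
    SignatureSurvivalModel,
    SurvivalCohort,
    dichotomize_median,
    fit_cox,
    group_hazard_ratio,
    km_estimate,
    leave_one_out_contributions,
    logrank_test,
    multivariate_cox,
    prognostic_index,
    signature_hr,
    single_gene_hr,
)
from kinsig.synthetic import SyntheticConfig, generate_survival_cohort

from conftest import make_cohort


def efron_log_partial_likelihood(beta, times, events, x):
    """Independent transcription of the Efron-tie partial log-likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        s_r = theta[R].sum()
        s_d = theta[D].sum()
        ll += beta * x[D].sum()
        for ell in range(d):
            ll -= np.log(s_r - (ell / d) * s_d)
    return ll


def brute_force_beta(times, events, x):
    res = minimize_scalar(
        lambda b: -efron_log_partial_likelihood(b, times, events, x),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


def _one_covariate_cohort(times, events, x):
    n = len(times)
    return SurvivalCohort(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "ttt_months": times, "ttt_event": events,
                "os_months": times, "os_event": events,
                "ighv": "mutated", "del17p": 0,
                "g": x,
            }
        )
    )


# Non-degenerate <=6-subject instances (times, events, covariate),
# including tied event times; the brute-force maximizer is finite for all.
COX_INSTANCES = [
    ((1, 2, 3, 4), (1, 1, 1, 0), (1, 0, 1, 0)),
    ((1, 2, 3, 4), (1, 1, 1, 1), (0, 1, 0, 1)),
    ((2, 2, 3, 5), (1, 1, 1, 1), (1, 0, 0, 1)),          # tie at t=2
    ((1, 1, 1, 2), (1, 1, 0, 1), (0, 1, 1, 0)),          # triple tie, censor
    ((1, 2, 2, 3, 4), (1, 1, 1, 0, 1), (0.5, -1, 2, 0, 1)),
    ((1, 1, 2, 3, 3, 4), (1, 1, 1, 1, 1, 0), (1, 0, 1, 0, 1, 0)),
    ((3, 1, 4, 1, 5, 2), (1, 1, 0, 1, 1, 1), (-1, 2, 0, 1, -2, 0.5)),
    ((1, 2, 3, 4, 5, 6), (1, 0, 1, 0, 1, 0), (2, 1, 0, -1, 1, 0)),
    ((2, 2, 2, 2), (1, 1, 1, 1), (1, 0, 2, -1)),          # all tied
    ((1, 2, 3, 4, 5), (1, 1, 1, 1, 1), (0.1, 0.9, -0.5, 0.4, 0.2)),
]


class TestCoxOracle:
    @pytest.mark.parametrize("times,events,x", COX_INSTANCES)
    def test_matches_brute_force_partial_likelihood(self, times, events, x):
        expected = brute_force_beta(times, events, x)
        assert abs(expected) < 5  # instance is non-degenerate
        fit = fit_cox(_one_covariate_cohort(times, events, x), ["g"], "ttt")
        assert fit.betas["g"] == pytest.approx(expected, abs=1e-3)

    def test_monotone_likelihood_instance_flagged(self):
        # Events 1,1,1,0 at times 1..4 with covariate 0,0,1,1: the partial
        # likelihood increases without bound as beta -> -inf (no finite MLE).
        cohort = _one_covariate_cohort((1, 2, 3, 4), (1, 1, 1, 0), (0, 0, 1, 1))
        fit = fit_cox(cohort, ["g"], "ttt")
        assert not fit.converged

    def test_duplicating_subjects_leaves_beta_unchanged(self):
        times, events, x = COX_INSTANCES[4]
        single = fit_cox(_one_covariate_cohort(times, events, x), ["g"], "ttt")
        double = fit_cox(
            _one_covariate_cohort(times * 2, events * 2, x * 2), ["g"], "ttt"
        )
        assert double.betas["g"] == pytest.approx(single.betas["g"], abs=1e-6)

    def test_no_events_and_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox(_one_covariate_cohort((1, 2), (0, 0), (0, 1)), ["g"], "ttt")
        with pytest.raises(ValueError, match="constant"):
            fit_cox(_one_covariate_cohort((1, 2, 3, 4, 5, 6), (1,) * 6, (1,) * 6), ["g"], "ttt")

    def test_null_covariate_wald_coverage(self, rng):
        inside = 0
        for _ in range(60):
            cohort = make_cohort(rng, 300, {"A": 0.0}, {"A": 0.0})
            fit = fit_cox(cohort, ["A"], "ttt")
            inside += abs(fit.betas["A"]) < 3 * fit.se["A"]
        assert inside >= 57  # |beta| < 3 SE in >= 95% of null seeds


class TestPrognosticIndex:
    def test_formula_and_degenerate_cases(self, rng):
        cohort = make_cohort(rng, 20, {"A": 0.5, "B": -0.2})
        fit = fit_cox(cohort, ["A", "B"], "ttt")
        pi = prognostic_index(fit, cohort)
        X = cohort.data[["A", "B"]].to_numpy()
        np.testing.assert_allclose(pi, X @ fit.betas.to_numpy())
        fit.betas[:] = 0.0
        assert (prognostic_index(fit, cohort) == 0).all()
        fit.betas[:] = [np.log(2), 0.0]
        cohort.data.loc[:, "A"] = 3.0
        cohort.data.loc[0, "A"] = 3.0
        assert prognostic_index(fit, cohort).iloc[0] == pytest.approx(3 * np.log(2))

    def test_missing_covariate_named(self, rng):
        cohort = make_cohort(rng, 10, {"A": 0.5})
        fit = fit_cox(cohort, ["A"], "ttt")
        fit.covariates = ["A", "GHOST"]
        fit.betas = pd.Series([0.1, 0.2], index=["A", "GHOST"])
        with pytest.raises(KeyError, match="GHOST"):
            prognostic_index(fit, cohort)

    def test_covariate_shift_preserves_ordering(self, rng):
        cohort = make_cohort(rng, 50, {"A": 0.5, "B": 0.3})
        fit = fit_cox(cohort, ["A", "B"], "ttt")
        pi = prognostic_index(fit, cohort)
        shifted = SurvivalCohort(cohort.data.assign(A=cohort.data["A"] + 7.0))
        pi2 = prognostic_index(fit, shifted)
        assert (np.argsort(pi.to_numpy()) == np.argsort(pi2.to_numpy())).all()
        np.testing.assert_allclose(pi2 - pi, 7.0 * fit.betas["A"])


class TestDichotomize:
    def test_even_odd_and_tie_rules(self):
        lab = dichotomize_median(np.arange(1, 11))
        assert (lab[:5] == "low").all() and (lab[5:] == "high").all()
        lab7 = dichotomize_median(np.arange(7))
        assert (lab7 == "low").sum() == 4 and (lab7 == "high").sum() == 3

    def test_permutation_invariant_per_sample(self, rng):
        values = rng.standard_normal(21)
        ids = np.array([f"s{i}" for i in range(21)])
        base = dichotomize_median(values, ids).sort_index()
        perm = rng.permutation(21)
        again = dichotomize_median(values[perm], ids[perm]).sort_index()
        pd.testing.assert_series_equal(base, again)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_median(np.ones(10))


class TestGroupHazardRatio:
    def test_label_swap_inverts_hr(self, rng):
        cohort = make_cohort(rng, 120, {"A": 1.0})
        labels = dichotomize_median(cohort.data["A"].to_numpy()).to_numpy()
        hr = group_hazard_ratio(cohort, labels, "ttt").hr
        swapped = np.where(labels == "low", "high", "low")
        hr_inv = group_hazard_ratio(cohort, swapped, "ttt").hr
        assert hr_inv == pytest.approx(1.0 / hr, rel=1e-6)

    def test_zero_event_group_flagged_not_crashed(self):
        cohort = _one_covariate_cohort(
            (1, 2, 3, 10, 11, 12, 13, 14), (1, 1, 1, 0, 0, 0, 0, 0),
            (1, 1, 1, 0, 0, 0, 0, 0),
        )
        labels = np.array(["high"] * 3 + ["low"] * 5)
        res = group_hazard_ratio(cohort, labels, "ttt")
        assert res.flagged and res.hr == np.inf

    def test_planted_group_hr_recovered(self, rng):
        hits = 0
        for _ in range(40):
            n = 500
            g = np.repeat([0.0, 1.0], n // 2)
            t = rng.exponential(1.0, n) / ((1 / 40) * np.exp(np.log(3) * g))
            cohort = _one_covariate_cohort(t, np.ones(n, int), g)
            labels = np.where(g == 1, "high", "low")
            hr = group_hazard_ratio(cohort, labels, "ttt").hr
            hits += 2.4 <= hr <= 3.75
        assert hits >= 38


class TestKaplanMeierAndLogrank:
    def test_no_events_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_uncensored_steps(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        steps = km.sort_values("time")["survival"].tolist()
        assert steps == pytest.approx([1.0, 0.75, 0.5, 0.25, 0.0])

    def test_censoring_worked_example(self):
        # subjects: events at 1, 2, 3, 4; censored at 2.5 and 5
        km = km_estimate([1, 2, 2.5, 3, 4, 5], [1, 1, 0, 1, 1, 0])
        surv = km.set_index("time")["survival"]
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[2.0] == pytest.approx(4 / 6)
        assert surv[3.0] == pytest.approx(4 / 9)   # risk set shrank to 3
        assert surv[4.0] == pytest.approx(2 / 9)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 40).round(1)
        km = km_estimate(t, np.ones(40, int))
        for row in km.itertuples():
            assert row.survival == pytest.approx((t > row.time).mean())

    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        stat, p = logrank_test(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_consistent_with_permutation_null(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.8).astype(int)
        labels = np.array(["a"] * 15 + ["b"] * 15)
        stat, p = logrank_test(t, e, labels)
        perm_stats = []
        for _ in range(2000):
            perm_stats.append(logrank_test(t, e, rng.permutation(labels))[0])
        p_perm = np.mean(np.asarray(perm_stats) >= stat)
        se = np.sqrt(p_perm * (1 - p_perm) / 2000) + 1e-3
        assert abs(p - p_perm) < 4 * se + 0.02

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestSignatureAnalyses:
    def test_single_gene_signature_equals_single_gene_hr(self, rng):
        cohort = make_cohort(rng, 200, {"A": 0.8})
        a = single_gene_hr(cohort, "A", "ttt")
        b = signature_hr(cohort, ["A"], "ttt")
        # with beta>0 the PI is a monotone map of expression: same split
        assert b.hr == pytest.approx(a.hr, rel=1e-9)

    def test_constant_gene_propagates_error(self, rng):
        cohort = make_cohort(rng, 30, {"A": 0.5})
        cohort.data["A"] = 1.0
        with pytest.raises(ValueError, match="identical"):
            single_gene_hr(cohort, "A", "ttt")

    def test_gene_order_invariance(self, rng):
        cohort = make_cohort(rng, 150, {"A": 0.8, "B": -0.4, "C": 0.2})
        hr1 = signature_hr(cohort, ["A", "B", "C"], "ttt").hr
        hr2 = signature_hr(cohort, ["C", "A", "B"], "ttt").hr
        assert hr1 == pytest.approx(hr2, rel=1e-9)

    def test_combined_signature_beats_individual_drivers(self, rng):
        wins = 0
        for _ in range(40):
            betas = {f"D{i}": 0.8 for i in range(5)}
            cohort = make_cohort(rng, 500, betas)
            sig = signature_hr(cohort, list(betas), "ttt").hr
            best = max(single_gene_hr(cohort, g, "ttt").hr for g in betas)
            wins += sig > best
        assert wins >= 32  # >= 80% of seeds

    def test_pure_noise_signature_hr_stays_modest(self, rng):
        hrs = []
        for _ in range(60):
            genes = {f"N{i}": 0.0 for i in range(8)}
            cohort = make_cohort(rng, 107, genes)
            hrs.append(signature_hr(cohort, list(genes), "ttt").hr)
        assert np.median(hrs) < 2.0  # overfitting stays bounded

    def test_leave_one_out_driver_dominates(self, rng):
        wins = 0
        for _ in range(30):
            cohort = make_cohort(rng, 500, {"DRIVER": 1.2, "NOISE": 0.0})
            out = leave_one_out_contributions(cohort, ["DRIVER", "NOISE"], "ttt")
            wins += out.iloc[0]["gene"] == "DRIVER"
        assert wins >= 27  # >= 90% of seeds

    def test_loo_k_validation(self, rng):
        cohort = make_cohort(rng, 60, {"A": 0.5, "B": 0.0})
        with pytest.raises(ValueError, match="exceeds pool"):
            leave_one_out_contributions(cohort, ["A", "B"], "ttt", k=3)
        with pytest.raises(ValueError, match=">= 2 genes"):
            leave_one_out_contributions(cohort, ["A"], "ttt")

    def test_model_results_summary(self, rng):
        cohort = make_cohort(rng, 150, {"A": 0.8, "B": 0.0})
        res = SignatureSurvivalModel(cohort, ["A", "B"], "ttt").fit(k=2)
        text = res.summary()
        assert "combined HR" in text and "A" in text
        assert res.hr > 0


class TestMultivariate:
    def test_planted_effects_recovered(self):
        cfg = SyntheticConfig(
            seed=13, cohort_n=1000, true_betas_ttt={"DNPEP": 0.6},
            true_betas_os={}, cohort_noise_genes=0,
            beta_ighv=0.0, beta_del17p=0.9,
        )
        cohort, _ = generate_survival_cohort(cfg)
        res = multivariate_cox(cohort, "ttt", gene="DNPEP")
        fit = res["multivariate"]
        assert fit.p_values["DNPEP_high"] < 0.01
        assert abs(fit.betas["del17p"] - 0.9) < 3 * fit.se["del17p"]
        assert set(res["univariate"]) == {"DNPEP_high", "ighv_unmutated", "del17p"}

    def test_unknown_ighv_excluded_listwise(self, rng):
        cohort = make_cohort(rng, 200, {"DNPEP": 0.8})
        data = cohort.data.copy()
        data.loc[:29, "ighv"] = "unknown"
        data.loc[30:120, "ighv"] = "unmutated"
        data.loc[:, "del17p"] = (rng.random(200) < 0.3).astype(int)
        res = multivariate_cox(SurvivalCohort(data), "ttt", gene="DNPEP")
        assert res["n"] == 170

    def test_constant_covariate_named(self, rng):
        cohort = make_cohort(rng, 100, {"DNPEP": 0.8})
        cohort.data["ighv"] = ["mutated", "unmutated"] * 50
        cohort.data["del17p"] = 0
        with pytest.raises(ValueError, match="del17p"):
            multivariate_cox(cohort, "ttt", gene="DNPEP")
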