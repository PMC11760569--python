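"""Survival, composition, t-test and single-observation inference tests.

lifelines serves as the independent oracle for the survival machinery; the
package's own product-limit and log-rank implementations are under test.
"""

import numpy as np
import pandas as pd
import pytest

from apoetraj.ahmm import FitResult
from apoetraj.validation import (
    SurvivalRecord, adipose_index, compare_cs_across_states, contingency_chisq,
    infer_state_single_obs, km_estimate, logrank_test, median_survival,
    survival_records, welch_ttest,
)

from conftest import random_params
from oracles import emission_logpdf_oracle
from test_ahmm import uniform_params


def rec(t, e, mid="m", group=None):
    return SurvivalRecord(mid, t, e, group)


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        km = km_estimate([rec(10, 1, "a"), rec(20, 1, "b"), rec(30, 1, "c")])
        assert np.allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate([rec(10, 0, "a"), rec(20, 0, "b")])
        assert km.empty  # no event rows; curve stays at 1

    def test_hand_computed_mixed_table(self):
        # deaths at 5, 10, 15; censored at 7 and 12:
        # S(5)=4/5; S(10)=4/5*2/3=8/15; S(15)=8/15*0=0
        records = [rec(5, 1, "a"), rec(7, 0, "b"), rec(10, 1, "c"),
                   rec(12, 0, "d"), rec(15, 1, "e")]
        km = km_estimate(records)
        assert np.allclose(km["survival"], [4 / 5, 8 / 15, 0.0], atol=1e-12)
        assert list(km["n_at_risk"]) == [5, 3, 1]

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter
        for _ in range(25):
            n = int(rng.integers(3, 40))
            times = rng.integers(1, 30, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            records = [rec(t, int(e), f"m{i}")
                       for i, (t, e) in enumerate(zip(times, events))]
            km = km_estimate(records)
            kmf = KaplanMeierFitter().fit(times, events)
            for _, row in km.iterrows():
                ref = float(kmf.survival_function_at_times(row["time"]).iloc[0])
                assert row["survival"] == pytest.approx(ref, abs=1e-8)


class TestMedianSurvival:
    def test_exact_hit(self):
        km = pd.DataFrame({"time": [10.0, 24.0], "n_at_risk": [4, 2],
                           "n_events": [2, 1], "survival": [0.5, 0.25]})
        assert median_survival(km) == 10.0

    def test_curve_never_reaching_half_undefined(self):
        km = pd.DataFrame({"time": [10.0], "n_at_risk": [10],
                           "n_events": [2], "survival": [0.8]})
        assert median_survival(km) is None

    def test_scan_matches_estimator_output(self):
        records = [rec(5, 1, "a"), rec(7, 0, "b"), rec(10, 1, "c"),
                   rec(12, 0, "d"), rec(15, 1, "e")]
        km = km_estimate(records)
        direct = min(t for t, s in zip(km["time"], km["survival"]) if s <= 0.5)
        assert median_survival(km) == direct


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [rec(10, 1, "a"), rec(20, 1, "b"), rec(30, 0, "c")]
        chi2, df, p = logrank_test([g, list(g)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_two_group(self):
        # one death per group, no censoring: at t=1 (group 1 dies)
        # E1 = 0.5, V = 0.25; t=2 contributes nothing -> chi2 = 1.0
        chi2, df, p = logrank_test([[rec(1, 1, "a")], [rec(2, 1, "b")]])
        assert chi2 == pytest.approx(1.0, abs=1e-10)
        from scipy.stats import chi2 as chi2_dist
        assert p == pytest.approx(chi2_dist.sf(1.0, 1), abs=1e-12)

    def test_matches_lifelines_multivariate(self, rng):
        from lifelines.statistics import multivariate_logrank_test
        for _ in range(25):
            K = int(rng.integers(2, 4))
            groups = []
            for k in range(K):
                n = int(rng.integers(4, 25))
                times = rng.integers(1, 30, n).astype(float)
                events = rng.integers(0, 2, n)
                groups.append([rec(t, int(e), f"g{k}m{i}")
                               for i, (t, e) in enumerate(zip(times, events))])
            if sum(r.event for g in groups for r in g) == 0:
                continue
            chi2, df, p = logrank_test(groups)
            times = np.concatenate([[r.time_months for r in g] for g in groups])
            events = np.concatenate([[r.event for r in g] for g in groups])
            labels = np.concatenate([[k] * len(g) for k, g in enumerate(groups)])
            ref = multivariate_logrank_test(times, labels, events)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_separated_hazards_detected(self):
        """Exponential groups with hazard 0.02 vs 0.10 per month at n=100
        should reject essentially always."""
        hits = 0
        n_trials = 30
        for seed in range(n_trials):
            r = np.random.default_rng(seed)
            g1 = [rec(t, 1, f"a{i}") for i, t in enumerate(r.exponential(50, 100))]
            g2 = [rec(t, 1, f"b{i}") for i, t in enumerate(r.exponential(10, 100))]
            _, _, p = logrank_test([g1, g2])
            hits += p < 0.001
        assert hits >= 0.95 * n_trials


class TestSurvivalRecords:
    def test_sacrificed_mice_excluded_and_censoring_at_last_visit(self):
        from test_colony import make_mouse
        mice = [
            make_mouse("nat", death="2020-06-01", death_cause="natural"),
            make_mouse("sac", death="2020-06-01", death_cause="sacrificed"),
            make_mouse("alive"),
        ]
        records = survival_records(mice)
        by_id = {r.mouse_id: r for r in records}
        assert "sac" not in by_id
        assert by_id["nat"].event == 1
        assert by_id["alive"].event == 0
        assert by_id["alive"].time_months == pytest.approx(8.0, abs=0.1)

    def test_unrelated_flags_do_not_change_results(self):
        from test_colony import make_mouse
        a = make_mouse("m", death="2020-06-01", death_cause="natural")
        b = make_mouse("m", death="2020-06-01", death_cause="natural", breeder=True)
        b.genotype = "E4/4"
        ra, rb = survival_records([a]), survival_records([b])
        assert ra[0].time_months == rb[0].time_months
        assert ra[0].event == rb[0].event


class TestContingency:
    def test_identical_composition_statistic_zero(self):
        groups = {"A": ["f"] * 10 + ["m"] * 10, "B": ["f"] * 10 + ["m"] * 10}
        chi2, df, p, _ = contingency_chisq(groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # [[10,20],[20,10]]: expected 15 everywhere, chi2 = 4*25/15 = 6.667
        groups = {"A": ["x"] * 10 + ["y"] * 20, "B": ["x"] * 20 + ["y"] * 10}
        chi2, df, p, expected = contingency_chisq(groups)
        assert chi2 == pytest.approx(20 / 3, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(0.00982, abs=1e-5)
        assert np.allclose(expected.values, 15.0)

    def test_pairwise_mode_restricts_groups(self):
        groups = {"A": ["x"] * 10 + ["y"] * 20, "B": ["x"] * 20 + ["y"] * 10,
                  "C": ["x"] * 25 + ["y"] * 5}
        chi2_all, *_ = contingency_chisq(groups)
        chi2_ab, *_ = contingency_chisq(groups, pairwise=("A", "B"))
        assert chi2_ab == pytest.approx(20 / 3, abs=1e-10)
        assert chi2_all != pytest.approx(chi2_ab)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_value(self):
        t, df, p = welch_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-9)

    def test_pooled_flag_matches_student(self):
        from scipy.stats import ttest_ind
        a, b = [1.0, 2.0, 3.5, 2.2], [4.0, 5.5, 6.0]
        t, df, p = welch_ttest(a, b, pooled=True)
        ref = ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)

    def test_power_on_shifted_gaussians(self):
        """Delta = 2 sigma at n=20/20 rejects at alpha=0.01 nearly always."""
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            r = np.random.default_rng(seed)
            a, b = r.normal(0, 1, 20), r.normal(2, 1, 20)
            hits += welch_ttest(a, b)[2] < 0.01
        assert hits >= 95


class TestAdiposeIndex:
    def test_formula_examples(self):
        assert adipose_index(10, 30, 0) == pytest.approx(25.0)
        assert adipose_index(0, 25, 0.4) == 0.0

    def test_random_triples_match_direct_formula(self, rng):
        for _ in range(50):
            f, l, w = rng.uniform(0.01, 30, 3)
            assert adipose_index(f, l, w) == pytest.approx(100 * f / (f + l + w))
            assert 0 <= adipose_index(f, l, w) <= 100

    def test_invalid_masses_raise(self):
        with pytest.raises(ValueError):
            adipose_index(-1, 10, 1)
        with pytest.raises(ValueError):
            adipose_index(0, 0, 0)


class TestSingleObsInference:
    def test_single_state_posterior_is_one(self, rng):
        p = random_params(rng, 1)
        post, label = infer_state_single_obs(p, 12.0, 30.0, 0, 0)
        assert post == pytest.approx([1.0]) and label == "A"

    def test_far_separated_means_dominate(self):
        p = uniform_params(2, w0_intercept=np.array([20.0, 60.0]))
        post, label = infer_state_single_obs(p, 15.0, 20.0, 0, 0,
                                             prior_mode="initial")
        assert label == "A" and post[0] > 0.99

    def test_matches_bayes_rule_oracle(self, rng):
        from apoetraj.trajectories import stationary_distribution
        for _ in range(20):
            p = random_params(rng, 3)
            age, w = rng.uniform(5, 28), rng.uniform(15, 45)
            sex, geno = int(rng.integers(2)), int(rng.integers(3))
            post, _ = infer_state_single_obs(p, age, w, sex, geno)
            prior = stationary_distribution(p.A, pi=p.pi)
            log_ref = np.log(prior) + np.array([
                emission_logpdf_oracle(p, i, age, w, None, sex, geno)
                for i in range(3)])
            ref = np.exp(log_ref - log_ref.max())
            ref /= ref.sum()
            assert np.allclose(post, ref, atol=1e-12)


class TestCrossSectionalComparison:
    def _frame(self, values_by_state, measurement="glucose"):
        rows = [{"measurement": measurement, "state": s, "value": v}
                for s, vals in values_by_state.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_values_give_p_one(self):
        cs = self._frame({"A": [5.0] * 4, "B": [5.0] * 4})
        out = compare_cs_across_states(cs)
        assert (out["p"].dropna() == 1.0).all()

    def test_single_populated_state_yields_note_only(self):
        cs = self._frame({"A": [5.0, 6.0], "B": [7.0]})
        out = compare_cs_across_states(cs)
        assert out["p"].isna().all()
        assert (out["note"] == "fewer than 2 records").any()

    def test_state_dependent_means_detected_with_holm_column(self):
        r = np.random.default_rng(1)
        cs = self._frame({"A": r.normal(100, 5, 25), "B": r.normal(140, 5, 25)})
        out = compare_cs_across_states(cs)
        row = out.dropna(subset=["p"]).iloc[0]
        assert row["p"] < 0.001
        assert row["p_holm"] >= row["p"]
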