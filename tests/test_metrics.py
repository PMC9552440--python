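"""Survival metrics against exhaustive oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aesurv.exceptions import ContractError
from aesurv.metrics import (
    aggregate_folds,
    brier_score,
    brier_score_at,
    concordance_index,
    covariate_tests,
    cox_compare,
    logrank_test,
)


def brute_force_cindex(time, event, risk):
    """Pair-by-pair enumeration of Harrell's C (independent oracle)."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def manual_logrank(time, event, group):
    """Risk-table tally of the two-group log-rank statistic (oracle)."""
    o1 = e1 = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v
    return chi2, stats.chi2.sf(chi2, 1)


class TestConcordance:
    def test_perfect_ranking(self):
        assert concordance_index([1, 3, 5], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_all_risks_tied(self):
        assert concordance_index([1, 3, 5], [1, 1, 1], [2, 2, 2]) == 0.5

    def test_censored_example_matches_pair_enumeration(self):
        """Permissible pairs: strictly shorter time with an event; here 5
        pairs, 4 concordant (the t=4 event vs t=6 censored pair is
        discordant), so C = 0.8 by the brute-force oracle."""
        t, d, r = [2, 4, 6, 8], [1, 1, 0, 1], [0.9, 0.3, 0.5, 0.1]
        expected = brute_force_cindex(np.array(t), np.array(d), np.array(r))
        assert expected == pytest.approx(0.8)
        assert concordance_index(t, d, r) == pytest.approx(expected)

    def test_matches_brute_force_on_random_censored_instances(self, rng):
        """Exact agreement with pair enumeration on 200 random instances
        with ties in both time and risk."""
        for _ in range(200):
            n = int(rng.integers(3, 31))
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            risk = np.round(rng.standard_normal(n), 1)
            if not ((time[:, None] < time[None, :]) & (event[:, None] == 1)).any():
                continue
            assert concordance_index(time, event, risk) == pytest.approx(
                brute_force_cindex(time, event, risk), abs=1e-12
            )

    def test_no_permissible_pair_is_an_error(self):
        with pytest.raises(ContractError):
            concordance_index([5, 5], [1, 1], [1, 2])


class TestBrier:
    def test_perfect_probabilities(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0

    def test_coin_flip_probabilities(self):
        assert brier_score([0.5, 0.5, 0.5], [1, 0, 1]) == 0.25

    def test_direct_evaluation(self):
        assert brier_score([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_probability_domain_enforced(self):
        with pytest.raises(ContractError):
            brier_score([1.2], [1])

    def test_horizon_variant_drops_ambiguous_censoring(self):
        # censored before the horizon is ambiguous and excluded
        v = brier_score_at([0.9, 0.1, 0.5], time=[2, 9, 4], event=[1, 0, 0], horizon=5)
        assert v == pytest.approx(((0.9 - 1) ** 2 + (0.1 - 0) ** 2) / 2)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        d = [1, 1, 0, 1, 1, 0]
        g = ["A", "A", "A", "B", "B", "B"]
        stat, p = logrank_test(g, t, d)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_example_matches_hand_tally(self):
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, dtype=int)
        group = np.array([1, 1, 1, 0, 0, 0])
        chi2_oracle, p_oracle = manual_logrank(time, event, group)
        stat, p = logrank_test(group, time, event)
        assert stat == pytest.approx(chi2_oracle, rel=1e-6)
        assert p == pytest.approx(p_oracle, rel=1e-6)
        assert stat == pytest.approx(5.0517, abs=1e-3)

    def test_permutation_null_p_values_uniform(self, rng):
        time = rng.exponential(1.0, 60)
        event = (rng.random(60) < 0.7).astype(int)
        ps = []
        for _ in range(300):
            g = rng.permutation(np.repeat([0, 1], 30))
            ps.append(logrank_test(g, time, event)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAggregateFolds:
    def test_geometric_mean_of_p_values(self):
        df = pd.DataFrame({"c_index": [0.5, 0.5], "brier": [0.2, 0.2],
                           "logrank_p": [1e-2, 1e-4]})
        assert aggregate_folds(df)["logrank_p_geomean"] == pytest.approx(1e-3)

    def test_single_fold_degenerates(self):
        df = pd.DataFrame({"c_index": [0.7], "brier": [0.1], "logrank_p": [0.5]})
        agg = aggregate_folds(df)
        assert agg["c_index_mean"] == 0.7 and agg["c_index_sd"] == 0.0

    def test_sample_sd_convention(self):
        df = pd.DataFrame({"c_index": [0.9, 0.94], "brier": [0.1, 0.1],
                           "logrank_p": [0.5, 0.5]})
        agg = aggregate_folds(df)
        assert agg["c_index_mean"] == pytest.approx(0.92)
        assert agg["c_index_sd"] == pytest.approx(np.std([0.9, 0.94], ddof=1))

    def test_zero_p_is_floored_not_crashing(self):
        df = pd.DataFrame({"c_index": [0.5], "brier": [0.2], "logrank_p": [0.0]})
        assert aggregate_folds(df)["logrank_p_geomean"] > 0


class TestCovariateTests:
    def _clinical(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"time": np.ones(n), "event": np.ones(n, dtype=int)}
        return pd.DataFrame({**base, **cols},
                            index=[f"S{i}" for i in range(n)])

    def test_identical_age_distributions_not_significant(self):
        age = np.array([40, 50, 60, 40, 50, 60], dtype=float)
        clinical = self._clinical(age=age)
        labels = pd.Series(["G1"] * 3 + ["G2"] * 3, index=clinical.index)
        res = covariate_tests(labels, clinical).set_index("covariate")
        assert res.loc["age", "test"] == "wilcoxon"
        assert res.loc["age", "p_value"] > 0.9

    def test_diagonal_contingency_table_chi2_20(self):
        grade = np.array(["II"] * 10 + ["IV"] * 10)
        clinical = self._clinical(grade=grade)
        labels = pd.Series(["G1"] * 10 + ["G2"] * 10, index=clinical.index)
        res = covariate_tests(labels, clinical).set_index("covariate")
        # direct formula on [[10,0],[0,10]] without continuity correction
        assert res.loc["grade", "statistic"] == pytest.approx(20.0)
        assert res.loc["grade", "p_value"] < 0.001

    def test_constant_categorical_covariate_is_null(self):
        clinical = self._clinical(gender=np.array(["f"] * 8))
        labels = pd.Series(["G1"] * 4 + ["G2"] * 4, index=clinical.index)
        res = covariate_tests(labels, clinical).set_index("covariate")
        assert res.loc["gender", "statistic"] == 0.0
        assert res.loc["gender", "p_value"] == 1.0

    def test_missing_covariate_skipped_with_warning(self):
        clinical = self._clinical(age=np.full(6, np.nan))
        labels = pd.Series(["G1"] * 3 + ["G2"] * 3, index=clinical.index)
        with pytest.warns(UserWarning, match="age"):
            res = covariate_tests(labels, clinical)
        assert "age" not in set(res.get("covariate", []))


class TestCoxCompare:
    def test_model_list_length_and_subtype_discrimination(self, small_cohort):
        res = cox_compare(
            small_cohort.clinical, small_cohort.true_labels,
            [["age", "gender", "grade", "tumor_type", "subtype"],
             ["subtype"], ["tumor_type"]],
        )
        assert len(res) == 3
        assert res["converged"].all()
        assert res.set_index("model").loc["subtype", "c_index"] > 0.6

    def test_pure_noise_covariate_changes_little(self, reference_cohort, rng):
        clinical = reference_cohort.clinical.copy()
        clinical["noise"] = rng.standard_normal(len(clinical))
        res = cox_compare(
            clinical, reference_cohort.true_labels, [["subtype"], ["subtype", "noise"]]
        ).set_index("model")
        # in-sample C inflation from one noise covariate at n=400 measures
        # ~0.020 under this seed; the property is that it stays marginal
        assert abs(res.loc["subtype", "c_index"]
                   - res.loc["subtype+noise", "c_index"]) < 0.025
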