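"""Statistics engine vs independent oracles (enumeration, brute force,
bootstrap, null simulation)."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from collateralfd.stats import (
    delong_paired_test,
    fit_logistic,
    group_compare,
    hosmer_lemeshow,
    reproduce_paper_tables,
    roc_analysis,
    spearman_correlation,
    wilcoxon_signed_rank,
)


def brute_force_auc(scores, labels):
    """Concordant-pair AUC over all positive-negative pairs (ties half)."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels, int)
    pos = s[lab == 1][:, None]
    neg = s[lab == 0][None, :]
    return float((pos > neg).mean() + 0.5 * (pos == neg).mean())


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)

    def test_four_point_example_pairwise_auc(self):
        r = roc_analysis([0.8, 0.3, 0.6, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_auc_equals_mann_whitney_pair_count(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            r = roc_analysis(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_youden_point_lies_on_the_curve(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=80), 1)
        labels = (scores + rng.normal(size=80) > 0).astype(int)
        r = roc_analysis(scores, labels)
        t = r.youden_threshold
        sens = (scores[labels == 1] > t).mean()
        spec = (scores[labels == 0] <= t).mean()
        assert r.youden_sensitivity == pytest.approx(sens)
        assert r.youden_specificity == pytest.approx(spec)
        assert r.youden_j == pytest.approx(sens + spec - 1)

    def test_sensitivity_non_increasing_in_threshold(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r = roc_analysis(scores, labels)
        assert all(a >= b for a, b in zip(r.sensitivity, r.sensitivity[1:]))

    def test_one_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = [0.9, 0.7, 0.4, 0.2]
        res = delong_paired_test(s, s, [1, 1, 0, 0])
        assert res.degenerate and res.p_value == 1.0
        assert res.notes["auc_difference"] == 0.0

    def test_type_one_error_under_null(self):
        """Two noisy copies of one latent score: rejection rate ~ alpha."""
        rng = np.random.default_rng(42)
        reps, n, rejected = 1000, 500, 0
        for _ in range(reps):
            latent = rng.normal(size=n)
            labels = (latent + rng.normal(size=n) > 0).astype(int)
            a = latent + rng.normal(size=n)
            b = latent + rng.normal(size=n)
            rejected += delong_paired_test(a, b, labels).p_value < 0.05
        assert 0.035 <= rejected / reps <= 0.065

    def test_agrees_with_stratified_bootstrap_on_small_data(self):
        a = np.array([0.9, 0.8, 0.7, 0.35, 0.6, 0.4, 0.3, 0.2])
        b = np.array([0.85, 0.6, 0.75, 0.5, 0.55, 0.45, 0.35, 0.15])
        lab = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = delong_paired_test(a, b, lab)
        rng = np.random.default_rng(0)
        pos_idx, neg_idx = np.where(lab == 1)[0], np.where(lab == 0)[0]
        diffs = []
        for _ in range(10000):
            idx = np.concatenate(
                [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
            )
            diffs.append(brute_force_auc(a[idx], lab[idx]) - brute_force_auc(b[idx], lab[idx]))
        se = np.std(diffs, ddof=1)
        obs = brute_force_auc(a, lab) - brute_force_auc(b, lab)
        p_boot = 2 * sps.norm.sf(abs(obs / se))
        assert res.p_value == pytest.approx(p_boot, abs=0.01)


class TestLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # exposed: 10 events / 5 non-events; unexposed: 2 / 8
        rows = (
            [(1, 1)] * 10 + [(1, 0)] * 5 + [(0, 1)] * 2 + [(0, 0)] * 8
        )
        df = pd.DataFrame(rows, columns=["exposed", "event"])
        fit = fit_logistic(df, "event", ["exposed"])
        assert fit.odds_ratios["exposed"] == pytest.approx(8.0, abs=1e-6)
        assert fit.converged

    def test_null_predictors_have_uniform_p(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame(
                {"x": rng.normal(size=200), "y": rng.integers(0, 2, 200)}
            )
            fit = fit_logistic(df, "y", ["x"])
            hits += fit.p_values["x"] < 0.05
        assert abs(hits / reps - 0.05) <= 0.03

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(-1.0 + 2.0 * x)))
        y = (rng.random(2000) < p).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=0.15)
        assert fit.coefficients["const"] == pytest.approx(-1.0, abs=0.15)

    def test_aic_matches_likelihood(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=300)})
        df["y"] = (rng.random(300) < 1 / (1 + np.exp(-df["x"]))).astype(int)
        fit = fit_logistic(df, "y", ["x"])
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood)

    def test_separation_is_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                           "y": np.r_[np.zeros(10), np.ones(10)].astype(int)})
        fit = fit_logistic(df, "y", ["x"])
        assert not fit.converged and fit.flags

    def test_hosmer_lemeshow_df(self):
        rng = np.random.default_rng(6)
        p_hat = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p_hat).astype(int)
        chi2, df_, p = hosmer_lemeshow(y, p_hat)
        assert df_ == 8
        assert 0 <= p <= 1


class TestRankStats:
    def test_spearman_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, x**3).value == pytest.approx(1.0)
        assert spearman_correlation(x, -x).value == pytest.approx(-1.0)

    def test_spearman_ties_match_brute_force_ranks(self):
        x = np.array([1, 2, 2, 3], float)
        y = np.array([1, 2, 3, 4], float)
        rho = spearman_correlation(x, y).value
        brute = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_spearman_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_wilcoxon_extreme_one_sided_shift(self):
        a = np.arange(20.0)
        res = wilcoxon_signed_rank(a, a + 1)
        n = 20
        # all |differences| tie at 1, so the tie-corrected variance applies
        sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (n**3 - n) / 48
        z_max = (n * (n + 1) / 4) / np.sqrt(sigma2)
        assert res.value == pytest.approx(-z_max)  # all differences negative
        assert res.notes["w_plus"] == 0.0

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        a = np.array([10.0, 8.0, 6.0, 5.0, 9.0, 4.0])
        b = np.array([7.0, 9.0, 4.0, 5.0, 5.0, 6.0])  # one zero difference
        res = wilcoxon_signed_rank(a, b)
        d = a - b
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        null_w = np.array(
            [sum(r for r, keep in zip(ranks, signs) if keep)
             for signs in product([0, 1], repeat=len(d))]
        )
        assert res.notes["w_plus"] == 11.5
        assert null_w.mean() == pytest.approx(len(d) * (len(d) + 1) / 4)
        sigma2_formula = (res.notes["w_plus"] - null_w.mean()) / res.value
        assert sigma2_formula**2 == pytest.approx(null_w.var(), abs=1e-9)

    def test_wilcoxon_type_one_error_under_null(self):
        rng = np.random.default_rng(21)
        rejected = 0
        for _ in range(1000):
            a = rng.normal(size=50)
            b = a + rng.normal(size=50)  # symmetric paired noise
            rejected += wilcoxon_signed_rank(a, b).p_value < 0.05
        assert 0.035 <= rejected / 1000 <= 0.065

    def test_wilcoxon_all_zero_differences_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestGroupCompare:
    def _table(self, g0, g1):
        return pd.DataFrame(
            {"v": np.concatenate([g0, g1]),
             "g": [0] * len(g0) + [1] * len(g1)}
        )

    def test_identical_groups_give_p_one(self):
        res = group_compare(self._table([1.0, 2, 3, 4], [1.0, 2, 3, 4]), "v", "g")
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        df = pd.DataFrame({"v": ["a"] * 3 + ["b"] * 3, "g": [0] * 3 + [1] * 3})
        res = group_compare(df, "v", "g", kind="categorical")
        assert res.statistic_name == "fisher_or"
        probs = {k: comb(3, k) * comb(3, 3 - k) / comb(6, 3) for k in range(4)}
        p_obs = probs[3]
        p_enum = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.p_value == pytest.approx(p_enum, abs=1e-9)
        assert res.p_value == pytest.approx(0.1, abs=1e-9)

    def test_two_sd_shift_is_detected(self):
        rng = np.random.default_rng(13)
        res = group_compare(
            self._table(rng.normal(0, 1, 50), rng.normal(2, 1, 50)), "v", "g"
        )
        assert res.p_value < 0.001

    def test_mann_whitney_flag(self):
        rng = np.random.default_rng(14)
        res = group_compare(
            self._table(rng.normal(0, 1, 30), rng.normal(1, 1, 30)), "v", "g",
            rank_based=True,
        )
        assert res.statistic_name == "U"

    def test_single_group_is_an_error(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": [0, 0]})
        with pytest.raises(ValueError, match="2 levels"):
            group_compare(df, "v", "g")


class TestCohortReport:
    def _hand_cohort(self):
        return pd.DataFrame(
            {
                "mfd": [0.80, 0.90, 1.00, 0.95, 0.85, 0.70],
                "vcs_scta": [2, 3, 4, 3, 2, 1],
                "vcs_mcta": [1, 3, 5, 4, 2, 1],
                "age": [60.0, 70, 65, 55, 75, 68],
                "sex": ["male", "female", "male", "male", "female", "female"],
                "pre_nihss": [20, 15, 10, 12, 22, 25],
                "mrs_90": [4, 2, 0, 1, 5, 6],
            }
        )

    def test_hand_built_cohort_means_match_arithmetic(self):
        rep = reproduce_paper_tables(self._hand_cohort())
        assert rep["n"] == 6
        assert rep["n_favorable"] == 3
        g = rep["group_comparisons"]["mfd"]
        assert g["favorable_mean"] == pytest.approx(np.mean([0.90, 1.00, 0.95]))
        assert g["unfavorable_mean"] == pytest.approx(np.mean([0.80, 0.85, 0.70]))
        assert g["all_sd"] == pytest.approx(
            np.std([0.80, 0.90, 1.00, 0.95, 0.85, 0.70], ddof=1)
        )

    def test_missing_columns_are_itemized(self):
        df = self._hand_cohort().drop(columns=["vcs_mcta", "age"])
        with pytest.raises(ValueError, match="vcs_mcta") as exc:
            reproduce_paper_tables(df)
        assert "age" in str(exc.value)

    def test_null_cohort_rarely_flags_differences(self):
        """With no true group effect each comparison stays above 0.05
        in >= 90% of seeded replicates."""
        counts: dict[str, int] = {}
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            df = pd.DataFrame(
                {
                    "mfd": rng.normal(0.9, 0.1, n).clip(0.3),
                    "vcs_scta": rng.integers(0, 6, n),
                    "vcs_mcta": rng.integers(0, 6, n),
                    "age": rng.normal(65, 12, n),
                    "sex": rng.choice(["male", "female"], n),
                    "pre_nihss": rng.integers(0, 30, n),
                    "mrs_90": rng.integers(0, 7, n),  # outcome independent of all
                }
            )
            rep = reproduce_paper_tables(df)
            for var, row in rep["group_comparisons"].items():
                counts.setdefault(var, 0)
                counts[var] += row["p_value"] > 0.05
        for var, good in counts.items():
            assert good / reps >= 0.9, f"{var}: {good}/{reps}"

    def test_adjusted_models_skipped_without_ldl(self):
        rep = reproduce_paper_tables(self._hand_cohort())
        assert rep["adjusted_models"]["skipped"]
        assert "ldl" in rep["adjusted_models"]["reason"]
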