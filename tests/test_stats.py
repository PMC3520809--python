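"""Statistical chain: slopes, rank tests, threshold, ROC machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiotox_utc import (
    cutoff_performance,
    derive_threshold,
    kruskal_wallis,
    mann_whitney_auc,
    per_animal_beta,
    roc_analysis,
    spearman,
)
from cardiotox_utc.errors import (
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from cardiotox_utc.stats import (
    bootstrap_ci,
    categorical_test,
    delong_ci,
    summarize_groups,
    youden_cutoff,
)


class TestPerAnimalBeta:
    def test_constant_values_give_zero_slope(self):
        assert per_animal_beta([0, 8, 12], [1.1, 1.1, 1.1]).slope == pytest.approx(0.0)

    def test_worked_four_point_example(self):
        b = per_animal_beta([0, 8, 12, 16], [1.0, 1.2, 1.3, 1.4])
        assert b.slope == pytest.approx(0.025)  # Sxy/Sxx = 3.5/140
        assert b.n_points == 4

    def test_exact_collinear_fit(self):
        doses = np.array([0.0, 8.0, 10.0, 16.0])
        b = per_animal_beta(doses, 2.0 + 0.1 * doses)
        assert b.slope == pytest.approx(0.1)
        assert b.intercept == pytest.approx(2.0)

    def test_identical_doses_raise(self):
        with pytest.raises(DegenerateDesignError):
            per_animal_beta([8, 8, 8], [1.0, 1.1, 1.2])

    def test_single_point_raises(self):
        with pytest.raises(InsufficientDataError):
            per_animal_beta([0], [1.0])

    @given(
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-3, max_value=3).filter(lambda b: abs(b) > 1e-3),
    )
    def test_affine_equivariance(self, a, b):
        """Slope of a + b*y equals b times the slope of y."""
        doses = [0.0, 8.0, 10.0, 12.0]
        y = np.array([1.0, 1.25, 1.2, 1.45])
        s0 = per_animal_beta(doses, y).slope
        s1 = per_animal_beta(doses, a + b * y).slope
        assert s1 == pytest.approx(b * s0, rel=1e-9, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_toy_groups(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27.0 / 7.0)  # 12/42*(12+75) - 21

    def test_three_singleton_groups(self):
        h, p = kruskal_wallis([[1.0], [2.0], [3.0]])
        assert np.isfinite(h) and 0 < p <= 1

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.5, 3.0], [4.2, 5.0], [0.5, 6.1, 7.0]]
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis([list(np.exp(g)) for g in groups])
        assert h1 == pytest.approx(h0)

    def test_empty_group_raises(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1.0], []])


class TestSpearman:
    def test_monotone_pairs(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [-1, -2, -3, -4])
        assert rho == pytest.approx(-1.0)

    def test_three_point_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)  # 1 - 6*6/24

    def test_monotone_transform_invariance(self):
        x = [0.2, 1.4, 2.2, 5.0, 3.3]
        y = [3.0, 1.0, 4.0, 2.0, 5.0]
        rho0, _ = spearman(x, y)
        rho1, _ = spearman(np.exp(x), np.sqrt(np.array(y)))
        assert rho1 == pytest.approx(rho0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestThreshold:
    def test_mean_plus_two_sd(self):
        spec = derive_threshold([1.0, 2.0, 3.0], k=2)
        assert spec.threshold == pytest.approx(4.0)
        assert spec.control_sd == pytest.approx(1.0)

    def test_degenerate_controls(self):
        assert derive_threshold([2.0, 2.0, 2.0]).threshold == pytest.approx(2.0)

    def test_k_zero_equals_mean(self):
        assert derive_threshold([1.0, 2.0, 3.0], k=0).threshold == pytest.approx(2.0)

    def test_single_control_raises(self):
        with pytest.raises(InsufficientDataError):
            derive_threshold([2.0])


def brute_force_auc(scores, labels):
    """Independent pairwise oracle: mean of win/tie-half indicators."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestAUC:
    def test_perfect_separation(self):
        assert mann_whitney_auc([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_identical_distributions(self):
        assert mann_whitney_auc([1, 2, 1, 2], [True, True, False, False]) == 0.5

    def test_tied_example(self):
        # cases {1, 2}, controls {1, 0}: pairwise (1+1+1+0.5)/4
        assert mann_whitney_auc([1, 2, 1, 0], [True, True, False, False]) == pytest.approx(
            0.875
        )

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            mann_whitney_auc([1, 2], [True, True])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        # coarse grid induces plenty of ties
        scores = rng.integers(0, 6, 40).astype(float)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        auc = mann_whitney_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_complement_under_negation(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=20), 1)
        labels = np.arange(20) < 8
        assert mann_whitney_auc(-scores, labels) == pytest.approx(
            1.0 - mann_whitney_auc(scores, labels), abs=1e-12
        )


class TestCIsAndCutoffs:
    def test_delong_interval_brackets_auc(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 1, 15), rng.normal(0, 1, 20)])
        labels = np.arange(35) < 15
        auc, lo, hi = delong_ci(scores, labels)
        assert 0 <= lo <= auc <= hi <= 1
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(1, 1, 12), rng.normal(0, 1, 12)])
        labels = np.arange(24) < 12
        a = bootstrap_ci(scores, labels, n_boot=200, seed=5)
        b = bootstrap_ci(scores, labels, n_boot=200, seed=5)
        assert a == b

    @pytest.mark.parametrize(
        "cutoff, sens, spec",
        [(-10.0, 100.0, 0.0), (1.21, pytest.approx(200 / 3, abs=0.01),
          pytest.approx(200 / 3, abs=0.01)), (10.0, 0.0, 100.0)],
    )
    def test_cutoff_performance(self, cutoff, sens, spec):
        scores = [1.30, 1.25, 1.10, 1.00, 1.22, 1.15]
        labels = [True, True, True, False, False, False]
        s, sp = cutoff_performance(scores, labels, cutoff)
        assert s == sens and sp == spec

    def test_youden_ties_break_toward_specificity(self):
        # J is maximal (=1) anywhere in the separation gap; candidates at the
        # observed values make 3.0 the spec-favoring choice over 1.0/2.0.
        scores = [3.0, 4.0, 1.0, 2.0]
        labels = [True, True, False, False]
        cut = youden_cutoff(scores, labels)
        assert cut == 3.0
        sens, spec = cutoff_performance(scores, labels, cut)
        assert sens == 100.0 and spec == 100.0

    def test_roc_analysis_bundle(self):
        scores = [1.30, 1.25, 1.10, 1.00, 1.22, 1.15]
        labels = [True, True, True, False, False, False]
        res = roc_analysis(scores, labels)
        assert res.n_pos == 3 and res.n_neg == 3
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 <= res.sensitivity_pct <= 100 and 0 <= res.specificity_pct <= 100


class TestCategoricalAndSummary:
    def test_fisher_for_2x2_chi2_otherwise(self):
        method, p = categorical_test([[8, 2], [1, 9]])
        assert method == "fisher" and 0 < p < 1
        method, p = categorical_test([[8, 2, 5], [1, 9, 4]])
        assert method == "chi2" and 0 < p <= 1

    def test_group_summary_flags_singletons(self):
        records = pd.DataFrame(
            {
                "animal_id": [1, 2, 3],
                "dose_mg_per_kg": [0.0, 0.0, 8.0],
                "variable": ["cc_ibs"] * 3,
                "value": [1.0, 1.2, 1.3],
            }
        )
        out = summarize_groups(records)
        base = out[out.dose_mg_per_kg == 0].iloc[0]
        single = out[out.dose_mg_per_kg == 8].iloc[0]
        assert base["mean"] == pytest.approx(1.1)
        assert base["se"] == pytest.approx(base["sd"] / np.sqrt(2))
        assert single["n"] == 1 and np.isnan(single["se"])
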