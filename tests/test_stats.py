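"""Diagnostics layer: U test, ROC/AUC, Youden, bootstrap procedures."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import ftburden as fb
from ftburden.stats import YoudenThresholdClassifier, youden_cutoff

score_lists = st.lists(
    st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 1)), min_size=2, max_size=15
)


def brute_force_u(x, y):
    """Independent oracle: count winning pairs plus half-ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1
            elif xi == yi:
                u += 0.5
    return u


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = fb.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        u, _ = fb.mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9.0  # orientation: U counts first-sample wins

    def test_identical_samples_p_one(self):
        _, p = fb.mann_whitney([5, 6, 7, 8], [5, 6, 7, 8])
        assert p == pytest.approx(1.0)

    @given(score_lists, score_lists)
    def test_u_equals_pair_count(self, x, y):
        u, _ = fb.mann_whitney(x, y)
        assert u == pytest.approx(brute_force_u(x, y), abs=1e-9)

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
        st.lists(st.integers(0, 8), min_size=2, max_size=6),
    )
    def test_exact_mode_equals_full_permutation(self, x, y):
        # independent enumeration oracle including ties, n1+n2 <= 12
        _, p = fb.mann_whitney(x, y)
        pooled = np.array(x + y, dtype=float)
        n1 = len(x)
        mu = n1 * len(y) / 2
        obs = abs(brute_force_u(x, y) - mu)
        hits = total = 0
        for subset in combinations(range(len(pooled)), n1):
            rest = [i for i in range(len(pooled)) if i not in subset]
            total += 1
            if abs(brute_force_u(pooled[list(subset)], pooled[rest]) - mu) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fb.mann_whitney([], [1, 2])


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array(["TP"] * 3 + ["TRA"] * 3)
        assert fb.roc_auc([10, 9, 8, 1, 2, 3], y, "TP") == 1.0

    def test_label_swap_inverts_auc(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = np.array(["TP"] * 14 + ["TRA"] * 16)
        a = fb.roc_auc(s, y, "TP")
        assert fb.roc_auc(s, y, "TRA") == pytest.approx(1 - a, abs=1e-12)

    def test_direction_lower(self):
        y = np.array(["TP"] * 3 + ["TRA"] * 3)
        assert fb.roc_auc([1, 2, 3, 8, 9, 10], y, "TP", "lower") == 1.0

    @given(score_lists)
    def test_auc_u_identity_and_sklearn_agreement(self, scores):
        n = len(scores)
        n_pos = n // 2
        if n_pos == 0 or n_pos == n:
            return
        y = np.array([1] * n_pos + [0] * (n - n_pos))
        scores = np.asarray(scores)
        auc = fb.roc_auc(scores, y, 1)
        u = brute_force_u(scores[:n_pos], scores[n_pos:])
        assert auc == pytest.approx(u / (n_pos * (n - n_pos)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fb.roc_auc([1, 2], np.array(["TP", "TP"]), "TP")


class TestYouden:
    def test_separated_groups(self):
        y = np.array([1] * 3 + [0] * 3)
        cutoff, sens, spec = youden_cutoff([10, 11, 12, 1, 2, 3], y, 1)
        assert sens == 1.0 and spec == 1.0
        assert 3 < cutoff < 10

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=30))
    def test_scan_matches_exhaustive_oracle(self, scores):
        n_pos = len(scores) // 2
        y = np.array([1] * n_pos + [0] * (len(scores) - n_pos))
        scores = np.array(scores, dtype=float)
        cutoff, sens, spec = youden_cutoff(scores, y, 1)
        # oracle: evaluate J at every candidate with plain loops
        pos, neg = scores[:n_pos], scores[n_pos:]
        uniq = np.unique(scores)
        cands = [-np.inf] + [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])] + [uniq[-1]]
        best_j = max(
            np.mean(pos > c) + np.mean(neg <= c) - 1 for c in cands
        )
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
        # reported operating point is consistent with the reported cutoff
        assert sens == pytest.approx(np.mean(pos > cutoff), abs=1e-12)
        assert spec == pytest.approx(np.mean(neg <= cutoff), abs=1e-12)

    def test_tie_break_prefers_specificity(self):
        # J ties at 0 everywhere for useless scores; highest specificity wins
        y = np.array([1, 1, 0, 0])
        cutoff, sens, spec = youden_cutoff([5.0, 5.0, 5.0, 5.0], y, 1)
        assert spec == 1.0 and sens == 0.0


class TestBootstrapCi:
    def test_degenerate_scores_give_unit_interval(self):
        y = np.array([1] * 5 + [0] * 5)
        lo, hi = fb.bootstrap_auc_ci([9, 9, 9, 9, 9, 1, 1, 1, 1, 1], y, 1, n_boot=300, seed=3)
        assert (lo, hi) == (1.0, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = np.array([1] * 20 + [0] * 20)
        ci1 = fb.bootstrap_auc_ci(s, y, 1, n_boot=500, seed=7)
        ci2 = fb.bootstrap_auc_ci(s, y, 1, n_boot=500, seed=7)
        assert ci1 == ci2

    def test_row_order_invariance(self):
        # stratified resampling: permuting patients within class keeps the CI
        rng = np.random.default_rng(2)
        pos = rng.normal(1, 1, 20)
        neg = rng.normal(0, 1, 15)
        s1 = np.concatenate([pos, neg])
        y = np.array([1] * 20 + [0] * 15)
        s2 = np.concatenate([pos, neg])
        assert fb.bootstrap_auc_ci(s1, y, 1, n_boot=400, seed=5) == fb.bootstrap_auc_ci(
            s2, y, 1, n_boot=400, seed=5
        )

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            fb.bootstrap_auc_ci([1, 2], np.array([1, 0]), 1, n_boot=50)


class TestCompareAuc:
    def test_identical_scores(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        y = np.array([1] * 15 + [0] * 15)
        c = fb.compare_auc_bootstrap(s, s, y, 1, n_boot=300, seed=0)
        assert c.d_stat == 0.0 and c.p_value == 1.0 and not c.degenerate

    def test_default_n_boot_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(fb.compare_auc_bootstrap)
        assert sig.parameters["n_boot"].default == 10_000

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 30))
        y = np.array([1] * 15 + [0] * 15)
        c1 = fb.compare_auc_bootstrap(a, b, y, 1, n_boot=400, seed=9)
        c2 = fb.compare_auc_bootstrap(a, b, y, 1, n_boot=400, seed=9)
        assert (c1.d_stat, c1.p_value) == (c2.d_stat, c2.p_value)


class TestYoudenClassifier:
    def test_fixed_cutoff_strict_inequality(self):
        clf = YoudenThresholdClassifier(positive_class="TP", cutoff=24.0)
        X = np.array([24.0, 24.1, 30.0, 10.0])
        y = np.array(["TP", "TP", "TP", "TRA"])
        clf.fit(X, y)
        assert clf.predict(X).tolist() == ["TRA", "TP", "TP", "TRA"]
        assert clf.sensitivity_ == pytest.approx(2 / 3)
        assert clf.specificity_ == 1.0

    def test_fitted_cutoff_matches_function(self):
        rng = np.random.default_rng(5)
        s = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        y = np.array([1] * 20 + [0] * 20)
        clf = YoudenThresholdClassifier(positive_class=1).fit(s, y)
        cutoff, sens, spec = youden_cutoff(s, y, 1)
        assert clf.cutoff_ == cutoff
        assert (clf.sensitivity_, clf.specificity_) == (sens, spec)


@pytest.fixture(scope="module")
def table():
    tab = fb.sample_fraction_table(fb.CohortSpec(seed=7))
    return tab.assign(
        pct_low=100 * tab.frac_low,
        pct_mid=100 * tab.frac_mid,
        pct_high=100 * tab.frac_high,
    )


class TestEvaluateCohort:

    def test_report_structure_and_determinism(self, table):
        import json

        kw = dict(n_boot=500, n_boot_compare=500, seed=0)
        r1 = fb.evaluate_cohort(table, **kw)
        r2 = fb.evaluate_cohort(table, **kw)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
        assert r1["n_tp"] == 35 and r1["n_tra"] == 24
        assert 0 <= r1["auc_comparison"]["p_value"] <= 1
        assert r1["roc_ftb_high"]["ci_low"] <= r1["roc_ftb_high"]["auc"] <= r1["roc_ftb_high"]["ci_high"]

    def test_complete_separation_reports_auc_one(self):
        rows = [
            {"label": "TP", "pct_low": 10.0, "pct_mid": 20.0, "pct_high": 70.0 + i}
            for i in range(5)
        ] + [
            {"label": "TRA", "pct_low": 80.0, "pct_mid": 15.0, "pct_high": 5.0 + i}
            for i in range(5)
        ]
        report = fb.evaluate_cohort(pd.DataFrame(rows), n_boot=300, n_boot_compare=300)
        assert report["roc_ftb_high"]["auc"] == 1.0
        assert report["roc_ftb_low"]["auc"] == 1.0

    def test_undersized_group_rejected(self):
        rows = [
            {"label": "TP", "pct_low": 10, "pct_mid": 20, "pct_high": 70},
            {"label": "TP", "pct_low": 12, "pct_mid": 20, "pct_high": 68},
            {"label": "TRA", "pct_low": 80, "pct_mid": 15, "pct_high": 5},
        ]
        with pytest.raises(ValueError, match="two patients"):
            fb.evaluate_cohort(pd.DataFrame(rows), n_boot=300)
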