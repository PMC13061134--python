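"""Sampling curves, ensemble diversity and ranking summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from abageval.evaluation import (pconsdock_diversity, ranking_summary,
                                 sampling_curve, sampling_curve_exact)


def _table(per_target: dict) -> pd.DataFrame:
    rows = []
    for tid, models in per_target.items():
        for mid, (dockq, conf) in models.items():
            rows.append({"target_id": tid, "model_id": mid, "dockq": dockq,
                         "ranking_confidence": conf})
    return pd.DataFrame(rows)


class TestSamplingCurve:
    def test_two_model_exact_expectation(self):
        # draws of size 2 with replacement from {0.1, 0.9}:
        # P(max=0.9) = 3/4 -> E[best] = 0.25*0.1 + 0.75*0.9 = 0.7
        table = _table({"T1": {"a": (0.1, 0.2), "b": (0.9, 0.8)}})
        exact = sampling_curve_exact(table, [2])
        assert exact.mean_best_dockq[0] == pytest.approx(0.7, abs=1e-12)
        boot = sampling_curve(table, [2], n_iter=2000, seed=1)
        # binomial standard error of the best-of-2 estimate
        se = np.sqrt(0.25 * 0.75 / 2000) * (0.9 - 0.1)
        assert abs(boot.mean_best_dockq[0] - 0.7) < 3 * se

    def test_k_one_equals_mean_dockq(self):
        rng = np.random.default_rng(2)
        table = _table({
            f"T{t}": {f"m{i}": (rng.uniform(), rng.uniform())
                      for i in range(10)} for t in range(4)})
        exact = sampling_curve_exact(table, [1])
        per_target_mean = table.groupby("target_id")["dockq"].mean().mean()
        assert exact.mean_best_dockq[0] == pytest.approx(per_target_mean)
        assert exact.mean_top_ranked_dockq[0] == pytest.approx(per_target_mean)

    def test_perfect_selector_makes_curves_coincide(self):
        rng = np.random.default_rng(3)
        table = _table({
            "T1": {f"m{i}": (v, v) for i, v in
                   enumerate(rng.uniform(size=20))}})
        curve = sampling_curve(table, [1, 2, 5, 10], n_iter=50, seed=5,
                               selector="dockq")
        np.testing.assert_allclose(curve.mean_best_dockq,
                                   curve.mean_top_ranked_dockq)

    def test_mean_best_nondecreasing_in_k(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            table = _table({
                f"T{t}": {f"m{i}": (rng.uniform(), rng.uniform())
                          for i in range(int(rng.integers(2, 15)))}
                for t in range(3)})
            exact = sampling_curve_exact(table, [1, 2, 4, 8, 16, 64])
            diffs = np.diff(exact.mean_best_dockq)
            assert np.all(diffs >= -1e-12)

    def test_best_approaches_target_maximum(self):
        table = _table({"T1": {f"m{i}": (v, 0.5) for i, v in
                               enumerate(np.linspace(0, 0.8, 10))}})
        exact = sampling_curve_exact(table, [100])
        assert exact.mean_best_dockq[0] == pytest.approx(0.8, abs=1e-3)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        rng = np.random.default_rng(6)
        table = _table({
            f"T{t}": {f"m{i}": (rng.uniform(), rng.uniform())
                      for i in range(30)} for t in range(5)})
        a = sampling_curve(table, [5], n_iter=50, seed=1)
        b = sampling_curve(table, [5], n_iter=50, seed=2)
        # conservative bound on the SD of a mean of 5x50 bounded draws
        se = 0.3 / np.sqrt(5 * 50)
        assert abs(a.mean_best_dockq[0] - b.mean_best_dockq[0]) < 3 * se

    def test_selector_ties_resolved_to_lower_model_id(self):
        table = _table({"T1": {"a": (0.3, 0.5), "b": (0.9, 0.5)}})
        exact = sampling_curve_exact(table, [50])
        # both models share the selector value; 'a' must win every sample
        # that contains it: P = 1 - (1/2)^50 ~ 1
        assert exact.mean_top_ranked_dockq[0] == pytest.approx(0.3, abs=1e-9)
        boot = sampling_curve(table, [10], n_iter=200, seed=0)
        assert boot.mean_top_ranked_dockq[0] < 0.31

    def test_missing_selector_column_rejected(self):
        table = _table({"T1": {"a": (0.1, 0.2)}})
        with pytest.raises(ValueError, match="column"):
            sampling_curve(table, [1], selector="nope")


class TestPconsdockDiversity:
    def test_identical_models_full_agreement(self):
        n = 6
        mat = pd.DataFrame(np.ones((n, n)),
                           index=[f"m{i}" for i in range(n)],
                           columns=[f"m{i}" for i in range(n)])
        per_model, per_target = pconsdock_diversity({"T1": mat}, mode="full")
        assert np.allclose(per_model["diversity"], 1.0)
        assert per_target["T1"] == pytest.approx(1.0)

    def test_two_cluster_toy_full_mode(self):
        # 10 models, two internally identical clusters of 5, cross DockQ 0:
        # each model agrees with 4 of its 9 partners -> 4/9
        ids = [f"m{i}" for i in range(10)]
        m = np.zeros((10, 10))
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        mat = pd.DataFrame(m, index=ids, columns=ids)
        per_model, per_target = pconsdock_diversity({"T1": mat}, mode="full")
        assert np.allclose(per_model["diversity"], 4 / 9)
        assert per_target["T1"] == pytest.approx(4 / 9)

    def test_sampled_mode_close_to_full(self):
        ids = [f"m{i}" for i in range(10)]
        m = np.zeros((10, 10))
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        mat = pd.DataFrame(m, index=ids, columns=ids)
        _, full = pconsdock_diversity({"T1": mat}, mode="full")
        estimates = [
            pconsdock_diversity({"T1": mat}, n_partners=6, seed=s,
                                mode="sampled")[1]["T1"]
            for s in range(30)]
        # hypergeometric SE of a single per-model mean, / sqrt(10) models
        se = np.std(estimates)
        assert abs(np.mean(estimates) - full["T1"]) < 3 * se / np.sqrt(30) + 1e-9

    def test_oversized_n_partners_falls_back_to_full(self):
        ids = [f"m{i}" for i in range(4)]
        mat = pd.DataFrame(np.ones((4, 4)), index=ids, columns=ids)
        with pytest.warns(UserWarning, match="falling back"):
            per_model, _ = pconsdock_diversity({"T1": mat}, n_partners=20,
                                               mode="sampled")
        assert np.allclose(per_model["diversity"], 1.0)


class TestRankingSummary:
    def test_dockq_as_its_own_selector(self):
        rng = np.random.default_rng(8)
        table = _table({
            f"T{t}": {f"m{i}": (v, v) for i, v in
                      enumerate(rng.uniform(size=12))} for t in range(3)})
        summary = ranking_summary(table, selector="dockq")
        expected_top = table.groupby("target_id")["dockq"].max().mean()
        assert summary.mean_top_dockq == pytest.approx(expected_top)
        assert summary.overall_r == pytest.approx(1.0)
        assert summary.mean_per_target_r == pytest.approx(1.0)

    def test_anticorrelated_selector(self):
        rng = np.random.default_rng(9)
        table = _table({
            f"T{t}": {f"m{i}": (v, 1 - v) for i, v in
                      enumerate(rng.uniform(size=10))} for t in range(3)})
        summary = ranking_summary(table)
        assert summary.mean_per_target_r == pytest.approx(-1.0)

    def test_hand_computed_spearman_three_targets(self):
        table = _table({
            "T1": {"a": (0.1, 0.3), "b": (0.5, 0.1), "c": (0.9, 0.2)},
            "T2": {"a": (0.2, 0.2), "b": (0.4, 0.4), "c": (0.6, 0.6)},
            "T3": {"a": (0.3, 0.9), "b": (0.6, 0.8), "c": (0.9, 0.7)},
        })
        summary = ranking_summary(table)
        # per-target Spearman by the rank formula: T1 ranks (3,1,2) vs
        # (1,2,3) -> r = -0.5; T2 perfectly correlated -> 1; T3 -> -1
        assert summary.mean_per_target_r == pytest.approx((-0.5 + 1 - 1) / 3)
        pooled = spearmanr(table["ranking_confidence"],
                           table["dockq"]).statistic
        assert summary.overall_r == pytest.approx(pooled)
        # top-ranked: T1 -> a (0.1), T2 -> c (0.6), T3 -> a (0.3)
        assert summary.mean_top_dockq == pytest.approx((0.1 + 0.6 + 0.3) / 3)

    def test_zero_variance_targets_excluded_and_counted(self):
        table = _table({
            "T1": {"a": (0.5, 0.5), "b": (0.5, 0.6)},   # no dockq variance
            "T2": {"a": (0.2, 0.2), "b": (0.4, 0.4)},
        })
        summary = ranking_summary(table)
        assert summary.n_targets == 2
        assert summary.n_targets_excluded == 1
        assert summary.mean_per_target_r == pytest.approx(1.0)

    def test_selector_equal_dockq_upper_bounds_other_selectors(self):
        rng = np.random.default_rng(10)
        table = _table({
            f"T{t}": {f"m{i}": (rng.uniform(), rng.uniform())
                      for i in range(15)} for t in range(4)})
        by_dockq = ranking_summary(table, selector="dockq").mean_top_dockq
        by_conf = ranking_summary(table).mean_top_dockq
        assert by_dockq >= by_conf - 1e-12
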