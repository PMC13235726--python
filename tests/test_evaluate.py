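import math

import numpy as np
import pandas as pd
import pytest

from lense.config_grid import PipelineConfig, default_grid
from lense.evaluate import (
    METRIC_NAMES,
    compute_metrics,
    metrics_table,
    pairwise_accuracy,
    rank_of_selected,
    ranking_correlation,
    scale_across_methods,
)
from lense.judge import NoisyOracleJudge, OracleJudge
from lense.preprocess import PipelineResult

from helpers import brute_ari, brute_mi, make_image


def fake_result(labels, pcs=None, config=None):
    labels = np.asarray(labels)
    n = len(labels)
    if pcs is None:
        pcs = np.random.default_rng(0).normal(size=(n, 3))
    config = config or PipelineConfig("lognorm", "all", 5, 0.5)
    return PipelineResult(
        config=config,
        pc_scores=np.asarray(pcs, dtype=float),
        embedding_umap=np.zeros((n, 2)),
        embedding_pca=np.asarray(pcs)[:, :2],
        cluster_labels=labels,
        n_clusters=len(np.unique(labels)),
        seed=0,
    )


class TestComputeMetrics:
    def test_perfect_clustering_scores_ari_one(self):
        truth = [0, 0, 1, 1, 2, 2]
        rep = compute_metrics(fake_result(truth), truth)
        assert rep.ari == 1.0

    def test_ari_anticorrelated_example(self):
        rep = compute_metrics(fake_result([1, 1, 2, 2]), [1, 2, 1, 2])
        assert rep.ari == pytest.approx(-0.5)

    def test_mi_of_balanced_identical_binary_labels_is_ln2(self):
        rep = compute_metrics(fake_result([0, 0, 1, 1]), [0, 0, 1, 1])
        assert rep.mi == pytest.approx(math.log(2))

    def test_report_has_exactly_the_five_named_metrics(self):
        rep = compute_metrics(fake_result([0, 1, 0, 1]), [0, 1, 1, 0])
        assert tuple(rep.as_dict().keys()) == METRIC_NAMES
        assert all(np.isfinite(v) for v in rep.as_dict().values())

    def test_dbi_is_reported_as_one_minus(self):
        from sklearn.metrics import davies_bouldin_score

        labels = [0, 0, 1, 1, 2, 2]
        res = fake_result(labels)
        rep = compute_metrics(res, labels)
        assert rep.one_minus_dbi == pytest.approx(
            1.0 - davies_bouldin_score(res.pc_scores, labels)
        )

    def test_single_cluster_marks_internal_metrics_undefined(self):
        rep = compute_metrics(fake_result([0, 0, 0, 0]), [0, 1, 0, 1])
        assert rep.silhouette is None and rep.chi is None and rep.one_minus_dbi is None
        assert np.isfinite(rep.ari) and np.isfinite(rep.mi)

    def test_ari_symmetric_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 4, 40)
        assert compute_metrics(fake_result(a), b).ari == pytest.approx(
            compute_metrics(fake_result(b), a).ari
        )
        remap = (a + 1) % 3  # relabeling leaves ARI unchanged
        assert compute_metrics(fake_result(remap), b).ari == pytest.approx(
            compute_metrics(fake_result(a), b).ari
        )

    def test_mi_nonnegative_and_near_zero_for_independent_labels(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        mi = compute_metrics(fake_result(a), b).mi
        assert 0 <= mi < 0.01

    def test_brute_force_agreement_ari_mi(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(5, 50)
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 3, n)
            rep = compute_metrics(fake_result(a), b)
            assert rep.ari == pytest.approx(brute_ari(b, a), rel=1e-10, abs=1e-12)
            assert rep.mi == pytest.approx(brute_mi(b, a), rel=1e-10, abs=1e-12)


class TestScaleAcrossMethods:
    def test_two_method_example(self):
        out = scale_across_methods(np.array([[1.0, 3.0]]))
        assert out[0] == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        out = scale_across_methods(rng.normal(size=(6, 9)))
        assert np.abs(out.mean(axis=1)).max() < 1e-12
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_idempotent_on_already_scaled_rows(self):
        rng = np.random.default_rng(3)
        once = scale_across_methods(rng.normal(size=(4, 7)))
        twice = scale_across_methods(once)
        assert twice == pytest.approx(once, abs=1e-12)

    def test_constant_row_errors_naming_scenario(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 3.0]], index=["liver", "lung"])
        with pytest.raises(ValueError, match="lung"):
            scale_across_methods(df)

    def test_dataframe_round_trips(self):
        df = pd.DataFrame([[1.0, 2.0, 6.0]], index=["s"], columns=list("abc"))
        out = scale_across_methods(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == list("abc")


class TestPairwiseAccuracy:
    def setup_method(self):
        self.grid = default_grid(normalizations=["lognorm", "raw"])  # 24 configs
        rng = np.random.default_rng(0)
        self.values = rng.random(len(self.grid))
        self.images = [make_image(c.config_id) for c in self.grid]
        self.scores = dict(zip([c.config_id for c in self.grid], self.values))

    def test_oracle_backend_is_perfectly_self_consistent(self):
        for mode in ("any", "single_step"):
            acc = pairwise_accuracy(
                self.grid, self.images, self.values, OracleJudge(self.scores),
                n_pairs=20, pair_mode=mode, seed=1,
            )
            assert acc == 1.0

    def test_single_step_pairs_differ_in_exactly_one_factor(self):
        import itertools
        from lense.evaluate import _differs_in_one_step

        eligible = [
            (i, j)
            for i, j in itertools.combinations(range(len(self.grid)), 2)
            if _differs_in_one_step(self.grid[i], self.grid[j])
        ]
        assert eligible  # sampler has a nonempty pool
        for i, j in eligible:
            a, b = self.grid[i], self.grid[j]
            diffs = sum(
                getattr(a, f) != getattr(b, f)
                for f in ("normalization", "feature_mode", "n_pcs", "resolution")
            )
            assert diffs == 1

    def test_requesting_more_pairs_than_eligible_errors(self):
        with pytest.raises(ValueError, match="eligible"):
            pairwise_accuracy(
                self.grid[:3], self.images[:3], self.values[:3],
                OracleJudge(self.scores), n_pairs=20, seed=0,
            )

    def test_tied_pairs_are_never_sampled(self):
        vals = np.zeros(len(self.grid))
        vals[0] = 1.0  # only pairs involving config 0 are decidable
        acc = pairwise_accuracy(
            self.grid, self.images, vals,
            OracleJudge(dict(zip([c.config_id for c in self.grid], vals))),
            n_pairs=20, seed=3,
        )
        assert acc == 1.0

    def test_noisy_judge_accuracy_concentrates_at_p(self):
        accs = []
        for seed in range(10):
            backend = NoisyOracleJudge(self.scores, p=0.8, seed=seed)
            accs.append(
                pairwise_accuracy(
                    self.grid, self.images, self.values, backend,
                    n_pairs=200, seed=seed,
                )
            )
        assert np.mean(accs) == pytest.approx(0.8, abs=0.02)


class TestRankOfSelected:
    def test_unique_maximum_is_rank_one(self):
        assert rank_of_selected("b", {"a": 3.0, "b": 9.0, "c": 5.0}) == 1

    def test_ties_share_the_best_rank(self):
        assert rank_of_selected("a", {"a": 9.0, "b": 9.0, "c": 5.0}) == 1
        assert rank_of_selected("b", {"a": 9.0, "b": 9.0, "c": 5.0}) == 1

    def test_middle_value_gets_rank_two(self):
        assert rank_of_selected("c", {"a": 3.0, "b": 9.0, "c": 5.0}) == 2

    def test_missing_or_undefined_winner_errors(self):
        with pytest.raises(ValueError):
            rank_of_selected("zzz", {"a": 1.0})
        with pytest.raises(ValueError, match="undefined"):
            rank_of_selected("a", {"a": None, "b": 1.0})


class TestRankingCorrelation:
    def test_identical_rankings_correlate_perfectly(self):
        assert ranking_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_rankings_anticorrelate(self):
        assert ranking_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_one_swap_example(self):
        assert ranking_correlation([1, 2, 3, 4], [2, 1, 3, 4]) == pytest.approx(0.8)

    def test_constant_or_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            ranking_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ranking_correlation([1, 2], [2, 1])


class TestMetricsTable:
    def test_table_indexed_by_config_id(self):
        truth = [0, 0, 1, 1, 2, 2]
        cfgs = [PipelineConfig("lognorm", "all", 5, r) for r in (0.2, 0.5)]
        results = [fake_result(truth, config=c) for c in cfgs]
        table = metrics_table(results, truth)
        assert list(table.index) == [c.config_id for c in cfgs]
        assert list(table.columns) == list(METRIC_NAMES)
        assert (table["ari"] == 1.0).all()
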