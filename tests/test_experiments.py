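import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sparsemil.data import PaddedBatch
from sparsemil.experiments import (
    attention_heatmap,
    compare_methods,
    exact_signed_rank_p,
    feature_heatmap,
    label_primary_instances,
    mstar_sensitivity,
    reference_distance_report,
    run_ablation,
    selection_recall,
)
from sparsemil.model import ModelConfig, SparseAttentionMIL
from sparsemil.train import TrainConfig, cross_validate


@pytest.fixture(scope="module")
def ablation(small_bags, small_model_config):
    config = TrainConfig(epochs=8, seed=2)
    return run_ablation(small_bags, small_model_config, config, k=3), config


class TestAblation:
    def test_grid_is_exact(self, ablation):
        (rows, _), _ = ablation
        assert len(rows) == 4
        assert {(r.skip_on, r.sparse_on) for r in rows} == {
            (False, False),
            (True, False),
            (False, True),
            (True, True),
        }
        assert [r.variant for r in rows] == ["FC", "Skip", "Sparse", "Proposed"]

    def test_fc_row_matches_direct_cv(self, ablation, small_bags, small_model_config):
        (rows, _), config = ablation
        from dataclasses import replace

        direct = cross_validate(
            small_bags,
            replace(small_model_config, use_skip=False, pooling="softmax"),
            config,
            k=3,
        )
        fc = next(r for r in rows if r.variant == "FC")
        assert fc.mean_auc == direct.mean_auc
        assert fc.sd_auc == direct.sd_auc

    def test_shared_folds(self, ablation):
        (_, results), _ = ablation
        bag_sets = [
            frozenset(map(tuple, cv.predictions[["bag_id", "fold"]].to_numpy()))
            for cv in results.values()
        ]
        assert all(s == bag_sets[0] for s in bag_sets)


class TestMstarSensitivity:
    def test_row_per_grid_value(self, small_bags, small_model_config):
        table = mstar_sensitivity(
            small_bags, [20, 25], small_model_config, TrainConfig(epochs=4, seed=1), k=3
        )
        assert list(table["m_star"]) == [20, 25]
        assert table.shape == (2, 3)

    def test_invalid_grid(self, small_bags, small_model_config):
        with pytest.raises(ValueError, match=">= 1"):
            mstar_sensitivity(
                small_bags, [0], small_model_config, TrainConfig(epochs=1), k=3
            )

    def test_degenerate_capacity_one(self, small_bags, small_model_config):
        table = mstar_sensitivity(
            small_bags, [1], small_model_config, TrainConfig(epochs=3, seed=0), k=3
        )
        assert 0.0 <= table["mean_auc"].iloc[0] <= 1.0


class TestAttentionHeatmap:
    def test_rows_sorted_and_simplex(self, trained_small, small_bags):
        model, _ = trained_small
        alpha, mask, bag_ids = attention_heatmap(model, small_bags)
        sizes = mask.sum(axis=1)
        assert np.all(np.diff(sizes) >= 0)  # sorted by bag size
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(alpha[~mask] == 0)

    def test_sparsemax_has_zeros_softmax_none(self, trained_small, small_bags):
        model, _ = trained_small
        alpha, mask, _ = attention_heatmap(model, small_bags)
        assert np.sum((alpha == 0) & mask) > 0
        soft = SparseAttentionMIL(ModelConfig(p=8, pooling="softmax"), seed=0)
        alpha_s, mask_s, _ = attention_heatmap(soft, small_bags)
        assert np.sum((alpha_s == 0) & mask_s) == 0


class TestFeatureHeatmap:
    def test_range_and_shape(self, trained_small, small_bags):
        model, _ = trained_small
        out = feature_heatmap(model, small_bags)
        assert out.shape == (len(small_bags), 8)
        assert out.min() >= 0.0
        assert out.max() <= np.log(2.0) + 1e-12

    def test_constant_column_zeroed(self, trained_small, small_bags, monkeypatch, caplog):
        model, _ = trained_small
        import sparsemil.experiments as exp

        real = exp.extract_features

        def with_constant_col(bags, m):
            feats = real(bags, m).copy()
            feats[:, 0] = 3.14
            return feats

        monkeypatch.setattr(exp, "extract_features", with_constant_col)
        with caplog.at_level("WARNING"):
            out = exp.feature_heatmap(model, small_bags)
        assert np.all(out[:, 0] == 0)
        assert "constant" in caplog.text


class TestInstanceSelection:
    def test_support_flags(self, trained_small, small_bags):
        model, _ = trained_small
        bag = small_bags[0]
        flags = label_primary_instances(model, bag)
        batch = PaddedBatch.from_bags([bag])
        alpha = model.forward(batch.features, batch.mask)["alpha"][0]
        np.testing.assert_array_equal(flags, alpha[: bag.n_instances] > 0)

    def test_single_instance_bag(self, trained_small, small_bags):
        model, _ = trained_small
        singles = [b for b in small_bags if b.n_instances == 1]
        assert singles, "fixture should contain single-instance bags"
        assert label_primary_instances(model, singles[0]).tolist() == [True]

    def test_softmax_model_unsupported(self, small_bags):
        soft = SparseAttentionMIL(ModelConfig(p=8, pooling="softmax"), seed=0)
        with pytest.raises(ValueError, match="sparsemax"):
            label_primary_instances(soft, small_bags[0])

    def test_recall_on_trained_model(self, trained_small, small_bags):
        model, _ = trained_small
        assert 0.0 <= selection_recall(model, small_bags) <= 1.0


class TestReferenceDistance:
    def test_zero_reference_gives_norms(self, rng):
        X = rng.normal(size=(10, 4))
        report = reference_distance_report(
            X,
            np.array([True] * 5 + [False] * 5),
            np.ones(10, dtype=int),
            np.zeros((1, 4)),
        )
        norms = np.linalg.norm(X, axis=1)
        prim = report.query("group == 'primary'")["mean_distance"].iloc[0]
        assert prim == pytest.approx(norms[:5].mean())

    def test_identical_groups_nonsignificant(self, rng):
        X = np.tile(rng.normal(size=(5, 3)), (2, 1))
        flags = np.array([True] * 5 + [False] * 5)
        report = reference_distance_report(X, flags, np.zeros(10, int), rng.normal(size=(7, 3)))
        assert report["ranksum_p"].iloc[0] >= 0.99

    def test_shifted_primaries_are_farther(self, rng):
        reference = rng.normal(size=(50, 6))
        background = rng.normal(size=(40, 6))
        primaries = rng.normal(size=(40, 6)) + 8.0
        X = np.vstack([primaries, background])
        flags = np.array([True] * 40 + [False] * 40)
        report = reference_distance_report(X, flags, np.ones(80, int), reference)
        prim = report.query("group == 'primary'")["mean_distance"].iloc[0]
        other = report.query("group == 'non_primary'")["mean_distance"].iloc[0]
        assert prim > other
        assert report["ranksum_p"].iloc[0] < 1e-6

    def test_empty_group_skipped(self, rng, caplog):
        X = rng.normal(size=(6, 3))
        with caplog.at_level("WARNING"):
            report = reference_distance_report(
                X, np.zeros(6, bool), np.zeros(6, int), rng.normal(size=(4, 3))
            )
        assert np.isnan(report["ranksum_p"]).all()
        assert "empty" in caplog.text

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            reference_distance_report(
                rng.normal(size=(3, 4)), np.ones(3, bool), np.ones(3), rng.normal(size=(2, 5))
            )


class TestExactSignedRank:
    def test_all_one_sided_n10(self):
        assert exact_signed_rank_p(-np.ones(10)) == pytest.approx(2 / 1024)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = rng.normal(size=8)
            expected = stats.wilcoxon(d, method="exact").pvalue
            assert exact_signed_rank_p(d) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        d = np.array([1.0, 1.0, -1.0, 2.0])
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = []
        for bits in range(16):
            signs = [(bits >> j) & 1 for j in range(4)]
            ws.append(sum(r for r, s in zip(ranks, signs) if s))
        ws = np.array(ws)
        p_exp = min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))
        assert exact_signed_rank_p(d) == pytest.approx(p_exp, abs=1e-12)


class TestCompareMethods:
    @staticmethod
    def table(values, methods, datasets=None):
        values = np.asarray(values, dtype=float)
        cols = datasets or [f"d{j}" for j in range(values.shape[1])]
        return pd.DataFrame(values, index=methods, columns=cols)

    def test_dominant_method(self):
        tbl = self.table(
            np.vstack([np.linspace(0.8, 0.9, 10), np.linspace(0.6, 0.7, 10)]), ["A", "B"]
        )
        result = compare_methods(tbl, "A", "B")
        assert result.avg_rank["A"] == 1.0
        assert result.avg_rank["B"] == 2.0
        assert result.signed_rank_p == pytest.approx(2 / 1024)

    def test_identical_aucs_tie(self):
        tbl = self.table(np.full((2, 6), 0.75), ["A", "B"])
        result = compare_methods(tbl, "A", "B")
        assert (result.ranks.to_numpy() == 1.5).all()
        assert np.isnan(result.signed_rank_p)

    def test_single_dataset_degenerate(self, caplog):
        tbl = self.table([[0.9], [0.7]], ["A", "B"])
        with caplog.at_level("WARNING"):
            result = compare_methods(tbl, "A", "B")
        assert result.ranks["d0"].tolist() == [1.0, 2.0]
        assert np.isnan(result.signed_rank_p)

    def test_ranks_match_bruteforce_oracle(self, rng):
        values = rng.random((5, 8))
        tbl = self.table(values, [f"m{i}" for i in range(5)])
        result = compare_methods(tbl, "m0", "m1")
        for j, col in enumerate(tbl.columns):
            # independent oracle: sort-based ranking with midrank ties
            order = np.argsort(-values[:, j], kind="stable")
            ranks = np.empty(5)
            i = 0
            while i < 5:
                tied = [order[i]]
                while i + len(tied) < 5 and values[order[i + len(tied)], j] == values[order[i], j]:
                    tied.append(order[i + len(tied)])
                avg = np.mean(np.arange(i + 1, i + len(tied) + 1))
                for t in tied:
                    ranks[t] = avg
                i += len(tied)
            np.testing.assert_array_equal(result.ranks[col].to_numpy(), ranks)
        # every column of ranks sums like a permutation of 1..5
        np.testing.assert_allclose(result.ranks.sum(axis=0), 15.0)

    def test_unknown_method(self):
        tbl = self.table([[0.9, 0.8], [0.7, 0.6]], ["A", "B"])
        with pytest.raises(ValueError, match="not in table"):
            compare_methods(tbl, "A", "C")

    def test_needs_two_methods(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_methods(self.table([[0.9]], ["A"]), "A", "A")
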