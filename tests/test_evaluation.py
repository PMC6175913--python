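"""Classifier wrappers, hold-one-site-out leakage contracts, and the
normalization-effect comparison."""
import numpy as np
import pandas as pd
import pytest

from glandstab.evaluation import (
    evaluate_grid,
    fit_predict_scores,
    hold_one_site_out,
    normalization_effect,
    percent_improvement,
)
from glandstab.selection import empirical_auc
from glandstab.stability import preparation_instability
from glandstab.synthetic import (
    TableSpec,
    confounded_table_spec,
    simulate_feature_table,
)


@pytest.fixture(scope="module")
def eval_table():
    spec = confounded_table_spec(seed=42)
    table, _ = simulate_feature_table(spec)
    return table


class TestFitPredictScores:
    def test_separable_lda_perfect_auc(self):
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal((50, 2))
        x1 = rng.standard_normal((50, 2)) + 8.0
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], 50)
        scores = fit_predict_scores(x, y, x, "lda")
        assert empirical_auc(scores, y) == 1.0

    @pytest.mark.parametrize("kappa", ["lda", "qda", "svm", "rf"])
    def test_permuted_labels_near_chance(self, kappa):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 4))
        y = rng.permutation(np.repeat([0, 1], 100))
        x_test = rng.standard_normal((200, 4))
        y_test = rng.permutation(np.repeat([0, 1], 100))
        scores = fit_predict_scores(x, y, x_test, kappa, seed=0)
        assert abs(empirical_auc(scores, y_test) - 0.5) < 0.1

    def test_rf_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((80, 3))
        y = (x[:, 0] > 0).astype(int)
        a = fit_predict_scores(x, y, x, "rf", seed=7)
        b = fit_predict_scores(x, y, x, "rf", seed=7)
        assert np.array_equal(a, b)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            fit_predict_scores(np.zeros((4, 1)), [0, 0, 1, 1],
                               np.zeros((2, 1)), "mlp")

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_predict_scores(np.zeros((4, 1)), [1, 1, 1, 1],
                               np.zeros((2, 1)), "lda")


class TestHoldOneSiteOut:
    def test_one_fold_per_site(self, eval_table):
        report = hold_one_site_out(eval_table, "cancer", "roc", "lda",
                                   gated=False, seed=0)
        assert len(report.folds) == 4
        assert sorted(f.held_out_site for f in report.folds) == [
            "site1", "site2", "site3", "site4"
        ]

    def test_held_out_rows_cannot_leak_into_selection(self, eval_table):
        report = hold_one_site_out(eval_table, "cancer", "wlcx", "lda",
                                   gated=True, seed=0)
        for fold in report.folds:
            mutated = eval_table.copy()
            mask = mutated["site"] == fold.held_out_site
            feats = [c for c in mutated.columns if c.startswith("f")]
            rng = np.random.default_rng(99)
            mutated.loc[mask, feats] = rng.standard_normal(
                (mask.sum(), len(feats))
            )
            report_m = hold_one_site_out(mutated, "cancer", "wlcx", "lda",
                                         gated=True, seed=0)
            fold_m = next(
                f for f in report_m.folds
                if f.held_out_site == fold.held_out_site
            )
            assert fold_m.selected_features == fold.selected_features

    def test_gated_selection_respects_training_pi(self, eval_table):
        report = hold_one_site_out(eval_table, "cancer", "roc", "lda",
                                   gated=True, pi_threshold=0.25, seed=0)
        for fold in report.folds:
            train = eval_table[
                (eval_table["site"] != fold.held_out_site)
                & (eval_table["class"] == "noncancer")
            ]
            profile = preparation_instability(train)
            for feat in fold.selected_features:
                assert profile.pi[feat] < 0.25

    def test_threshold_above_one_reduces_to_ungated(self, eval_table):
        gated = hold_one_site_out(eval_table, "cancer", "roc", "lda",
                                  gated=True, pi_threshold=1.01, seed=0)
        ungated = hold_one_site_out(eval_table, "cancer", "roc", "lda",
                                    gated=False, seed=0)
        assert gated.mean_auc == ungated.mean_auc
        for fg, fu in zip(gated.folds, ungated.folds):
            assert fg.selected_features == fu.selected_features

    def test_aggregates_match_fold_records(self, eval_table):
        report = hold_one_site_out(eval_table, "cancer", "wlcx", "lda",
                                   gated=False, seed=0)
        aucs = np.array([f.auc for f in report.folds])
        assert report.mean_auc == pytest.approx(aucs.mean())
        assert report.std_auc == pytest.approx(aucs.std())

    def test_fewer_than_three_sites_rejected(self, eval_table):
        small = eval_table[eval_table["site"].isin(["site1", "site2"])]
        with pytest.raises(ValueError, match="3 sites"):
            hold_one_site_out(small, "cancer", "roc", "lda", gated=False)


class TestPercentImprovement:
    def test_arithmetic(self):
        assert percent_improvement(0.5, 0.5) == 0.0
        assert percent_improvement(0.6, 0.5) == pytest.approx(20.0)
        # rounded published pairs reproduce only approximately, which is
        # why the computation must use unrounded AUCs
        assert percent_improvement(0.75, 0.67) == pytest.approx(11.94, abs=0.01)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_improvement(0.5, 0.0)


class TestNormalizationEffect:
    def _tables(self):
        spec = TableSpec(seed=3, n_sites=3, n_regions_per_site=20,
                         class_balance=0.0, n_features=5,
                         unstable_features={0: 6.0})
        table, _ = simulate_feature_table(spec)
        return table

    def test_identical_tables_give_zero_deltas(self):
        table = self._tables()
        effect = normalization_effect(table, table)
        assert (effect.per_feature_delta == 0.0).all()

    def test_removed_shift_delta_equals_minus_pre(self):
        pre = self._tables()
        post = pre.copy()
        # normalization that fully removes the site shift on f000
        shifted = post["site"] == "site1"
        post.loc[shifted, "f000"] -= 6.0
        effect = normalization_effect(pre, post)
        assert effect.per_feature_delta["f000"] == pytest.approx(
            -effect.pi_pre["f000"]
        )
        assert effect.pi_pre["f000"] > 0

    def test_family_means_are_member_averages(self):
        table = self._tables()
        fam = {"f000": "a", "f001": "a", "f002": "b", "f003": "b",
               "f004": "b"}
        effect = normalization_effect(table, table, family_map=fam)
        summary = effect.family_summary.set_index("family")
        assert summary.loc["a", "pi_pre_mean"] == pytest.approx(
            effect.pi_pre[["f000", "f001"]].mean()
        )
        assert summary.loc["b", "pi_post_mean"] == pytest.approx(
            effect.pi_post[["f002", "f003", "f004"]].mean()
        )

    def test_mismatched_regions_rejected(self):
        table = self._tables()
        with pytest.raises(ValueError, match="same regions"):
            normalization_effect(table, table.iloc[:-2])


class TestEvaluateGrid:
    def test_grid_covers_all_cells(self, eval_table):
        grid = evaluate_grid(
            eval_table, "cancer", selectors=("wlcx", "roc"),
            classifiers=("lda", "rf"), seed=0,
        )
        assert len(grid) == 4
        assert set(grid["selector"]) == {"wlcx", "roc"}
        for _, row in grid.iterrows():
            assert row["pct_improvement"] == pytest.approx(
                percent_improvement(row["auc_sd_mean"], row["auc_d_mean"])
            )
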