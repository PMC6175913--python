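"""Feature selectors, the empirical AUC primitive and the stability gate."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glandstab._discriminant import cv_auc
from glandstab.selection import (
    GateError,
    empirical_auc,
    select_features,
    stability_gate,
)
from glandstab.stability import InstabilityProfile
from glandstab.synthetic import TableSpec, simulate_feature_table


def _profile(pi_values: dict) -> InstabilityProfile:
    return InstabilityProfile(pi=pd.Series(pi_values))


class TestStabilityGate:
    def test_three_site_exact_grid_keeps_only_zero(self):
        # exact-mode PI with 3 training sites lives on {0, 1/3, 2/3, 1}
        profile = _profile({"a": 0.0, "b": 1 / 3, "c": 2 / 3, "d": 1.0})
        assert stability_gate(list("abcd"), profile, 0.25) == ["a"]

    def test_threshold_above_one_keeps_everything(self):
        profile = _profile({"a": 0.0, "b": 0.5, "c": 1.0})
        assert stability_gate(list("abc"), profile, 1.01) == ["a", "b", "c"]

    def test_survivors_nested_in_threshold(self):
        profile = _profile({f"f{i}": i / 10 for i in range(10)})
        cands = list(profile.pi.index)
        prev = set()
        for t in (0.15, 0.35, 0.75, 1.01):
            cur = set(stability_gate(cands, profile, t))
            assert prev <= cur
            prev = cur

    def test_empty_survivor_set_raises(self):
        profile = _profile({"a": 0.9, "b": 1.0})
        with pytest.raises(GateError, match="stability gate"):
            stability_gate(["a", "b"], profile, 0.25)

    def test_missing_pi_value_raises(self):
        profile = _profile({"a": 0.0})
        with pytest.raises(ValueError, match="no PI value"):
            stability_gate(["a", "z"], profile, 0.25)

    def test_gate_is_strict_at_the_threshold(self):
        profile = _profile({"a": 0.25, "b": 0.249})
        assert stability_gate(["a", "b"], profile, 0.25) == ["b"]


class TestEmpiricalAuc:
    def test_perfect_orientation(self):
        assert empirical_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert empirical_auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_auc([1, 2, 3], [1, 1, 1])

    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=6,
                    max_size=25))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle(self, values):
        rng = np.random.default_rng(len(values))
        labels = rng.random(len(values)) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        got = empirical_auc(values, labels)
        pos = [v for v, l in zip(values, labels) if l]
        neg = [v for v, l in zip(values, labels) if not l]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        )
        assert got == pytest.approx(wins / (len(pos) * len(neg)))


@pytest.fixture(scope="module")
def planted_table():
    """One 3-sigma feature among 20 noise features."""
    spec = TableSpec(seed=13, n_sites=3, n_regions_per_site=30,
                     n_features=21, discriminative_features={7: 3.0})
    table, _ = simulate_feature_table(spec)
    feats = [f"f{i:03d}" for i in range(21)]
    y = (table["class"] == "cancer").to_numpy()
    return table[feats], y


class TestSelectFeatures:
    @pytest.mark.parametrize("selector", ["sfs", "wlcx", "mrmr", "roc"])
    def test_planted_feature_ranked_first(self, planted_table, selector):
        x, y = planted_table
        result = select_features(x, y, selector, k=3, seed=0)
        assert result.features[0] == "f007"

    def test_roc_k1_equals_argmax_of_standalone_auc(self, planted_table):
        x, y = planted_table
        result = select_features(x, y, "roc", k=1, seed=0)
        scores = {
            c: max(empirical_auc(x[c], y), 1 - empirical_auc(x[c], y))
            for c in x.columns
        }
        assert result.features[0] == max(scores, key=scores.get)

    def test_sfs_k1_equals_exhaustive_cv_loop(self, planted_table):
        x, y = planted_table
        result = select_features(x, y, "sfs", k=1, seed=3)
        best = max(
            x.columns,
            key=lambda c: cv_auc(x[c].to_numpy(), y, iterations=10,
                                 folds=3, seed=3),
        )
        assert result.features == [best]

    @pytest.mark.parametrize("selector", ["sfs", "wlcx", "mrmr", "roc"])
    def test_deterministic_given_seed(self, planted_table, selector):
        x, y = planted_table
        a = select_features(x, y, selector, k=4, seed=11)
        b = select_features(x, y, selector, k=4, seed=11)
        assert a.features == b.features

    def test_constant_feature_never_crashes(self, planted_table):
        x, y = planted_table
        x = x.copy()
        x["f000"] = 1.0
        for selector in ("wlcx", "mrmr", "roc"):
            result = select_features(x, y, selector, k=3, seed=0)
            assert len(result.features) == 3

    def test_anticorrelated_feature_not_penalized_by_roc(self):
        rng = np.random.default_rng(0)
        n = 120
        y = rng.random(n) < 0.5
        x = pd.DataFrame({
            "anti": -3.0 * y + rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        })
        result = select_features(x, y, "roc", k=1, seed=0)
        assert result.features == ["anti"]

    def test_too_few_candidates_raise(self, planted_table):
        x, y = planted_table
        with pytest.raises(ValueError, match="at least"):
            select_features(x[["f000", "f001"]], y, "roc", k=5, seed=0)

    def test_unknown_selector_rejected(self, planted_table):
        x, y = planted_table
        with pytest.raises(ValueError, match="unknown selector"):
            select_features(x, y, "lasso", k=2, seed=0)
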