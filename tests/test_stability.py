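"""PI / LI statistics, the gland-removal perturbation and the PI-AUC map."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

from glandstab.stability import (
    gland_removal_perturbation,
    latent_instability,
    pi_auc_map,
    preparation_instability,
)
from glandstab.synthetic import TableSpec, simulate_feature_table


def _table(n_sites=3, n_per_site=10, n_features=4, seed=0, **kwargs):
    spec = TableSpec(seed=seed, n_sites=n_sites, n_regions_per_site=n_per_site,
                     class_balance=0.0, n_features=n_features, **kwargs)
    table, _ = simulate_feature_table(spec)
    return table


class TestPreparationInstability:
    def test_identical_values_give_zero_pi(self):
        table = _table()
        table["f000"] = np.tile(np.arange(10.0), 3)  # same values per site
        profile = preparation_instability(table)
        assert profile.pi["f000"] == 0.0

    def test_strong_single_site_shift_gives_two_thirds(self):
        table = _table(n_per_site=12, unstable_features={0: 10.0})
        profile = preparation_instability(table)
        assert profile.pi["f000"] == pytest.approx(2.0 / 3.0)

    def test_exact_mode_values_on_multiples_of_pair_count(self):
        table = _table(n_sites=4, n_per_site=8, n_features=10, seed=3)
        profile = preparation_instability(table)
        grid = np.arange(7) / 6.0
        for v in profile.pi:
            assert np.isclose(grid, v).any()

    def test_exact_mode_matches_brute_force_oracle(self):
        table = _table(n_sites=4, n_per_site=10, n_features=6, seed=5,
                       unstable_features={2: [0.0, 1.0, 2.0, 3.0]})
        profile = preparation_instability(table, alpha=0.05)
        sites = sorted(table["site"].unique())
        for feat in profile.pi.index:
            rejections = 0
            pairs = list(itertools.combinations(sites, 2))
            for a, b in pairs:
                _, p = ranksums(
                    table.loc[table["site"] == a, feat],
                    table.loc[table["site"] == b, feat],
                )
                rejections += p < 0.05
            assert profile.pi[feat] == pytest.approx(rejections / len(pairs))

    def test_small_site_error_names_site(self):
        table = _table()
        table = table[~((table["site"] == "site2")
                        & (table["region_id"] > "site2_r002"))]
        with pytest.raises(ValueError, match="site2"):
            preparation_instability(table)

    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-3.0, max_value=3.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transform(self, scale, shift):
        table = _table(seed=7, unstable_features={1: 2.0})
        transformed = table.copy()
        feats = [c for c in table.columns if c.startswith("f")]
        transformed[feats] = np.exp(scale * table[feats] + shift)
        a = preparation_instability(table).pi
        b = preparation_instability(transformed).pi
        pd.testing.assert_series_equal(a, b)

    def test_subsampled_with_full_size_equals_exact(self):
        table = _table(seed=9, unstable_features={0: 1.5})
        exact = preparation_instability(table, mode="exact").pi
        sub = preparation_instability(
            table, mode="subsampled", repetitions=20, subsample_size=10,
            seed=1,
        ).pi
        pd.testing.assert_series_equal(exact, sub)

    def test_values_confined_to_unit_interval(self):
        table = _table(seed=11, unstable_features={0: 8.0, 1: 0.5})
        profile = preparation_instability(table)
        assert ((profile.pi >= 0) & (profile.pi <= 1)).all()


class TestLatentInstability:
    def test_type_one_calibration(self):
        table = _table(n_sites=1, n_per_site=60, n_features=50, seed=2)
        li = latent_instability(table, repetitions=200, seed=0)
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(li.mean() - 0.05) < 3 * se + 0.01

    def test_constant_feature_is_zero(self):
        table = _table(n_sites=1, n_per_site=20)
        table["f000"] = 1.0
        li = latent_instability(table, repetitions=50, seed=0)
        assert li["f000"] == 0.0

    def test_deterministic_given_seed(self):
        table = _table(n_sites=1, n_per_site=20, seed=4)
        a = latent_instability(table, repetitions=30, seed=9)
        b = latent_instability(table, repetitions=30, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_regions_raise(self):
        table = _table(n_sites=1, n_per_site=6)
        with pytest.raises(ValueError, match="at least 8"):
            latent_instability(table)


class TestGlandRemovalPerturbation:
    def _count_feature(self, glands):
        def fn(indices):
            return pd.Series({"gland count": float(len(indices))})

        return fn

    def test_grid_shape_and_zero_origin(self, base_roi):
        _, glands = base_roi
        result = gland_removal_perturbation(
            None, glands, feature_fn=self._count_feature(glands), seed=0
        )
        assert result.percent_change.shape[0] == 21
        assert list(result.levels_pct) == list(range(21))
        assert result.sims_per_level == 10
        assert (result.percent_change.loc[0] == 0.0).all()

    def test_gland_count_feature_tracks_removal_level(self, base_roi):
        _, glands = base_roi
        result = gland_removal_perturbation(
            None, glands, feature_fn=self._count_feature(glands), seed=0
        )
        n = len(glands)
        at_10 = result.percent_change.loc[10, "gland count"]
        expected = -100.0 * round(0.10 * n) / n
        assert at_10 == pytest.approx(expected, abs=1.0)

    def test_too_few_glands_raise(self, base_roi):
        _, glands = base_roi
        with pytest.raises(ValueError, match="at least 10"):
            gland_removal_perturbation(
                None, glands.subset(range(5)),
                feature_fn=self._count_feature(glands),
            )


class TestPiAucMap:
    def _task_table(self, seed=0, effect=0.0, n_per_site=40, n_sites=3):
        spec = TableSpec(seed=seed, n_sites=n_sites,
                         n_regions_per_site=n_per_site, n_features=3,
                         discriminative_features={0: effect} if effect else {})
        table, _ = simulate_feature_table(spec)
        return table

    def test_perfectly_separating_feature_has_auc_one(self):
        table = self._task_table()
        table["f000"] = np.where(table["class"] == "cancer", 10.0, 0.0)
        table["f000"] += np.tile(
            np.linspace(0, 0.5, len(table) // 3), 3
        )[: len(table)]
        points = pi_auc_map(table, cv_iterations=10, seed=0)
        by_name = {p.feature: p for p in points}
        assert by_name["f000"].mean_auc == pytest.approx(1.0)

    def test_noise_feature_near_half(self):
        # sampling sd of a single-site empirical AUC at n=250 is ~0.037;
        # averaging 4 sites brings the null deviation well inside 0.05
        table = self._task_table(seed=3, n_per_site=250, n_sites=4)
        points = pi_auc_map(table, cv_iterations=20, seed=0)
        by_name = {p.feature: p for p in points}
        assert abs(by_name["f001"].mean_auc - 0.5) < 0.05

    def test_pi_matches_standalone_computation(self):
        spec = TableSpec(seed=5, n_sites=3, n_regions_per_site=30,
                         n_features=3, unstable_features={1: 3.0})
        table, _ = simulate_feature_table(spec)
        points = pi_auc_map(table, cv_iterations=5, seed=0)
        nc = table[table["class"] == "noncancer"]
        profile = preparation_instability(nc)
        for p in points:
            assert p.pi == profile.pi[p.feature]

    def test_single_class_site_names_site(self):
        table = self._task_table(seed=7)
        table.loc[table["site"] == "site2", "class"] = "noncancer"
        with pytest.raises(ValueError, match="site2"):
            pi_auc_map(table, cv_iterations=2)
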