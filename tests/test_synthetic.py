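"""Synthetic ROI and feature-table generators: determinism, ground truth,
and the statistical structure the stability analysis relies on."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ranksums
from shapely.geometry import Point, Polygon

from glandstab.selection import empirical_auc
from glandstab.stability import preparation_instability
from glandstab.synthetic import (
    RoiSpec,
    SiteEffect,
    TableSpec,
    apply_site_effect,
    roi_spec_for_class,
    simulate_feature_table,
    simulate_roi,
)


class TestSimulateRoi:
    def test_deterministic_given_seed(self):
        spec = RoiSpec(seed=1, n_glands=15, image_size_px=(384, 384))
        roi_a, glands_a = simulate_roi(spec)
        roi_b, glands_b = simulate_roi(spec)
        assert np.array_equal(roi_a.image, roi_b.image)
        assert len(glands_a) == len(glands_b)
        for ga, gb in zip(glands_a, glands_b):
            assert np.array_equal(ga.boundary, gb.boundary)

    def test_ground_truth_construction(self):
        spec = RoiSpec(seed=3, n_glands=3, lumen_fraction=1.0,
                       image_size_px=(384, 384))
        roi, glands = simulate_roi(spec)
        assert len(glands) == 3
        h, w = roi.image.shape[:2]
        for g in glands:
            assert Polygon(g.boundary).contains(Point(g.centroid))
            assert g.boundary[:, 0].min() >= 0
            assert g.boundary[:, 0].max() < w
            assert g.boundary[:, 1].min() >= 0
            assert g.boundary[:, 1].max() < h
            assert len(g.lumen_pixels) > 0

    def test_crowding_reduces_nearest_centroid_distance(self):
        kwargs = dict(n_glands=30, image_size_px=(512, 512),
                      gland_radius_mean_um=24.0)
        _, sparse = simulate_roi(RoiSpec(seed=7, crowding=1.0, **kwargs))
        _, dense = simulate_roi(RoiSpec(seed=7, crowding=2.0, **kwargs))

        def mean_nn(glands):
            d = squareform(pdist(glands.centroids))
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        assert mean_nn(dense) < mean_nn(sparse)

    def test_lumen_fraction_controls_lumenless_glands(self):
        spec = roi_spec_for_class("gleason4", seed=5)
        _, glands = simulate_roi(spec)
        n_lumen = sum(1 for g in glands if len(g.lumen_pixels) > 0)
        assert n_lumen == round(spec.lumen_fraction * spec.n_glands)

    def test_infeasible_placement_raises_with_parameters(self):
        spec = RoiSpec(seed=0, n_glands=200, image_size_px=(200, 200),
                       gland_radius_mean_um=40.0, crowding=5.0)
        with pytest.raises(ValueError, match="200"):
            simulate_roi(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            RoiSpec(seed=0, lumen_fraction=0.0)
        with pytest.raises(ValueError):
            RoiSpec(seed=0, class_label="benign")


class TestSiteEffect:
    def test_identity_effect_is_bit_identical(self, small_roi):
        roi, _ = small_roi
        out = apply_site_effect(roi, SiteEffect("s"))
        assert np.array_equal(out.image, roi.image)
        assert out.site == "s"

    def test_rgb_shift_is_exact_arithmetic(self, small_roi):
        roi, _ = small_roi
        capped = roi.image.copy()
        capped[..., 0] = np.minimum(capped[..., 0], 235)
        roi_c = type(roi)(image=capped, microns_per_pixel=roi.microns_per_pixel)
        out = apply_site_effect(roi_c, SiteEffect("s", rgb_shift=(20, 0, 0)))
        delta = out.image[..., 0].astype(float) - capped[..., 0].astype(float)
        assert np.allclose(delta, 20.0)
        assert np.array_equal(out.image[..., 1:], capped[..., 1:])

    def test_distinct_effects_separate_mean_intensity(self, small_roi):
        roi, glands = small_roi
        eff_a = SiteEffect("a", rgb_shift=(5, 2, 0), gland_dropout_rate=0.1)
        eff_b = SiteEffect("b", rgb_shift=(-5, -2, 0), gland_dropout_rate=0.1)
        means_a = [
            apply_site_effect(roi, eff_a, seed=i, glands=glands).image.mean()
            for i in range(30)
        ]
        means_b = [
            apply_site_effect(roi, eff_b, seed=i + 100, glands=glands).image.mean()
            for i in range(30)
        ]
        _, p = ranksums(means_a, means_b)
        assert p < 0.05

    def test_dropout_requires_ground_truth(self, small_roi):
        roi, _ = small_roi
        with pytest.raises(ValueError, match="GlandSet"):
            apply_site_effect(roi, SiteEffect("s", gland_dropout_rate=0.2))


class TestSimulateFeatureTable:
    def test_deterministic_and_annotated(self):
        spec = TableSpec(seed=4, n_features=8,
                         discriminative_features={1: 2.0},
                         unstable_features={2: [1.0, 0, 0, 0]})
        a, truth = simulate_feature_table(spec)
        b, _ = simulate_feature_table(spec)
        assert a.equals(b)
        assert truth["discriminative"] == {"f001": 2.0}
        assert truth["unstable"] == {"f002": [1.0, 0, 0, 0]}
        assert list(a.columns[:4]) == ["region_id", "patient_id", "site",
                                       "class"]

    def test_invalid_feature_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            TableSpec(seed=0, n_features=5, discriminative_features={9: 1.0})

    def test_single_site_shift_gives_pi_two_thirds(self):
        spec = TableSpec(seed=0, n_sites=3, n_regions_per_site=40,
                         n_features=5, unstable_features={0: 10.0})
        table, _ = simulate_feature_table(spec)
        profile = preparation_instability(
            table[table["class"] == "noncancer"]
        )
        assert profile.pi["f000"] == pytest.approx(2.0 / 3.0)

    def test_discriminative_effect_yields_high_auc(self):
        spec = TableSpec(seed=6, n_sites=3, n_regions_per_site=80,
                         n_features=4, discriminative_features={0: 2.0})
        table, _ = simulate_feature_table(spec)
        y = (table["class"] == "cancer").to_numpy()
        # closed-form AUC of two unit-variance Gaussians 2 sigma apart:
        # Phi(2 / sqrt(2)) = 0.921
        assert empirical_auc(table["f000"], y) > 0.85

    def test_null_rejection_rate_near_alpha(self):
        spec = TableSpec(seed=8, n_sites=3, n_regions_per_site=60,
                         class_balance=0.0, n_features=150)
        table, _ = simulate_feature_table(spec)
        profile = preparation_instability(table)
        assert abs(profile.pi.mean() - 0.05) < 0.03

    def test_site_shift_monotone_in_expected_pi(self):
        pis = []
        for shift in (0.5, 5.0):
            vals = []
            for seed in range(3):
                spec = TableSpec(seed=seed, n_sites=3, n_regions_per_site=30,
                                 class_balance=0.0, n_features=3,
                                 unstable_features={0: shift})
                table, _ = simulate_feature_table(spec)
                vals.append(preparation_instability(table).pi["f000"])
            pis.append(np.mean(vals))
        assert pis[1] >= pis[0]

    def test_lognormal_family_is_monotone_image_of_gaussian(self):
        base = TableSpec(seed=9, n_features=4, unstable_features={0: 3.0})
        logn = TableSpec(seed=9, n_features=4, unstable_features={0: 3.0},
                         noise_family="lognormal")
        tg, _ = simulate_feature_table(base)
        tl, _ = simulate_feature_table(logn)
        feats = ["f000", "f001", "f002", "f003"]
        assert np.allclose(np.exp(tg[feats].to_numpy()), tl[feats].to_numpy())
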