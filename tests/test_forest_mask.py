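import numpy as np
import pytest

from betelmap.core_io import Affine, FeatureStack, RasterGrid
from betelmap.forest_mask import (
    ClassSignature,
    Rule,
    RuleConfig,
    RuleSet,
    SIGNATURE_FEATURES,
    apply_rules,
    compute_signatures,
    derive_rules,
    gndvi_threshold,
    majority_filter,
    mmu_filter,
    refine_with_gndvi,
)


def signature_scene(rng, n=40):
    """Four well-separated super-class blocks over the signature features."""
    means = {"forest": -9.0, "cropland": -14.0, "built_up": -4.0, "water": -22.0}
    codes = {"forest": 2, "cropland": 4, "built_up": 5, "water": 6}
    labels = np.zeros((n, n), dtype=np.int32)
    base = np.zeros((n, n))
    q = n // 4
    for i, (name, mu) in enumerate(means.items()):
        sl = slice(i * q, (i + 1) * q)
        labels[sl] = codes[name]
        base[sl] = mu + rng.normal(0, 0.4, size=(q, n))
    stack = FeatureStack()
    for i, f in enumerate(SIGNATURE_FEATURES):
        # distinct affine versions of the base field keep class separation
        stack.add(f, RasterGrid(base * (1.0 + 0.05 * i) + 0.1 * i))
    groups = {"forest": [2], "cropland": [4], "built_up": [5], "water": [6]}
    return stack, RasterGrid(labels, nodata=-1), groups


class TestSignatures:
    def test_percentiles_monotone_every_feature(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        for s in sigs.values():
            for f in SIGNATURE_FEATURES:
                assert (np.diff(s.percentiles[f]) >= 0).all()

    def test_constant_feature_degenerate_histogram(self, rng):
        stack, labels, groups = signature_scene(rng)
        const = FeatureStack({f: RasterGrid(np.full((40, 40), 1.5))
                              for f in SIGNATURE_FEATURES})
        sigs = compute_signatures(const, labels, groups)
        edges, counts = sigs["forest"].histograms["VV"]
        assert (counts > 0).sum() == 1

    def test_water_vv_below_forest(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        assert sigs["water"].pct("VV", 95) < sigs["forest"].pct("VV", 5)

    def test_missing_superclass_rejected(self, rng):
        stack, labels, groups = signature_scene(rng)
        del groups["water"]
        with pytest.raises(ValueError, match="water"):
            compute_signatures(stack, labels, groups)


class TestDeriveRules:
    def test_intervals_valid_and_audit_log(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        rs = derive_rules(sigs)
        assert all(r.lo <= r.hi for r in rs.rules)
        assert len(rs.include_rules) == 6
        text = rs.to_text()
        assert "include-forest" in text and "exclude-water" in text

    def test_separated_classes_classify_forest_pixels(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        mask = apply_rules(stack, derive_rules(sigs))
        forest = labels.values == 2
        assert (mask.values[forest] == 1).mean() >= 0.85
        assert (mask.values[~forest] == 1).mean() <= 0.01

    def test_degenerate_water_equals_forest_warns(self, rng):
        stack, labels, groups = signature_scene(rng)
        # water radiometrically identical to forest
        labels2 = labels.values.copy()
        labels2[labels2 == 6] = 2
        labels2[:5, :5] = 6  # water pixels drawn from the forest block
        lab = RasterGrid(labels2, nodata=-1)
        sigs = compute_signatures(stack, lab, groups)
        with pytest.warns(UserWarning, match="overlap"):
            derive_rules(sigs)

    def test_rule_interval_validation(self):
        with pytest.raises(ValueError, match="lo > hi"):
            Rule("VV", "forest", 1.0, -1.0, "include-forest")


class TestApplyRules:
    def test_centroid_membership(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        rs = derive_rules(sigs)
        mask = apply_rules(stack, rs)
        # block centers: forest rows at top quarter, water at bottom
        assert mask.values[5, 20] == 1
        assert mask.values[35, 20] == 0

    def test_vote_threshold_monotone(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        areas = []
        for m in range(1, 7):
            rs = derive_rules(sigs, RuleConfig(vote_threshold=m))
            areas.append((apply_rules(stack, rs).values == 1).sum())
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_missing_feature_rejected(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        rs = derive_rules(sigs)
        partial = FeatureStack({"VV": stack["VV"]})
        with pytest.raises(KeyError):
            apply_rules(partial, rs)

    def test_vote_threshold_bounds_checked(self):
        rules = [Rule("VV", "forest", -12, -6, "include-forest")]
        with pytest.raises(ValueError, match="vote threshold"):
            RuleSet(rules, vote_threshold=5)


class TestGndviThreshold:
    def test_degenerate_constant_distribution(self):
        g = RasterGrid(np.full((10, 10), 0.5))
        assert gndvi_threshold(g, np.ones((10, 10), bool)) == pytest.approx(0.5)

    def test_interpolated_order_statistic(self):
        # 100 evenly spaced values on [0,1]: p5 by linear interpolation
        vals = np.linspace(0, 1, 100).reshape(10, 10)
        want = np.percentile(np.linspace(0, 1, 100), 5, method="linear")
        got = gndvi_threshold(RasterGrid(vals), np.ones((10, 10), bool))
        assert got == pytest.approx(want)
        # hand computation: index 4.95 between the 5th and 6th order stats
        assert got == pytest.approx(4.95 / 99.0)

    def test_too_few_pixels_rejected(self):
        g = RasterGrid(np.full((4, 4), 0.5))
        with pytest.raises(ValueError, match="20"):
            gndvi_threshold(g, np.ones((4, 4), bool))

    def test_affine_equivariance(self, rng):
        vals = rng.random((10, 10))
        m = np.ones((10, 10), bool)
        t = gndvi_threshold(RasterGrid(vals), m)
        t2 = gndvi_threshold(RasterGrid(3.0 * vals + 1.0), m)
        assert t2 == pytest.approx(3.0 * t + 1.0)


class TestRefineWithGndvi:
    def mask_and_gndvi(self, rng):
        mask = RasterGrid((rng.random((12, 12)) > 0.4).astype(np.int16), nodata=-1)
        gndvi = RasterGrid(rng.random((12, 12)))
        return mask, gndvi

    def test_threshold_minus_one_is_identity(self, rng):
        mask, gndvi = self.mask_and_gndvi(rng)
        out = refine_with_gndvi(mask, gndvi, -1.0)
        np.testing.assert_array_equal(out.values, mask.values)

    def test_threshold_plus_one_empties_mask(self, rng):
        mask, gndvi = self.mask_and_gndvi(rng)
        out = refine_with_gndvi(mask, gndvi, 1.0 + 1e-9)
        assert (out.values == 1).sum() == 0

    def test_monotone_in_threshold_and_never_adds(self, rng):
        mask, gndvi = self.mask_and_gndvi(rng)
        prev = None
        for thr in np.linspace(-0.2, 1.0, 7):
            out = refine_with_gndvi(mask, gndvi, thr)
            assert not ((out.values == 1) & (mask.values != 1)).any()
            area = (out.values == 1).sum()
            if prev is not None:
                assert area <= prev
            prev = area


def oracle_mode_filter(values, valid, window):
    """Brute-force windowed mode with center-tie retention."""
    h, w = values.shape
    half = window // 2
    out = values.copy()
    for i in range(h):
        for j in range(w):
            if not valid[i, j]:
                continue
            counts = {}
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and valid[ii, jj]:
                        counts[values[ii, jj]] = counts.get(values[ii, jj], 0) + 1
            best = max(counts.values())
            if counts.get(values[i, j], 0) == best:
                continue  # tie or winner includes center -> keep center
            winners = sorted(c for c, k in counts.items() if k == best)
            out[i, j] = winners[0]
    return out


class TestMajorityFilter:
    def test_constant_map_unchanged(self):
        g = RasterGrid(np.full((10, 10), 3, dtype=np.int32), nodata=-1)
        np.testing.assert_array_equal(majority_filter(g, 5).values, g.values)

    def test_isolated_salt_pixel_removed(self):
        vals = np.zeros((9, 9), dtype=np.int32)
        vals[4, 4] = 1
        out = majority_filter(RasterGrid(vals, nodata=-1), 5)
        assert out.values[4, 4] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_windowed_mode(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 2, size=(12, 12)).astype(np.int32)
        g = RasterGrid(vals, nodata=-1)
        got = majority_filter(g, 3).values
        want = oracle_mode_filter(vals, np.ones_like(vals, bool), 3)
        np.testing.assert_array_equal(got, want)

    def test_nodata_ignored_and_preserved(self):
        vals = np.zeros((9, 9), dtype=np.int32)
        vals[0, :] = -1
        out = majority_filter(RasterGrid(vals, nodata=-1), 3)
        assert (out.values[0] == -1).all()


class TestMmuFilter:
    def grid(self, vals):
        # 10 m pixels -> 0.01 ha each; 0.5 ha = 50 pixels
        return RasterGrid(vals.astype(np.int16), Affine(), nodata=-1)

    def test_threshold_boundary_49_removed_50_kept(self):
        vals = np.zeros((20, 20))
        vals[:7, :7] = 1
        vals.ravel()[np.flatnonzero(vals.ravel())[0]] = 1
        small = np.zeros((20, 20))
        small[:7, :7] = 1  # 49 pixels
        small[0, 0] = 0
        out = mmu_filter(self.grid(small))
        assert (out.values == 1).sum() == 0
        big = np.zeros((20, 20))
        big[:10, :5] = 1  # 50 pixels
        out = mmu_filter(self.grid(big))
        assert (out.values == 1).sum() == 50

    def test_empty_mask_stays_empty(self):
        out = mmu_filter(self.grid(np.zeros((10, 10))))
        assert (out.values == 1).sum() == 0

    def test_diagonal_touching_blobs_count_as_one_component(self):
        vals = np.zeros((30, 30))
        vals[:6, :5] = 1          # 30 pixels
        vals[6:12, 5:10] = 1      # 30 pixels, diagonal contact at (5,4)/(6,5)
        out = mmu_filter(self.grid(vals))
        assert (out.values == 1).sum() == 60


class TestPipelineOrderInvariant:
    def test_post_rule_stages_only_remove_forest(self, rng):
        stack, labels, groups = signature_scene(rng)
        sigs = compute_signatures(stack, labels, groups)
        mask = apply_rules(stack, derive_rules(sigs))
        gndvi = RasterGrid(rng.random((40, 40)))
        refined = refine_with_gndvi(mask, gndvi, 0.3)
        assert not ((refined.values == 1) & (mask.values != 1)).any()
        cleaned = mmu_filter(refined)
        assert not ((cleaned.values == 1) & (refined.values != 1)).any()
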