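"""Feature-bank tests.

The GLCM brute-force oracle here enumerates co-occurring pixel pairs
directly from definitions (counts -> normalized joint distribution ->
moments), independently of the windowed numba engine and of the
single-window helper in the package.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betelmap.core_io import RasterGrid
from betelmap.features import (
    FEATURE_REGISTRY,
    GLCM_STATS,
    GlcmConfig,
    OPTICAL_FEATURES,
    SAR_FEATURES,
    build_stack,
    canonical_name,
    glcm_features,
    glcm_stats,
    quantize,
    sar_indices,
    vegetation_indices,
)
from betelmap.synthetic_scene import OPTICAL_BANDS


# --------------------------------------------------------------------------
# independent GLCM oracle: exhaustive pair enumeration from definitions
# --------------------------------------------------------------------------

def oracle_glcm_stats(img, levels, offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    per_orientation = []
    h, w = img.shape
    for dr, dc in offsets:
        pairs = {}
        n = 0
        for i in range(h):
            for j in range(w):
                ii, jj = i + dr, j + dc
                if 0 <= ii < h and 0 <= jj < w:
                    for a, b in ((img[i, j], img[ii, jj]), (img[ii, jj], img[i, j])):
                        pairs[(a, b)] = pairs.get((a, b), 0) + 1
                        n += 1
        P = {k: v / n for k, v in pairs.items()}
        mu = sum(i * p for (i, _), p in P.items())
        var = sum((i - mu) ** 2 * p for (i, _), p in P.items())
        home = sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items())
        cont = sum(p * (i - j) ** 2 for (i, j), p in P.items())
        diss = sum(p * abs(i - j) for (i, j), p in P.items())
        corr = (sum(p * (i - mu) * (j - mu) for (i, j), p in P.items()) / var
                if var > 0 else 0.0)
        entr = -sum(p * math.log(p) for p in P.values())
        asm = sum(p * p for p in P.values())
        per_orientation.append(dict(Home=home, Cont=cont, Corr=corr, Mean=mu,
                                    Vari=var, Diss=diss, Entr=entr, Asm=asm))
    return {k: np.mean([o[k] for o in per_orientation]) for k in GLCM_STATS}


class TestGlcmStats:
    def test_constant_window_degenerate_values(self):
        st_ = glcm_stats(np.full((5, 5), 3, dtype=np.int64), levels=8)
        assert st_["Cont"] == 0.0
        assert st_["Diss"] == 0.0
        assert st_["Asm"] == 1.0
        assert st_["Home"] == 1.0
        assert st_["Entr"] == 0.0
        assert st_["Corr"] == 0.0  # zero-variance convention
        assert st_["Mean"] == 3.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 9, size=2)
        img = rng.integers(0, 8, size=(h, w)).astype(np.int64)
        got = glcm_stats(img, levels=8)
        want = oracle_glcm_stats(img, 8)
        for k in GLCM_STATS:
            assert got[k] == pytest.approx(want[k], abs=1e-9), k

    def test_matches_skimage_single_orientation(self):
        skimage = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(7)
        img = rng.integers(0, 8, size=(8, 8)).astype(np.uint8)
        P = skimage.graycomatrix(img, [1], [0], levels=8, symmetric=True,
                                 normed=True)[:, :, 0, 0]
        from betelmap.features import glcm_from_pairs, glcm_stats_from_matrix
        mine = glcm_from_pairs(img.astype(np.int64), 8, (0, 1))
        np.testing.assert_allclose(mine, P, atol=1e-12)
        props = glcm_stats_from_matrix(mine)
        for name, sk_name in [("Cont", "contrast"), ("Home", "homogeneity"),
                              ("Diss", "dissimilarity"), ("Corr", "correlation"),
                              ("Asm", "ASM")]:
            sk = skimage.graycoprops(P[:, :, None, None], sk_name)[0, 0]
            assert props[name] == pytest.approx(sk, abs=1e-9)

    def test_windowed_engine_matches_per_window_stats(self):
        rng = np.random.default_rng(3)
        vals = rng.random((9, 9))
        cfg = GlcmConfig(window=5, levels=8, range_values=(0.0, 1.0))
        grids = glcm_features(RasterGrid(vals), cfg, prefix="T_")
        q = quantize(vals, cfg)
        # interior pixel (4,4): window is fully inside, no padding effects
        win = q[2:7, 2:7].astype(np.int64)
        want = glcm_stats(win, 8)
        for k in GLCM_STATS:
            assert grids[f"T_{k}"].values[4, 4] == pytest.approx(want[k], abs=1e-9)

    def test_quantization_shift_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random((12, 12))
        cfg_a = GlcmConfig(window=5, levels=16, range_values=(0.0, 1.0))
        cfg_b = GlcmConfig(window=5, levels=16, range_values=(10.0, 11.0))
        a = glcm_features(RasterGrid(vals), cfg_a, prefix="T_")
        b = glcm_features(RasterGrid(vals + 10.0), cfg_b, prefix="T_")
        for k in GLCM_STATS:
            np.testing.assert_allclose(a[f"T_{k}"].values, b[f"T_{k}"].values)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            glcm_features(RasterGrid(np.zeros((3, 3))), GlcmConfig(window=5))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matrix_normalization_and_ranges(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 6, size=(6, 6)).astype(np.int64)
        stats = glcm_stats(img, levels=6)
        assert 0 < stats["Asm"] <= 1
        assert stats["Entr"] >= 0
        assert 0 <= stats["Home"] <= 1


class TestSarIndices:
    def grids(self, vv, vh):
        return RasterGrid(np.full((2, 2), float(vv))), RasterGrid(np.full((2, 2), float(vh)))

    def test_symmetric_input(self):
        out = sar_indices(*self.grids(-10, -10))
        assert out["DIF"].values[0, 0] == 0
        assert out["RAT1"].values[0, 0] == pytest.approx(1.0)
        assert out["RAT2"].values[0, 0] == pytest.approx(1.0)
        assert out["NDI"].values[0, 0] == 0
        assert out["AVE"].values[0, 0] == -10
        assert out["NL"].values[0, 0] == pytest.approx(-5.0)

    def test_arithmetic_example(self):
        out = sar_indices(*self.grids(-6, -12))
        assert out["DIF"].values[0, 0] == pytest.approx(6.0)
        assert out["AVE"].values[0, 0] == pytest.approx(-9.0)
        # (VV-VH)/(VV+VH) = 6 / -18 with both bands in dB
        assert out["NDI"].values[0, 0] == pytest.approx(-1.0 / 3.0)

    def test_zero_denominator_guarded(self):
        out = sar_indices(*self.grids(5, -5))
        assert np.isnan(out["NDI"].values).all()
        assert np.isnan(out["NL"].values).all()
        assert np.isfinite(out["DIF"].values).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sar_indices(RasterGrid(np.zeros((2, 2))), RasterGrid(np.zeros((3, 3))))


class TestVegetationIndices:
    def bands(self, **overrides):
        out = {b: np.full((2, 2), 0.3) for b in OPTICAL_BANDS}
        for k, v in overrides.items():
            out[k] = np.full((2, 2), float(v))
        return out

    def test_equal_nir_red(self):
        vi = vegetation_indices(self.bands(B8=0.25, B4=0.25))
        assert vi["NDVI"][0, 0] == 0
        assert vi["SRI"][0, 0] == pytest.approx(1.0)
        assert vi["MSR"][0, 0] == pytest.approx(0.0)

    def test_gndvi_gcvi_example(self):
        vi = vegetation_indices(self.bands(B8=0.4, B3=0.2))
        assert vi["GNDVI"][0, 0] == pytest.approx(1.0 / 3.0)
        assert vi["GCVI"][0, 0] == pytest.approx(1.0)

    def test_swir_indices_example(self):
        vi = vegetation_indices(self.bands(B11=0.3, B12=0.15))
        assert vi["STI"][0, 0] == pytest.approx(2.0)
        assert vi["NDTI"][0, 0] == pytest.approx(1.0 / 3.0)

    def test_ndmi_ndns1_identical_twins(self):
        vi = vegetation_indices(self.bands(B8=0.5, B11=0.2))
        np.testing.assert_array_equal(vi["NDMI"], vi["NDNS1"])

    def test_missing_band_rejected(self):
        b = self.bands()
        del b["B12"]
        with pytest.raises(ValueError, match="B12"):
            vegetation_indices(b)

    def test_count_is_24(self):
        assert len(vegetation_indices(self.bands())) == 24

    def test_normalized_difference_indices_bounded(self, rng):
        b = {k: rng.uniform(0.01, 1.0, size=(16, 16)) for k in OPTICAL_BANDS}
        vi = vegetation_indices(b)
        for name in ("NDVI", "GNDVI", "NDTI", "NDMI", "NDRE", "MODCRC",
                     "MNDWI", "NDNS1", "NDNS2", "VIgreen"):
            assert np.nanmax(np.abs(vi[name])) <= 1.0 + 1e-12, name


class TestRegistry:
    def test_58_features_24_sar_34_optical(self):
        assert len(FEATURE_REGISTRY) == 58
        assert len(SAR_FEATURES) == 24
        assert len(OPTICAL_FEATURES) == 34
        assert len(set(FEATURE_REGISTRY)) == 58

    def test_aliases_map_to_registry(self):
        for alias in ("GCTV", "MNDW", "RT1", "VV-Home"):
            assert canonical_name(alias) in FEATURE_REGISTRY


class TestBuildStack:
    def small_inputs(self, rng):
        vv = RasterGrid(10 * np.log10(rng.gamma(4, 0.25, (16, 16)) * 10 ** -0.9))
        vh = RasterGrid(10 * np.log10(rng.gamma(4, 0.25, (16, 16)) * 10 ** -1.4))
        optical = {b: RasterGrid(rng.uniform(100, 5000, (16, 16)))
                   for b in OPTICAL_BANDS}
        return vv, vh, optical

    def test_registry_complete_58_bands(self, rng):
        stack = build_stack(*self.small_inputs(rng))
        assert len(stack) == 58
        assert stack.names == list(FEATURE_REGISTRY)

    def test_missing_band_rejected(self, rng):
        vv, vh, optical = self.small_inputs(rng)
        del optical["B12"]
        with pytest.raises(ValueError, match="B12"):
            build_stack(vv, vh, optical)

    def test_idempotent(self, rng):
        args = self.small_inputs(rng)
        a = build_stack(*args)
        b = build_stack(*args)
        for n in a.names:
            np.testing.assert_array_equal(a[n].values, b[n].values)

    def test_20m_bands_resampled_nearest(self, rng):
        vv, vh, optical = self.small_inputs(rng)
        coarse = RasterGrid(rng.uniform(100, 5000, (8, 8)))
        optical["B11"] = coarse
        stack = build_stack(vv, vh, optical)
        np.testing.assert_array_equal(stack["B11"].values[:2, :2],
                                      np.full((2, 2), coarse.values[0, 0]))
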