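"""SAR calibration, despeckling, NDBI and texture layers."""

import math
from collections import Counter

import numpy as np
import pytest

from tdfagb.grids import Grid
from tdfagb.sar import (
    TEXTURE_MEASURES,
    TextureConfig,
    build_sar_stack,
    compute_glcm_textures,
    compute_ndbi,
    dn_to_gamma0,
    extract_plot_features,
    gamma0_to_dn,
    lee_filter,
    quantize,
)

_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_measures_bruteforce(q: np.ndarray) -> dict:
    """Exhaustive pair enumeration over one window, averaged over the four
    directions: the independent oracle for the windowed GLCM kernel."""
    per_dir = []
    h, w = q.shape
    for dr, dc in _DIRECTIONS:
        pairs = []
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < h and 0 <= j2 < w:
                    pairs.append((q[i, j], q[i2, j2]))
                    pairs.append((q[i2, j2], q[i, j]))  # symmetric
        if not pairs:
            continue
        total = len(pairs)
        p = {k: c / total for k, c in Counter(pairs).items()}
        hom = sum(v / (1 + (a - b) ** 2) for (a, b), v in p.items())
        cont = sum(v * (a - b) ** 2 for (a, b), v in p.items())
        dis = sum(v * abs(a - b) for (a, b), v in p.items())
        ent = -sum(v * math.log(v) for v in p.values())
        asm = sum(v**2 for v in p.values())
        mu = sum(v * a for (a, b), v in p.items())
        var = sum(v * (a - mu) ** 2 for (a, b), v in p.items())
        cov = sum(v * (a - mu) * (b - mu) for (a, b), v in p.items())
        cor = cov / var if var > 0 else 0.0
        per_dir.append((hom, cont, dis, ent, asm, mu, var, cor))
    return dict(zip(TEXTURE_MEASURES, np.mean(per_dir, axis=0)))


class TestCalibration:
    def test_dn_one_is_floor(self):
        assert dn_to_gamma0(np.array([[1.0]]))[0, 0] == -83.0

    def test_dn_zero_is_nodata(self):
        assert np.isnan(dn_to_gamma0(np.array([[0.0]]))[0, 0])

    def test_hand_evaluated_dn(self):
        got = dn_to_gamma0(np.array([[5000.0]]))[0, 0]
        assert got == pytest.approx(10 * math.log10(25e6) - 83.0, rel=1e-9)
        assert got == pytest.approx(-9.021, abs=5e-4)

    def test_negative_dn_rejected(self):
        with pytest.raises(ValueError):
            dn_to_gamma0(np.array([[-2.0]]))

    def test_roundtrip(self, rng):
        g = rng.uniform(-25, -5, (12, 12))
        assert np.allclose(dn_to_gamma0(gamma0_to_dn(g)), g, atol=1e-10)


class TestLeeFilter:
    def test_constant_raster_unchanged(self):
        img = np.full((9, 9), -12.0)
        assert np.allclose(lee_filter(img, noise_sd=1.0), img)

    def test_vanishing_noise_is_identity(self, rng):
        img = rng.uniform(-20, -5, (15, 15))
        assert np.allclose(lee_filter(img, noise_sd=1e-9), img, atol=1e-6)

    def test_large_noise_pulls_center_to_window_mean(self):
        img = np.full((5, 5), -10.0)
        img[2, 2] = -1.0
        out = lee_filter(img, noise_sd=100.0)
        expected = (8 * -10.0 + -1.0) / 9.0  # mean of the central 3x3 window
        assert out[2, 2] == pytest.approx(expected)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            lee_filter(np.zeros((5, 5)), noise_sd=0.0)


class TestNDBI:
    def test_equal_bands_zero(self):
        assert compute_ndbi(np.full((3, 3), -10.0), np.full((3, 3), -10.0)).max() == 0.0

    def test_linear_arithmetic(self):
        hh = 10 * np.log10(np.full((2, 2), 0.2))
        hv = 10 * np.log10(np.full((2, 2), 0.1))
        assert compute_ndbi(hh, hv)[0, 0] == pytest.approx(0.1 / 0.3)

    def test_bounded(self, rng):
        hh = rng.uniform(-25, -5, (20, 20))
        hv = rng.uniform(-25, -5, (20, 20))
        nd = compute_ndbi(hh, hv)
        assert np.all(nd >= -1.0) and np.all(nd <= 1.0)

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            compute_ndbi(np.zeros((3, 3)), np.zeros((4, 4)))


class TestGLCM:
    def test_matches_bruteforce_on_random_patches(self, rng):
        """Interior pixels of the windowed kernel agree with exhaustive pair
        enumeration to 1e-10 on random 5x5 integer patches."""
        cfg = TextureConfig(window=5, gray_levels=8)
        for _ in range(12):
            patch = rng.integers(0, 8, (5, 5)).astype(float)
            patch.flat[rng.integers(25)] = 0.0
            patch.flat[rng.integers(25)] = 7.0  # pin quantization endpoints
            tex = compute_glcm_textures(patch, cfg)
            q = quantize(patch, 8)
            oracle = glcm_measures_bruteforce(q)
            for m in TEXTURE_MEASURES:
                assert tex[m][2, 2] == pytest.approx(oracle[m], abs=1e-10), m

    def test_matches_skimage_whole_window(self, rng):
        """Independent library check on a full-window co-occurrence matrix."""
        skimage = pytest.importorskip("skimage.feature")
        patch = rng.integers(0, 8, (5, 5))
        patch.flat[0], patch.flat[1] = 0, 7
        glcm = skimage.graycomatrix(
            patch.astype(np.uint8), [1],
            [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8, symmetric=True, normed=True,
        )
        tex = compute_glcm_textures(patch.astype(float), TextureConfig(window=5, gray_levels=8))
        for ours, theirs in [("cont", "contrast"), ("dis", "dissimilarity"),
                             ("hom", "homogeneity"), ("asm", "ASM")]:
            expected = skimage.graycoprops(glcm, theirs)[0].mean()
            assert tex[ours][2, 2] == pytest.approx(expected, abs=1e-10)

    def test_constant_window_values(self):
        tex = compute_glcm_textures(np.full((7, 7), 3.0), TextureConfig(window=3, gray_levels=8))
        assert np.allclose(tex["cont"], 0) and np.allclose(tex["dis"], 0)
        assert np.allclose(tex["ent"], 0) and np.allclose(tex["var"], 0)
        assert np.allclose(tex["asm"], 1) and np.allclose(tex["hom"], 1)
        assert np.allclose(tex["cor"], 0)  # defined degenerate value

    def test_checkerboard_contrast(self):
        """On a 0/1 checkerboard every horizontal and vertical pair differs by
        one level (contrast 1) while diagonal pairs match (contrast 0), so
        the four-direction average is 0.5."""
        board = (np.indices((5, 5)).sum(axis=0) % 2).astype(float)
        tex = compute_glcm_textures(board, TextureConfig(window=5, gray_levels=2))
        assert tex["cont"][2, 2] == pytest.approx((1.0 + 0.0 + 1.0 + 0.0) / 4)
        assert tex["dis"][2, 2] == pytest.approx(0.5)

    def test_probability_bounds(self, rng):
        tex = compute_glcm_textures(rng.uniform(0, 1, (9, 9)), TextureConfig(window=3))
        assert np.all(tex["asm"] > 0) and np.all(tex["asm"] <= 1)
        assert np.all(tex["ent"] >= 0)

    def test_window_larger_than_raster(self):
        with pytest.raises(ValueError):
            compute_glcm_textures(np.zeros((2, 2)), TextureConfig(window=3))


class TestStackAndExtraction:
    def test_24_texture_layers(self, rng):
        dn = gamma0_to_dn(rng.uniform(-20, -5, (12, 12)))
        stack = build_sar_stack(dn, dn * 0.5, Grid(12, 12))
        assert len(stack.textures) == 24
        names = {f"{b}_{m}" for b in ("HH", "HV", "NDBI") for m in TEXTURE_MEASURES}
        assert set(stack.textures) == names
        assert len(stack.layers()) == 27

    def test_constant_layers_give_constant_features(self):
        grid = Grid(10, 10)
        layers = {"A": np.full((10, 10), 3.5)}
        units = __import__("pandas").DataFrame(
            [{"unit_id": "u", "x": 125.0, "y": 125.0}]
        )
        out = extract_plot_features(layers, grid, units)
        assert out.loc[0, "A"] == 3.5
        assert out.loc[0, "footprint_coverage"] == 1.0

    def test_outside_unit_dropped_and_edge_partial(self):
        grid = Grid(10, 10)
        layers = {"A": np.arange(100.0).reshape(10, 10)}
        units = __import__("pandas").DataFrame(
            [
                {"unit_id": "out", "x": -50.0, "y": 125.0},
                {"unit_id": "edge", "x": 5.0, "y": 125.0},
            ]
        )
        out = extract_plot_features(layers, grid, units)
        assert list(out["unit_id"]) == ["edge"]
        assert out.loc[0, "footprint_coverage"] < 1.0

    def test_single_pixel_footprint(self):
        grid = Grid(6, 6)
        layers = {"A": np.arange(36.0).reshape(6, 6)}
        units = __import__("pandas").DataFrame([{"unit_id": "u", "x": 62.5, "y": 62.5}])
        out = extract_plot_features(layers, grid, units, radius_m=1.0)
        r, c = grid.rowcol(62.5, 62.5)
        assert out.loc[0, "A"] == layers["A"][r, c]
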