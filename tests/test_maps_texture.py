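"""Quantization, GLCM construction, texture features and map orchestration."""

import warnings

import numpy as np
import pytest

from qusradiomics.maps_texture import (
    FEATURE_NAMES,
    MAP_NAMES,
    ExtractionConfig,
    ParametricMap,
    aggregate_subject_features,
    build_parametric_maps,
    compute_glcm,
    glcm_features,
    quantize_map,
)
from qusradiomics.rf_core import EmptyROIError, ROIMask
from qusradiomics.synthetic import ScattererFieldConfig, simulate_rf_frame


def brute_force_features(p):
    """Direct double-loop evaluation of the four texture definitions."""
    n = p.shape[0]
    con = cor_num = ene = hom = 0.0
    mu_x = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * p[i, j] for i in range(n) for j in range(n))
    sig_x = np.sqrt(sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n)))
    sig_y = np.sqrt(sum((j - mu_y) ** 2 * p[i, j] for i in range(n) for j in range(n)))
    for i in range(n):
        for j in range(n):
            con += (i - j) ** 2 * p[i, j]
            cor_num += i * j * p[i, j]
            ene += p[i, j] ** 2
            hom += p[i, j] / (1 + (i - j) ** 2)
    cor = (cor_num - mu_x * mu_y) / (sig_x * sig_y) if sig_x * sig_y > 0 else np.nan
    return con, cor, ene, hom


class TestQuantize:
    def test_identity_on_already_quantized(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        levels, degenerate = quantize_map(vals)
        assert not degenerate
        np.testing.assert_array_equal(levels, vals)

    def test_linear_ramp_equal_counts(self):
        vals = np.linspace(0, 1, 1600).reshape(40, 40)
        levels, _ = quantize_map(vals)
        counts = np.bincount(levels.ravel().astype(int), minlength=16)
        assert counts.min() >= 99 and counts.max() <= 101  # 100 each up to rounding

    def test_max_maps_to_top_level(self):
        vals = np.array([[0.0, 3.0], [7.0, 10.0]])
        levels, _ = quantize_map(vals)
        assert levels[1, 1] == 15
        assert levels[0, 0] == 0

    def test_constant_map_degenerate(self):
        _, degenerate = quantize_map(np.full((4, 4), 2.0))
        assert degenerate

    def test_nan_preserved(self):
        vals = np.array([[np.nan, 1.0], [2.0, 3.0]])
        levels, _ = quantize_map(vals)
        assert np.isnan(levels[0, 0])
        assert np.isfinite(levels[0, 1])


def test_map_png_preview(tmp_path):
    vals = np.random.default_rng(0).normal(size=(6, 6))
    vals[0, 0] = np.nan
    pmap = ParametricMap(vals, "MBF", "dB", 0.12)
    path = tmp_path / "mbf.png"
    pmap.save_png(path)
    assert path.stat().st_size > 0


class TestGLCM:
    def test_constant_grid_single_cell(self):
        g = compute_glcm(np.full((4, 4), 5.0), 1, 0)
        assert g.p[5, 5] == 1.0
        assert g.p.sum() == pytest.approx(1.0)

    def test_checkerboard_off_diagonal(self):
        grid = np.indices((4, 4)).sum(axis=0) % 2
        g = compute_glcm(grid.astype(float), 1, 0)
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)
        assert g.p[0, 0] == g.p[1, 1] == 0.0

    def test_single_pixel_empty(self):
        assert compute_glcm(np.ones((1, 1)), 1, 0) is None

    def test_nan_pairs_excluded(self):
        grid = np.array([[0.0, np.nan, 1.0]])
        g = compute_glcm(grid, 1, 0)
        assert g is None  # both horizontal pairs touch the NaN

    def test_probabilities_sum_to_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 16, size=(12, 12)).astype(float)
        for d in (1, 2, 3, 4):
            for theta in (0, 45, 90, 135):
                g = compute_glcm(grid, d, theta)
                assert abs(g.p.sum() - 1.0) < 1e-12
                np.testing.assert_allclose(g.p, g.p.T, atol=1e-14)

    def test_matches_skimage_on_full_grids(self):
        """Independent library cross-check (no NaN, symmetric, normalized)."""
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 16, size=(10, 14))
        # skimage measures angles with the row axis pointing down, so its
        # pi/4 is our 135-degree displacement and vice versa
        angle_of = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        # skimage rounds sin/cos offsets, so its d=2 diagonals are (1, 1)
        # displacements rather than (2, 2); compare axial/lateral at d=1,2
        # and diagonals at d=1 only
        for d, theta in [(1, 0), (1, 45), (1, 90), (1, 135), (2, 0), (2, 90)]:
            ours = compute_glcm(grid.astype(float), d, theta)
            ref = skimage_feature.graycomatrix(
                grid.astype(np.uint8), [d], [angle_of[theta]],
                levels=16, symmetric=True, normed=True,
            )[:, :, 0, 0]
            np.testing.assert_allclose(ours.p, ref, atol=1e-12)


class TestTextureFeatures:
    def test_constant_grid_features(self):
        g = compute_glcm(np.full((4, 4), 3.0), 1, 0)
        f = glcm_features(g)
        assert f.con == 0.0
        assert f.ene == 1.0
        assert f.hom == 1.0
        assert np.isnan(f.cor)

    def test_checkerboard_features(self):
        grid = np.indices((4, 4)).sum(axis=0) % 2
        f = glcm_features(compute_glcm(grid.astype(float), 1, 0))
        assert f.con == pytest.approx(1.0)
        assert f.ene == pytest.approx(0.5)
        assert f.hom == pytest.approx(0.5)
        assert f.cor == pytest.approx(-1.0)

    def test_random_glcms_match_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            grid = rng.integers(0, 16, size=(8, 8)).astype(float)
            for d, theta in [(1, 0), (2, 45), (3, 90), (4, 135)]:
                g = compute_glcm(grid, d, theta)
                if g is None:
                    continue
                f = glcm_features(g)
                con, cor, ene, hom = brute_force_features(g.p)
                assert f.con == pytest.approx(con, abs=1e-12)
                assert f.ene == pytest.approx(ene, abs=1e-12)
                assert f.hom == pytest.approx(hom, abs=1e-12)
                assert f.cor == pytest.approx(cor, abs=1e-12)

    def test_energy_homogeneity_bounds(self):
        rng = np.random.default_rng(4)
        grid = rng.integers(0, 16, size=(9, 9)).astype(float)
        f = glcm_features(compute_glcm(grid, 1, 0))
        assert 0 < f.ene < 1
        assert 0 < f.hom < 1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(10, 10))
        f1 = glcm_features(compute_glcm(quantize_map(vals)[0], 1, 45))
        f2 = glcm_features(compute_glcm(quantize_map(3.7 * vals - 11.0)[0], 1, 45))
        assert f1 == f2

    def test_rotation_permutes_directions_average_invariant(self):
        rng = np.random.default_rng(6)
        grid = rng.integers(0, 16, size=(8, 8)).astype(float)
        rotated = np.rot90(grid)

        def feats(g, d, theta):
            return glcm_features(compute_glcm(g, d, theta)).con

        # 90-degree rotation swaps 0<->90 and 45<->135
        assert feats(grid, 1, 0) == pytest.approx(feats(rotated, 1, 90), abs=1e-12)
        assert feats(grid, 1, 90) == pytest.approx(feats(rotated, 1, 0), abs=1e-12)
        assert feats(grid, 1, 45) == pytest.approx(feats(rotated, 1, 135), abs=1e-12)
        mean_orig = np.mean([feats(grid, 1, t) for t in (0, 45, 90, 135)])
        mean_rot = np.mean([feats(rotated, 1, t) for t in (0, 45, 90, 135)])
        assert mean_orig == pytest.approx(mean_rot, abs=1e-12)


class TestAggregate:
    def make_maps(self, rng):
        maps = []
        for name in MAP_NAMES:
            maps.append(ParametricMap(rng.normal(size=(9, 9)), name, "dB", 0.12))
        return maps

    def test_feature_vector_has_40_named_entries(self):
        rng = np.random.default_rng(0)
        fv = aggregate_subject_features(self.make_maps(rng))
        assert list(fv.keys()) == FEATURE_NAMES
        assert len(fv) == 40
        assert all(np.isfinite(v) for v in fv.values())

    def test_identical_glcms_average_to_single(self):
        # a map whose quantized grid is translation invariant in all four
        # directions gives 16 identical GLCMs: stripes of period 2
        vals = np.tile(np.array([0.0, 1.0]), (8, 4))
        maps = []
        rng = np.random.default_rng(1)
        for name in MAP_NAMES:
            maps.append(ParametricMap(vals, name, "dB", 0.12))
        config = ExtractionConfig(distances=(2, 4), directions=(0,))
        fv = aggregate_subject_features(maps, config)
        single = glcm_features(compute_glcm(quantize_map(vals)[0], 2, 0))
        assert fv["MBF-con"] == pytest.approx(single.con)
        assert fv["MBF-ene"] == pytest.approx(single.ene)

    def test_single_finite_pixel_mean_defined_texture_missing(self):
        vals = np.full((5, 5), np.nan)
        vals[2, 2] = 7.5
        maps = [ParametricMap(vals.copy(), n, "dB", 0.12) for n in MAP_NAMES]
        fv = aggregate_subject_features(maps)
        assert fv["SI"] == 7.5
        assert np.isnan(fv["SI-con"])

    def test_seeded_maps_match_independent_loop(self):
        rng = np.random.default_rng(7)
        maps = self.make_maps(rng)
        config = ExtractionConfig()
        fv = aggregate_subject_features(maps, config)
        for pmap in maps:
            # oracle: recompute with explicit loops
            levels, degenerate = quantize_map(pmap, 16)
            assert not degenerate
            feats = []
            for d in (1, 2, 3, 4):
                for theta in (0, 45, 90, 135):
                    g = compute_glcm(levels, d, theta)
                    feats.append(brute_force_features(g.p))
            con = np.mean([f[0] for f in feats])
            assert fv[f"{pmap.name}-con"] == pytest.approx(con, abs=1e-12)


class TestBuildMaps:
    @pytest.fixture(scope="class")
    def one_window_result(self, small_geometry, reference):
        cfg = ScattererFieldConfig(density=20, mean_diameter=40.0, seed=21)
        frame, _ = simulate_rf_frame(cfg, small_geometry)
        mask = np.zeros(frame.samples.shape, bool)
        # exactly one window-center lattice point: centers sit at
        # ax = 104//2 + 52 k and line = 13//2 + 7 k for this geometry
        mask[676, 62] = True
        roi = ROIMask(mask, "tiny")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps = build_parametric_maps(
                frame, roi, reference, ExtractionConfig(overlap_frac=0.5)
            )
        return maps

    def test_single_window_roi_gives_single_pixel_maps(self, one_window_result):
        for pmap in one_window_result:
            if pmap.name == "SAS":
                continue  # legitimately undefined in diffuse speckle
            assert np.isfinite(pmap.values).sum() == 1

    def test_map_lattice_and_units(self, one_window_result):
        by_name = {m.name: m for m in one_window_result}
        assert by_name["SS"].units == "dB/MHz"
        assert by_name["ASD_gau"].pixel_pitch == pytest.approx(1.0)

    def test_empty_roi_rejected(self, small_geometry, reference):
        cfg = ScattererFieldConfig(density=20, seed=3)
        frame, _ = simulate_rf_frame(cfg, small_geometry)
        mask = np.zeros(frame.samples.shape, bool)
        mask[0:2, 0:2] = True  # no window center falls here
        with pytest.raises(EmptyROIError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                build_parametric_maps(
                    frame, ROIMask(mask, "x"), reference, ExtractionConfig(overlap_frac=0.5)
                )

    def test_two_region_frame_asd_separates(self, small_geometry, reference):
        """Halves with different scatterer diameters give different ASD map
        means on the corresponding halves."""
        rng = np.random.default_rng(31)
        geom = small_geometry
        area = geom.axial_mm * geom.lateral_mm
        n = rng.poisson(20 * area)
        z = rng.uniform(0, geom.axial_mm, n)
        x = rng.uniform(0, geom.lateral_mm, n)
        # split laterally so the size contrast cannot alias into the
        # depth-dependent attenuation estimate
        left = x < geom.lateral_mm / 2
        diam = np.where(left, 30.0, 60.0)
        cfg = ScattererFieldConfig(density=20, seed=31)
        frame, _ = simulate_rf_frame(cfg, geom, scatterer_field=(z, x, diam))
        mask = np.zeros(frame.samples.shape, bool)
        mask[150:1250, 20:110] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps = build_parametric_maps(
                frame, ROIMask(mask, "two"), reference, ExtractionConfig(overlap_frac=0.5)
            )
        asd = next(m for m in maps if m.name == "ASD_gau")
        cols = asd.values.shape[1]
        left_mean = np.nanmean(asd.values[:, : cols // 2])
        right_mean = np.nanmean(asd.values[:, cols // 2 :])
        assert right_mean - left_mean > 10.0  # 30 vs 60 um ground truth
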