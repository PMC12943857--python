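import numpy as np
import pandas as pd
import pytest

from agbmap.features import (
    FEATURE_ORDER,
    GlcmConfig,
    assemble_feature_stack,
    extract_features,
    glcm_textures,
    pca,
    resample,
    sar_indices,
    terrain,
    vegetation_indices,
)
from agbmap.grids import GridGeometry, RasterStack


def stack_from(grid, **bands):
    return RasterStack(grid, {k: np.full(grid.shape, v) if np.isscalar(v) else v
                              for k, v in bands.items()})


GRID2 = GridGeometry(2, 2, 10.0)


class TestVegetationIndices:
    @pytest.mark.parametrize("nir,red,blue,expect", [
        # NIR = RED makes the NDVI numerator vanish
        (0.3, 0.3, 0.1, {"NDVI": 0.0, "RVI": 1.0}),
        (0.6, 0.2, 0.1, {"NDVI": 0.5, "RVI": 3.0}),
        (0.4, 0.1, 0.05, {"ARVI": 0.25 / 0.55, "EVI": 2.5 * 0.3 / (0.4 + 0.6 - 0.375 + 1)}),
    ])
    def test_hand_values(self, nir, red, blue, expect):
        stack = stack_from(GRID2, B2=blue, B4=red, B8=nir)
        out = vegetation_indices(stack)
        for name, val in expect.items():
            assert np.allclose(out[name], val)

    def test_bounds_and_missing_band(self):
        rng = np.random.default_rng(0)
        grid = GridGeometry(20, 20, 10.0)
        stack = stack_from(grid, B2=rng.uniform(0.01, 0.2, grid.shape),
                           B4=rng.uniform(0.01, 0.3, grid.shape),
                           B8=rng.uniform(0.05, 0.6, grid.shape))
        out = vegetation_indices(stack)
        assert np.nanmax(np.abs(out["NDVI"])) <= 1.0
        with pytest.raises(KeyError, match="B4"):
            vegetation_indices(stack_from(grid, B2=0.1, B8=0.4))


class TestSarIndices:
    def test_symmetric_case(self):
        out = sar_indices(stack_from(GRID2, HH=0.05, HV=0.05))
        assert np.allclose(out["RFDI"], 0.0)
        assert np.allclose(out["HH/HV"], 1.0)
        assert np.allclose(out["RVI_radar"], np.sqrt(0.5))

    def test_hand_values(self):
        out = sar_indices(stack_from(GRID2, HH=0.06, HV=0.02))
        assert np.allclose(out["HH/HV"], 3.0)
        assert np.allclose(out["RFDI"], 0.5)
        assert np.allclose(out["RVI_radar"], np.sqrt(0.75) * 3.0)

    def test_rfdi_limit_small_hv(self):
        out = sar_indices(stack_from(GRID2, HH=0.06, HV=1e-9))
        assert np.allclose(out["RFDI"], 1.0, atol=1e-6)

    def test_nonpositive_backscatter_becomes_nodata(self):
        hh = np.array([[0.05, -0.01], [0.0, 0.02]])
        out = sar_indices(stack_from(GRID2, HH=hh, HV=0.02))
        assert np.isnan(out["RFDI"][0, 1]) and np.isnan(out["RFDI"][1, 0])
        assert np.isfinite(out["RFDI"][0, 0])


class TestPca:
    def test_identical_bands_single_component(self):
        grid = GridGeometry(10, 10, 1.0)
        band = np.random.default_rng(1).normal(size=grid.shape)
        stack = stack_from(grid, a=band, b=band.copy())
        with pytest.warns(UserWarning):
            out, evr = pca(stack, ("a", "b"), n_components=2)
        assert evr[0] > 0.999
        assert out.names == ["PC1"]

    def test_variance_fractions_sum_to_one(self, small_scenario):
        _, evr = pca(small_scenario.stack, n_components=3)
        assert np.isclose(evr.sum(), 1.0)

    def test_pc1_dominates_when_bands_share_one_latent(self):
        # bands that are monotone responses of one latent AGB signal with
        # modest noise concentrate their variance in the first component
        from agbmap.synthetic import ScenarioConfig, build_scenario

        cfg = ScenarioConfig(n_rows=48, n_cols=48, band_noise_frac=0.03)
        scen = build_scenario(cfg, seed=2)
        _, evr = pca(scen.stack, n_components=3)
        assert evr[0] > 0.8

    def test_sign_convention(self, small_scenario):
        out, _ = pca(small_scenario.stack, n_components=3)
        # deterministic: recomputing flips nothing
        out2, _ = pca(small_scenario.stack, n_components=3)
        assert np.allclose(out["PC1"], out2["PC1"], equal_nan=True)


class TestGlcm:
    def test_constant_image(self):
        band = np.full((9, 9), 4.2)
        out = glcm_textures(band, GlcmConfig(window=3, levels=8))
        assert np.allclose(out["contrast33"], 0)
        assert np.allclose(out["dissimilarity33"], 0)
        assert np.allclose(out["entropy33"], 0)
        assert np.allclose(out["secondmoment33"], 1)
        assert np.allclose(out["homogeneity33"], 1)
        # constant image quantizes to level 0, so the GLCM mean is 0
        assert np.allclose(out["mean33"], 0)

    def test_checkerboard_pair_enumeration(self):
        # 5x5 checkerboard, single horizontal offset, window covering the
        # whole image at the center: all co-occurrence mass on (0,1)/(1,0)
        band = np.indices((5, 5)).sum(axis=0) % 2
        cfg = GlcmConfig(window=5, levels=2, offsets=((0, 1),), symmetric=True)
        out = glcm_textures(band.astype(float), cfg)
        c = out["contrast55"][2, 2]
        d = out["dissimilarity55"][2, 2]
        assert np.isclose(c, 1.0)
        assert np.isclose(d, 1.0)
        assert np.isclose(out["homogeneity55"][2, 2], 0.5)

    def test_value_ranges(self, small_scenario):
        pc1 = small_scenario.stack["B8"]
        out = glcm_textures(pc1, GlcmConfig(window=5, levels=16))
        assert np.nanmin(out["homogeneity55"]) > 0
        assert np.nanmax(out["homogeneity55"]) <= 1
        assert np.nanmin(out["secondmoment55"]) > 0
        assert np.nanmax(out["secondmoment55"]) <= 1
        assert np.nanmin(out["entropy55"]) >= 0

    def test_window_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            glcm_textures(np.zeros((3, 3)), GlcmConfig(window=5))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            GlcmConfig(window=4)
        with pytest.raises(ValueError):
            GlcmConfig(levels=1)
        with pytest.raises(ValueError):
            GlcmConfig(offsets=((0, 0),))


class TestTerrain:
    def test_constant_dem_flat(self):
        grid = GridGeometry(6, 6, 10.0)
        out = terrain(np.full(grid.shape, 300.0), grid)
        assert np.allclose(out["slope"], 0.0)
        assert np.allclose(out["aspect"], -1.0)

    def test_plane_rising_east(self):
        grid = GridGeometry(8, 8, 10.0)
        # +1 m per cell eastward
        dem = np.tile(np.arange(8, dtype=float), (8, 1))
        out = terrain(dem, grid)
        assert np.allclose(out["slope"][2:-2, 2:-2], np.degrees(np.arctan(0.1)), atol=1e-9)
        assert np.allclose(out["aspect"][2:-2, 2:-2], 270.0)

    def test_rotating_plane_rotates_aspect(self):
        grid = GridGeometry(8, 8, 10.0)
        east = np.tile(np.arange(8, dtype=float), (8, 1))
        south = east.T  # rising southward
        a_east = terrain(east, grid)["aspect"][3, 3]
        a_south = terrain(south, grid)["aspect"][3, 3]
        assert np.isclose((a_east - a_south) % 360.0, 270.0 - 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            terrain(np.zeros((1, 5)), GridGeometry(1, 5, 10.0))


class TestResample:
    def test_identity_on_same_grid(self):
        grid = GridGeometry(12, 12, 10.0)
        band = np.random.default_rng(2).normal(size=grid.shape)
        for method in ("nearest", "bilinear"):
            out = resample(band, grid, grid, method)
            assert np.allclose(out, band)

    def test_constant_band_any_resolution(self):
        src = GridGeometry(10, 10, 25.0)
        dst = GridGeometry(25, 25, 10.0)
        out = resample(np.full(src.shape, 7.0), src, dst, "bilinear")
        assert np.allclose(out, 7.0)

    def test_bilinear_exact_on_linear_ramp(self):
        src = GridGeometry(20, 20, 25.0)
        xs, ys = src.all_centers()
        ramp = 0.01 * xs + 0.02 * ys
        dst = GridGeometry(30, 30, 10.0, origin_x=50.0, origin_y=-50.0)
        out = resample(ramp, src, dst, "bilinear")
        xt, yt = dst.all_centers()
        inside = (xt > 37.5) & (xt < 462.5) & (yt < -62.5) & (yt > -437.5)
        assert np.allclose(out[inside], (0.01 * xt + 0.02 * yt)[inside], atol=1e-9)

    def test_disjoint_extents_rejected(self):
        src = GridGeometry(5, 5, 10.0)
        dst = GridGeometry(5, 5, 10.0, origin_x=1e6, origin_y=1e6)
        with pytest.raises(ValueError):
            resample(np.zeros(src.shape), src, dst)


class TestExtractFeatures:
    def test_plot_at_cell_center_reads_that_cell(self):
        grid = GridGeometry(4, 4, 10.0)
        band = np.arange(16, dtype=float).reshape(4, 4)
        stack = RasterStack(grid, {"v": band})
        plots = pd.DataFrame({"plot_id": [1], "x": [25.0], "y": [-15.0], "agb_t_ha": [99.0]})
        table = extract_features(stack, plots)
        assert table.loc[1, "v"] == band[1, 2]
        assert table.loc[1, "agb"] == 99.0

    def test_plots_outside_or_on_nodata_dropped(self):
        grid = GridGeometry(4, 4, 10.0)
        band = np.ones(grid.shape)
        band[0, 0] = np.nan
        stack = RasterStack(grid, {"v": band})
        plots = pd.DataFrame({
            "plot_id": [1, 2, 3],
            "x": [5.0, 5.0, 500.0],
            "y": [-5.0, -35.0, -5.0],
            "agb_t_ha": [10.0, 20.0, 30.0],
        })
        table = extract_features(stack, plots)
        assert list(table.index) == [2]

    def test_all_plots_dropped_rejected(self):
        grid = GridGeometry(2, 2, 10.0)
        stack = RasterStack(grid, {"v": np.full(grid.shape, np.nan)})
        plots = pd.DataFrame({"plot_id": [1], "x": [5.0], "y": [-5.0], "agb_t_ha": [1.0]})
        with pytest.raises(ValueError):
            extract_features(stack, plots)


class TestFeatureUniverse:
    def test_exactly_fifty_variables(self, small_scenario, small_feature_table):
        assert len(FEATURE_ORDER) == 50
        feature_cols = [c for c in small_feature_table.columns if c != "agb"]
        assert sorted(feature_cols) == sorted(FEATURE_ORDER)
        assert len(small_feature_table) == len(small_scenario.plots)

    def test_derived_bands_ignore_unrelated_band_shift(self, small_scenario):
        stack = small_scenario.stack.copy()
        out1 = vegetation_indices(stack)
        shifted = stack.copy()
        shifted.bands["B11"] = shifted.bands["B11"] + 0.05  # unused by the VIs
        out2 = vegetation_indices(shifted)
        for name in out1.names:
            assert np.allclose(out1[name], out2[name], equal_nan=True)
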