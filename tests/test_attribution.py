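import numpy as np
import pytest

from deforheat.attribution import (
    RADIUS_FALLBACK,
    RADIUS_NONE,
    RADIUS_PRIMARY,
    MatchParams,
    attribute,
    find_controls,
    normalize_per_point,
    raw_attribution,
    reconstruct,
    regional_mean_per_point,
    smooth_per_point,
)
from deforheat.forest_change import CoverChange, PixelClass, cover_change, extent_gain_mask
from deforheat.raster import Raster, RasterError, cell_area_weights
from deforheat.surface_change import DeltaT
from deforheat.synthetic import TrendSpec, generate_world
from tests import _oracle
from tests.conftest import class_map, make_grid, small_params


def scene(n=40, res=36.0):
    """Blank scene: everything NON_FOREST, constant ΔT and elevation."""
    g = make_grid(n, n, res_arcsec=res)
    codes = np.full(g.shape, int(PixelClass.NON_FOREST), dtype=np.int16)
    dt = np.full(g.shape, 0.5)
    elev = np.full(g.shape, 100.0)
    return g, codes, dt, elev


def world_inputs(world):
    change = cover_change(world.cover2001, world.cover2020)
    gain = extent_gain_mask(world.extent2000, world.extent2020)
    from deforheat.forest_change import classify_pixels

    classes = classify_pixels(world.cover2001, change, gain)
    return world.dt_total, classes, world.elevation, change


class TestFindControls:
    def test_elevation_band_screens(self):
        g, codes, dt, elev = scene()
        codes[20, 20] = PixelClass.DEFORESTED
        for (i, j), de in [((20, 22), 10.0), ((22, 20), -60.0), ((18, 18), 49.0)]:
            codes[i, j] = PixelClass.NON_DEFORESTED
            elev[i, j] = elev[20, 20] + de
        controls, code = find_controls(
            (20, 20), class_map(g, codes), Raster(g, elev), DeltaT(Raster(g, dt))
        )
        assert code == RADIUS_PRIMARY
        assert sorted(controls) == [(18, 18), (20, 22)]

    def test_fallback_radius(self):
        g, codes, dt, elev = scene(80)
        codes[10, 10] = PixelClass.DEFORESTED
        codes[10, 50] = PixelClass.NON_DEFORESTED  # ~0.40 deg away
        codes[12, 52] = PixelClass.NON_DEFORESTED
        controls, code = find_controls(
            (10, 10), class_map(g, codes), Raster(g, elev), DeltaT(Raster(g, dt))
        )
        assert code == RADIUS_FALLBACK
        assert len(controls) == 2

    def test_no_controls_anywhere(self):
        g, codes, dt, elev = scene()
        codes[5, 5] = PixelClass.DEFORESTED
        controls, code = find_controls(
            (5, 5), class_map(g, codes), Raster(g, elev), DeltaT(Raster(g, dt))
        )
        assert controls == [] and code == RADIUS_NONE

    def test_center_must_be_deforested(self):
        g, codes, dt, elev = scene()
        with pytest.raises(RasterError, match="not classified deforested"):
            find_controls((3, 3), class_map(g, codes), Raster(g, elev), DeltaT(Raster(g, dt)))

    def test_masked_dt_control_skipped(self):
        g, codes, dt, elev = scene()
        codes[20, 20] = PixelClass.DEFORESTED
        codes[20, 22] = PixelClass.NON_DEFORESTED
        mask = np.zeros(g.shape, dtype=bool)
        mask[20, 22] = True
        controls, code = find_controls(
            (20, 20), class_map(g, codes), Raster(g, elev), DeltaT(Raster(g, dt, mask))
        )
        assert code == RADIUS_NONE


class TestRawAttribution:
    def test_hand_example(self):
        g, codes, dt, elev = scene()
        codes[20, 20] = PixelClass.DEFORESTED
        dt[20, 20] = 1.2
        for (i, j), v in [((20, 22), 0.2), ((22, 20), 0.3), ((18, 18), 0.1)]:
            codes[i, j] = PixelClass.NON_DEFORESTED
            dt[i, j] = v
        res = raw_attribution(DeltaT(Raster(g, dt)), class_map(g, codes), Raster(g, elev))
        assert res.dt_defor_raw.values[20, 20] == pytest.approx(1.0, abs=1e-14)
        assert res.n_controls[20, 20] == 3

    def test_uniform_trend_cancels(self):
        world = generate_world(small_params(2, beta=0.0))
        dt, classes, elev, change = world_inputs(world)
        res = raw_attribution(dt, classes, elev)
        vals = res.dt_defor_raw.values[res.dt_defor_raw.valid]
        assert vals.size > 50
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_beta_world_recovers_signal(self, small_world):
        dt, classes, elev, change = world_inputs(small_world)
        res = raw_attribution(dt, classes, elev)
        ok = res.dt_defor_raw.valid
        expected = small_world.params.beta * change.loss_pct[ok]
        np.testing.assert_allclose(res.dt_defor_raw.values[ok], expected, atol=1e-10)

    def test_unmatched_retained_with_missing_indicator(self):
        g, codes, dt, elev = scene()
        codes[5, 5] = PixelClass.DEFORESTED
        res = raw_attribution(DeltaT(Raster(g, dt)), class_map(g, codes), Raster(g, elev))
        assert res.dt_defor_raw.mask[5, 5]
        assert res.radius_used[5, 5] == RADIUS_NONE
        assert res.center_mask[5, 5]  # still recorded as a center


class TestNormalize:
    def test_division(self):
        g = make_grid(1, 1)
        raw = Raster(g, np.array([[1.0]]))
        out = normalize_per_point(raw, CoverChange(Raster(g, np.array([[-20.0]]))))
        assert out.values[0, 0] == pytest.approx(0.05)

    def test_negative_raw_legal(self):
        g = make_grid(1, 1)
        out = normalize_per_point(
            Raster(g, np.array([[-0.3]])), CoverChange(Raster(g, np.array([[-10.0]])))
        )
        assert out.values[0, 0] == pytest.approx(-0.03)

    def test_small_loss_amplifies(self):
        g = make_grid(1, 1)
        out = normalize_per_point(
            Raster(g, np.array([[0.9]])), CoverChange(Raster(g, np.array([[-2.0]])))
        )
        assert out.values[0, 0] == pytest.approx(0.45)

    def test_zero_loss_asserts(self):
        g = make_grid(1, 1)
        with pytest.raises(AssertionError):
            normalize_per_point(
                Raster(g, np.array([[1.0]])), CoverChange(Raster(g, np.array([[0.0]])))
            )


def smoothing_scene(values, losses=None):
    """Deforested block holding `values` (row-major) within one 0.1° circle."""
    values = np.asarray(values, dtype=float)
    n = values.size
    rows = int(np.ceil(n / 5))
    g = make_grid(20, 20)
    codes = np.full(g.shape, int(PixelClass.NON_FOREST), dtype=np.int16)
    per_point = np.full(g.shape, np.nan)
    loss = np.zeros(g.shape)
    k = 0
    for i in range(rows):
        for j in range(5):
            if k >= n:
                break
            codes[8 + i, 8 + j] = PixelClass.DEFORESTED
            per_point[8 + i, 8 + j] = values[k]
            loss[8 + i, 8 + j] = 10.0 if losses is None else losses[k]
            k += 1
    mask = ~np.isfinite(per_point)
    return (
        Raster(g, per_point, mask),
        CoverChange(Raster(g, -loss)),
        class_map(g, codes),
    )


class TestSmoothing:
    def test_constant_set_fixed_point(self):
        pp, change, classes = smoothing_scene([0.05, 0.05, 0.05])
        out, fb, nn = smooth_per_point(pp, change, classes)
        vals = out.values[classes.is_class(PixelClass.DEFORESTED)]
        np.testing.assert_allclose(vals, 0.05, rtol=1e-14)
        assert not fb.any()
        assert nn[classes.is_class(PixelClass.DEFORESTED)].min() == 3

    def test_z_score_outlier_dropped(self):
        # 19 zeros and one 100: the outlier's z = 95/21.79 > 3, so it is
        # dropped and every smoothed value is 0
        vals = [0.0] * 19 + [100.0]
        pp, change, classes = smoothing_scene(vals)
        out, _, _ = smooth_per_point(pp, change, classes)
        sel = classes.is_class(PixelClass.DEFORESTED)
        np.testing.assert_allclose(out.values[sel], 0.0, atol=1e-14)

    def test_low_loss_excluded_from_window(self):
        # the 100-valued pixel has loss 3 (<5): excluded by the loss rule
        pp, change, classes = smoothing_scene([0.1, 0.1, 100.0], losses=[10.0, 10.0, 3.0])
        out, _, _ = smooth_per_point(pp, change, classes)
        sel = classes.is_class(PixelClass.DEFORESTED)
        np.testing.assert_allclose(out.values[sel], 0.1, rtol=1e-12)

    def test_regional_fallback(self):
        pp, change, classes = smoothing_scene([0.7], losses=[3.0])  # below min loss
        out, fb, _ = smooth_per_point(pp, change, classes, regional_mean=0.033)
        sel = classes.is_class(PixelClass.DEFORESTED)
        assert out.values[sel][0] == pytest.approx(0.033)
        assert fb[sel].all()

    def test_missing_regional_mean_fails(self):
        pp, change, classes = smoothing_scene([0.7], losses=[3.0])
        with pytest.raises(RasterError, match="regional mean"):
            smooth_per_point(pp, change, classes, regional_mean=None)

    def test_exclude_center_option(self):
        pp, change, classes = smoothing_scene([1.0, 3.0])
        params = MatchParams(include_center_in_smoothing=False)
        out, _, _ = smooth_per_point(pp, change, classes, params)
        sel = np.nonzero(classes.is_class(PixelClass.DEFORESTED))
        assert out.values[sel[0][0], sel[1][0]] == pytest.approx(3.0)
        assert out.values[sel[0][1], sel[1][1]] == pytest.approx(1.0)


class TestRegionalMean:
    def test_equal_area_pair(self):
        pp, change, classes = smoothing_scene([0.02, 0.04])
        out = regional_mean_per_point(pp, change, classes)
        assert out[0] == pytest.approx(0.03)

    def test_single_pixel_region(self):
        pp, change, classes = smoothing_scene([0.07])
        assert regional_mean_per_point(pp, change, classes)[0] == pytest.approx(0.07)

    def test_beta_world_recovers_beta(self, small_world):
        dt, classes, elev, change = world_inputs(small_world)
        res = raw_attribution(dt, classes, elev)
        pp = normalize_per_point(res.dt_defor_raw, change)
        means = regional_mean_per_point(pp, change, classes, small_world.regions)
        for v in means.values():
            assert v == pytest.approx(small_world.params.beta, abs=1e-10)

    def test_empty_region_fails(self):
        pp, change, classes = smoothing_scene([0.7], losses=[3.0])
        with pytest.raises(RasterError, match="qualifying"):
            regional_mean_per_point(pp, change, classes)


class TestReconstruct:
    def test_inverse_of_normalization(self):
        g = make_grid(1, 1)
        out = reconstruct(
            Raster(g, np.array([[0.05]])), CoverChange(Raster(g, np.array([[-20.0]])))
        )
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_full_chain_on_beta_world(self, small_world):
        dt, classes, elev, change = world_inputs(small_world)
        res = attribute(dt, classes, elev, change, regions=small_world.regions)
        ok = res.dt_defor.valid
        expected = small_world.params.beta * change.loss_pct[ok]
        np.testing.assert_allclose(res.dt_defor.values[ok], expected, atol=1e-10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("world_seed,noise", [(0, 0.0), (7, 0.2)])
    def test_matches_brute_force(self, world_seed, noise):
        world = generate_world(small_params(world_seed, noise_sigma=noise))
        dt, classes, elev, change = world_inputs(world)
        params = MatchParams()
        res = attribute(dt, classes, elev, change, regions=world.regions)

        g = dt.raster.grid
        raw_b, raw_mask_b, code_b, ncon_b = _oracle.brute_raw_attribution(
            dt.raster.values, dt.raster.mask,
            classes.raster.values, elev.values, elev.mask,
            g.lat_centers, g.lon_centers,
            params.primary_radius, params.fallback_radius, params.elevation_band,
        )
        np.testing.assert_array_equal(res.dt_defor_raw.mask, raw_mask_b)
        both = ~raw_mask_b
        # raw stage: bit-for-bit
        assert np.array_equal(res.dt_defor_raw.values[both], raw_b[both])
        np.testing.assert_array_equal(res.radius_used, code_b)
        np.testing.assert_array_equal(res.n_controls, ncon_b)

        with np.errstate(invalid="ignore", divide="ignore"):
            pp_b = raw_b / np.where(both, change.loss_pct, 1.0)
        smooth_b, fb_b = _oracle.brute_smooth(
            pp_b, ~np.isfinite(pp_b), classes.raster.values, change.loss_pct,
            g.lat_centers, g.lon_centers,
            params.smooth_radius, params.min_loss_for_smoothing, params.z_threshold,
        )
        sel = res.dt_per_point_smoothed.valid & np.isfinite(smooth_b)
        np.testing.assert_array_equal(res.dt_per_point_smoothed.valid, np.isfinite(smooth_b))
        np.testing.assert_allclose(
            res.dt_per_point_smoothed.values[sel], smooth_b[sel], atol=1e-12, rtol=0
        )
        np.testing.assert_array_equal(res.regional_fallback_used, fb_b)


class TestInvariants:
    def test_translation_invariance_exact(self):
        # dyadic construction: every intermediate is exactly representable,
        # so adding a constant to all dT changes nothing, bit for bit
        g = make_grid(30, 30)
        codes = np.full(g.shape, int(PixelClass.NON_DEFORESTED), dtype=np.int16)
        loss = np.zeros(g.shape)
        beta = 1.0 / 64.0
        for (i, j), l in [((10, 10), 16.0), ((10, 11), 8.0), ((11, 10), 16.0)]:
            codes[i, j] = PixelClass.DEFORESTED
            loss[i, j] = l
        dt_vals = 0.25 + beta * loss
        elev = Raster(g, np.full(g.shape, 128.0))
        classes = class_map(g, codes)
        change = CoverChange(Raster(g, -loss))

        res0 = attribute(DeltaT(Raster(g, dt_vals.copy())), classes, elev, change)
        res1 = attribute(DeltaT(Raster(g, dt_vals + 2.0)), classes, elev, change)
        assert np.array_equal(
            res0.dt_defor.values[res0.dt_defor.valid],
            res1.dt_defor.values[res1.dt_defor.valid],
        )
        np.testing.assert_array_equal(res0.dt_defor.mask, res1.dt_defor.mask)

    def test_translation_invariance_noisy_world(self, noisy_world):
        dt, classes, elev, change = world_inputs(noisy_world)
        res0 = attribute(dt, classes, elev, change, regions=noisy_world.regions)
        res1 = attribute(dt.shifted(3.7), classes, elev, change, regions=noisy_world.regions)
        ok = res0.dt_defor.valid
        np.testing.assert_allclose(
            res0.dt_defor.values[ok], res1.dt_defor.values[ok], atol=1e-9
        )

    def test_final_masked_exactly_where_unmatched(self, small_world):
        dt, classes, elev, change = world_inputs(small_world)
        res = attribute(dt, classes, elev, change, regions=small_world.regions)
        defor = classes.is_class(PixelClass.DEFORESTED)
        unmatched = defor & (res.radius_used == RADIUS_NONE)
        np.testing.assert_array_equal(res.dt_defor.mask & defor, unmatched)

    def test_elevation_screen_reduces_lapse_error(self):
        params_world = small_params(
            11,
            trend=TrendSpec("elevation_lapse", constant=0.2, lapse=0.004),
            elevation_amplitude=300.0,
        )
        world = generate_world(params_world)
        dt, classes, elev, change = world_inputs(world)
        tight = attribute(dt, classes, elev, change, MatchParams(elevation_band=50.0),
                          regions=world.regions)
        loose = attribute(dt, classes, elev, change, MatchParams(elevation_band=1e9),
                          regions=world.regions)

        def rmse(res):
            both = res.dt_defor.valid & world.truth.true_dt_defor.valid
            d = res.dt_defor.values[both] - world.truth.true_dt_defor.values[both]
            return float(np.sqrt(np.mean(d**2)))

        assert rmse(tight) < rmse(loose)
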