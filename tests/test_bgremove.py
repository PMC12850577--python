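"""Background field removal: annihilation, recovery, erosion behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from qsmhead import bgremove, forward

STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _rms(x):
    return float(np.sqrt(np.mean(np.asarray(x, float) ** 2)))


@pytest.fixture(scope="module")
def deep_source():
    """Compact interior source inside a spherical ROI, plus an outside shell."""
    g = np.ogrid[:64, :64, :64]
    r2 = sum((gi - 31.5) ** 2 for gi in g)
    roi = r2 <= 24**2
    kern = forward.padded_kernel_for((64, 64, 64), (1, 1, 1), (0, 0, 1), 2.0)
    chi_in = ndimage.gaussian_filter((r2 <= 4**2).astype(float), 0.7)
    chi_out = ndimage.gaussian_filter(np.where(r2 >= 28**2, 0.5, 0.0), 0.7)
    local = forward.field_from_chi(chi_in, kern).values
    background = forward.field_from_chi(chi_out, kern).values
    return {"roi": roi, "local": local, "background": background}


class TestSmvFilter:
    def test_constant_field_zeroed(self, deep_source):
        roi = deep_source["roi"]
        out, er = bgremove.smv_filter(np.full(roi.shape, 3.0) * roi, roi, 3)
        assert np.allclose(out.values[er], 0.0, atol=1e-9)

    def test_harmonic_background_annihilated(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        out, er = bgremove.smv_filter(bg, roi, 4)
        assert _rms(out.values[er]) < 0.02 * _rms(bg[er])

    def test_radius1_matches_morphological_erosion(self, deep_source):
        roi = deep_source["roi"]
        _, er = bgremove.smv_filter(np.zeros(roi.shape), roi, 1)
        expect = ndimage.binary_erosion(roi, STRUCT6)
        assert np.array_equal(er, expect)

    def test_linearity(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        out1, _ = bgremove.smv_filter(bg, roi, 3)
        out2, _ = bgremove.smv_filter(2.5 * bg, roi, 3)
        assert np.allclose(out2.values, 2.5 * out1.values, atol=1e-10)

    def test_oversized_radius_rejected(self, deep_source):
        with pytest.raises(ValueError):
            bgremove.smv_filter(deep_source["background"],
                                deep_source["roi"], 30)


class TestResharp:
    def test_background_annihilated(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        res = bgremove.resharp(bg, roi, radius=4, tik_lambda=1e-4)
        m = res.effective_mask
        assert _rms(res.local_field.values[m]) < 0.05 * _rms(bg[m])

    def test_local_recovered(self, deep_source):
        loc, roi = deep_source["local"], deep_source["roi"]
        res = bgremove.resharp(loc, roi, radius=4, tik_lambda=1e-4)
        m = res.effective_mask
        err = _rms(res.local_field.values[m] - loc[m]) / _rms(loc[m])
        assert err < 0.10

    def test_large_lambda_shrinks_to_zero(self, deep_source):
        loc, roi = deep_source["local"], deep_source["roi"]
        res = bgremove.resharp(loc, roi, radius=4, tik_lambda=1e6)
        assert _rms(res.local_field.values) < 1e-4 * _rms(loc[roi])

    def test_invalid_lambda_rejected(self, deep_source):
        with pytest.raises(ValueError):
            bgremove.resharp(deep_source["local"], deep_source["roi"],
                             radius=3, tik_lambda=0.0)


class TestVsharp:
    def test_background_annihilated(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        res = bgremove.vsharp(bg, roi, r_min=1, r_max=10)
        m = res.effective_mask
        assert _rms(res.local_field.values[m]) < 0.05 * _rms(bg[m])

    def test_degenerate_schedule_single_radius(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        res = bgremove.vsharp(bg, roi, r_min=4, r_max=4)
        _, er = bgremove.smv_filter(bg, roi, 4)
        assert np.array_equal(res.effective_mask, er)

    def test_erosion_increases_with_r_min(self, split_fields48):
        roi = split_fields48["roi"]
        total = split_fields48["total"]
        fracs = []
        for r in (1, 2, 3, 4):
            res = bgremove.vsharp(total.values, roi, r_min=r, r_max=8)
            fracs.append(res.erosion_fraction_roi)
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_invalid_radii_rejected(self, deep_source):
        with pytest.raises(ValueError):
            bgremove.vsharp(deep_source["background"], deep_source["roi"],
                            r_min=5, r_max=3)


class TestPdf:
    def test_background_annihilated(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        res = bgremove.pdf(bg, roi, pre_erosion=1)
        m = res.effective_mask
        assert _rms(res.local_field.values[m]) < 0.05 * _rms(bg[m])

    def test_zero_field_zero_local(self, deep_source):
        roi = deep_source["roi"]
        res = bgremove.pdf(np.zeros(roi.shape), roi, pre_erosion=0)
        assert np.allclose(res.local_field.values, 0.0, atol=1e-12)

    def test_interior_source_recovered_up_to_smooth_leak(self, deep_source):
        # the exterior fit can absorb a smooth (2nd-order) harmonic
        # component of the local field; score in its complement, exactly as
        # the pipeline's polynomial correction stage does
        loc, roi = deep_source["local"], deep_source["roi"]
        res = bgremove.pdf(loc, roi, pre_erosion=1)
        m = res.effective_mask
        err = np.where(m, res.local_field.values - loc, 0.0)
        ce = bgremove.residual_field_correction(err, m, order=2)
        assert _rms(ce.values[m]) < 0.10 * _rms(loc[m])


class TestLbv:
    def test_harmonic_input_annihilated(self, deep_source):
        bg, roi = deep_source["background"], deep_source["roi"]
        res = bgremove.lbv(bg, roi, peel=1, depth=3)
        m = res.effective_mask
        assert _rms(res.local_field.values[m]) < 0.05 * _rms(bg[m])

    def test_interior_bump_recovered(self, deep_source):
        loc, bg, roi = (deep_source["local"], deep_source["background"],
                        deep_source["roi"])
        res = bgremove.lbv(bg + loc, roi, peel=1, depth=3)
        m = res.effective_mask
        err = _rms(res.local_field.values[m] - loc[m]) / _rms(loc[m])
        assert err < 0.10

    def test_constant_field_is_harmonic(self, deep_source):
        roi = deep_source["roi"]
        res = bgremove.lbv(np.full(roi.shape, 2.0), roi, peel=1)
        assert np.allclose(res.local_field.values, 0.0, atol=1e-5)


class TestResidualFieldCorrection:
    def _poly2(self, shape):
        g = np.ogrid[tuple(slice(0, s) for s in shape)]
        x, y, z = (2.0 * gi / (s - 1) - 1 for gi, s in zip(g, shape))
        return 1.0 + 0.5 * x - 0.3 * y + 0.2 * z + 0.7 * x * y - 0.4 * z**2

    def test_exact_polynomial_annihilated(self):
        shape = (24, 24, 24)
        f = self._poly2(shape) * np.ones(shape)
        mask = np.ones(shape, bool)
        out = bgremove.residual_field_correction(f, mask, order=2)
        assert np.max(np.abs(out.values)) < 1e-8 * np.max(np.abs(f))

    def test_higher_order_annihilates_lower(self):
        shape = (24, 24, 24)
        f = self._poly2(shape) * np.ones(shape)
        mask = np.ones(shape, bool)
        out = bgremove.residual_field_correction(f, mask, order=4)
        assert np.max(np.abs(out.values)) < 1e-7 * np.max(np.abs(f))

    def test_spherical_harmonics_annihilate_linear(self):
        shape = (20, 20, 20)
        g = np.ogrid[:20, :20, :20]
        f = (0.3 * g[0] - 0.2 * g[2]) * np.ones(shape)
        mask = np.ones(shape, bool)
        out = bgremove.residual_field_correction(f, mask,
                                                 basis="spherical_harmonic",
                                                 order=2)
        assert np.max(np.abs(out.values)) < 1e-7 * np.max(np.abs(f))

    def test_noise_preserved(self):
        shape = (20, 20, 20)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(shape)
        f = self._poly2(shape) + noise
        mask = np.ones(shape, bool)
        out = bgremove.residual_field_correction(f, mask, order=2)
        assert abs(out.values.mean()) < 0.02
        assert np.var(out.values) == pytest.approx(np.var(noise), rel=0.05)

    def test_rank_deficient_design_names_axis(self):
        shape = (16, 16, 16)
        mask = np.zeros(shape, bool)
        mask[:, :, 8] = True  # single slice: z degenerate
        f = np.ones(shape)
        with pytest.raises(ValueError, match="z"):
            bgremove.residual_field_correction(f, mask, order=2)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            bgremove.residual_field_correction(np.ones((8, 8, 8)),
                                               np.ones((8, 8, 8), bool),
                                               order=5)


class TestMaskPreDilation:
    def test_zero_is_identity(self):
        m = np.zeros((8, 8, 8), bool)
        m[4, 4, 4] = True
        assert np.array_equal(bgremove.mask_pre_dilation(m, 0), m)

    def test_single_voxel_6connected(self):
        m = np.zeros((8, 8, 8), bool)
        m[4, 4, 4] = True
        assert bgremove.mask_pre_dilation(m, 1).sum() == 7

    def test_closing_covers_original(self):
        g = np.ogrid[:24, :24, :24]
        m = sum((gi - 11.5) ** 2 for gi in g) <= 8**2
        closed = ndimage.binary_erosion(bgremove.mask_pre_dilation(m, 2),
                                        STRUCT6, iterations=2)
        assert np.all(closed[m])


class TestErosionSweep:
    @pytest.fixture(scope="class")
    def bench(self, split_fields48):
        return split_fields48

    def test_schema_and_finite_metrics(self, bench):
        tab = bgremove.erosion_sweep("vsharp", [1, 2], bench["local"],
                                     bench["total"],
                                     {"roi": bench["roi"], "gtv": bench["gtv"]})
        assert isinstance(tab, pd.DataFrame)
        for col in ("method", "param", "rmse_roi", "rmse_gtv", "mae_roi",
                    "erosion_roi_pct", "erosion_gtv_pct", "rmse_roi_corrected"):
            assert col in tab.columns
        assert np.isfinite(tab["rmse_roi"]).all()

    def test_truth_vs_itself_zero_rmse(self, bench):
        from qsmhead.metrics import error_metrics
        m = bench["roi"]
        em = error_metrics(bench["local"].values, bench["local"].values, m)
        assert em["RMSE"] == 0.0

    def test_gtv_erosion_monotone(self, bench):
        tab = bgremove.erosion_sweep("resharp", [1, 2, 3], bench["local"],
                                     bench["total"],
                                     {"roi": bench["roi"], "gtv": bench["gtv"]})
        er = tab["erosion_gtv_pct"].to_numpy()
        assert np.all(np.diff(er) >= -1e-9)

    def test_correction_never_hurts(self, bench):
        tab = bgremove.erosion_sweep("vsharp", [1, 2], bench["local"],
                                     bench["total"],
                                     {"roi": bench["roi"], "gtv": bench["gtv"]})
        assert np.all(tab["rmse_roi_corrected"].to_numpy()
                      <= tab["rmse_roi"].to_numpy() + 1e-12)

    def test_failed_run_recorded_not_fatal(self, bench):
        tab = bgremove.erosion_sweep("resharp", [50], bench["local"],
                                     bench["total"], {"roi": bench["roi"]})
        assert len(tab) == 1
        assert tab["error"].iloc[0] != ""
        assert np.isnan(tab["rmse_roi"].iloc[0])
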