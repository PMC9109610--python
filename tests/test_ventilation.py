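import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

from ventimap.errors import DataError, ParameterError
from ventimap.imagecore import Mask, Volume
from ventimap.registration import VectorField, jacobian_determinant
from ventimap.ventilation import (
    VentilationImage,
    postprocess,
    ventilation_density_change,
    ventilation_jacobian,
    voi_mean_inhale,
)


def box_mask(shape, margin=1, spacing=(2.0, 2.0, 2.0)):
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, n - margin) for n in shape)
    m[sl] = True
    return Mask(m, spacing)


class TestVentilationJacobian:
    def test_zero_field_zero_ventilation(self):
        mask = box_mask((8, 8, 8))
        dvf = VectorField(np.zeros((3, 8, 8, 8)), (2, 2, 2))
        vi = ventilation_jacobian(dvf, mask)
        assert np.all(vi.values == 0)
        assert vi.provenance == "JAC"

    def test_affine_expansion(self):
        # oracle: 1.1^3 - 1 = 0.331
        shape, spacing = (10, 10, 10), (2.0, 2.0, 2.0)
        coords = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        u = np.stack([0.1 * c for c in coords])
        vi = ventilation_jacobian(VectorField(u, spacing), box_mask(shape))
        m = box_mask(shape).values
        assert np.abs(vi.values[m] - 0.331).max() < 1e-9

    def test_phantom_closed_form(self, clean_subject):
        from ventimap.phantom import expansion_field

        vi = ventilation_jacobian(clean_subject.true_dvf, clean_subject.exhale_mask)
        a = expansion_field(clean_subject.spec)
        m = clean_subject.exhale_mask.values
        assert np.abs(vi.values - a[:, :, None])[m].max() < 1e-6
        rs = spearmanr(vi.values[m], clean_subject.true_ventilation.values[m]).statistic
        assert rs >= 0.999


class TestVoiMeanInhale:
    def test_zero_field_returns_same_voxel(self):
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(-800, 30, (8, 8, 8)), (2, 2, 2))
        dvf = VectorField(np.zeros((3, 8, 8, 8)), (2, 2, 2))
        assert voi_mean_inhale(vol, dvf, (3, 4, 5)) == pytest.approx(
            vol.values[3, 4, 5]
        )

    def test_uniform_expansion_averages_mapped_cell(self):
        # oracle: exhaustive enumeration on a tiny grid.  With u = x (doubling
        # map), the cell of exhale voxel i spans inhale coordinates
        # [2i-1, 2i+1] mm, i.e. inhale-grid voxel centers 2i-1, 2i, 2i+1 on a
        # 1D-varying volume.
        shape, spacing = (8, 8, 8), (1.0, 1.0, 1.0)
        coords = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        u = np.stack([coords[0], np.zeros(shape), np.zeros(shape)])
        x_ramp = Volume(coords[0].copy(), spacing)
        got = voi_mean_inhale(x_ramp, VectorField(u, spacing), (2, 4, 4))
        members = [v for v in range(8) if 3.0 <= v <= 5.0]
        assert got == pytest.approx(np.mean(members))

    def test_contraction_falls_back_to_trilinear(self):
        # u = -0.75 x contracts cells to 0.5 mm on a 2 mm grid: no inhale
        # centers inside the bbox for odd cells -> fallback sample
        shape, spacing = (9, 9, 9), (2.0, 2.0, 2.0)
        coords = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        u = np.stack([-0.75 * coords[0], np.zeros(shape), np.zeros(shape)])
        ramp = Volume(coords[0].copy(), spacing)
        got = voi_mean_inhale(ramp, VectorField(u, spacing), (3, 4, 4))
        assert got == pytest.approx(0.25 * 6.0)  # trilinear sample at x=1.5mm


class TestDensityChange:
    def test_hand_case(self):
        # 1000*(-850 + 800) / (-800 * (1000 - 850)) = 0.41667
        shape, spacing = (6, 6, 6), (2.0, 2.0, 2.0)
        inhale = Volume(np.full(shape, -850.0), spacing)
        exhale = Volume(np.full(shape, -800.0), spacing)
        dvf = VectorField(np.zeros((3,) + shape), spacing)
        vi = ventilation_density_change(inhale, exhale, dvf, box_mask(shape))
        m = box_mask(shape).values
        assert vi.values[m] == pytest.approx(0.41667, abs=1e-4)

    def test_no_density_change_gives_zero(self):
        shape, spacing = (6, 6, 6), (2.0, 2.0, 2.0)
        vol = Volume(np.full(shape, -800.0), spacing)
        dvf = VectorField(np.zeros((3,) + shape), spacing)
        vi = ventilation_density_change(vol, vol, dvf, box_mask(shape))
        assert np.all(vi.values == 0)

    def test_mass_conserving_phantom_consistency(self, notexture_subject):
        # oracle: substituting mass conservation into the density-change
        # formula gives VI_HU = 1000 (J-1) / (-HU_ex) = 1.25 (J-1) at
        # HU_ex = -800
        sub = notexture_subject
        vi = ventilation_density_change(
            sub.series.inhale, sub.series.exhale, sub.true_dvf, sub.exhale_mask
        )
        jac = jacobian_determinant(sub.true_dvf)
        interior = ndimage.binary_erosion(sub.exhale_mask.values, iterations=3)
        expected = 1.25 * (jac.values[interior] - 1.0)
        assert np.abs(vi.values[interior] / expected - 1.0).max() < 0.02

    def test_guarded_voxels_counted_and_limited(self):
        shape, spacing = (6, 6, 6), (2.0, 2.0, 2.0)
        exhale_vals = np.full(shape, -800.0)
        exhale_vals[2, 2, 2] = 0.0  # vessel-like voxel: denominator guard
        inhale = Volume(np.full(shape, -850.0), spacing)
        exhale = Volume(exhale_vals, spacing)
        dvf = VectorField(np.zeros((3,) + shape), spacing)
        vi = ventilation_density_change(inhale, exhale, dvf, box_mask(shape))
        assert vi.info["n_guarded"] == 1
        assert vi.values[2, 2, 2] == 0.0

    def test_too_many_guards_raise(self):
        shape, spacing = (6, 6, 6), (2.0, 2.0, 2.0)
        inhale = Volume(np.full(shape, -850.0), spacing)
        exhale = Volume(np.zeros(shape), spacing)
        dvf = VectorField(np.zeros((3,) + shape), spacing)
        with pytest.raises(DataError):
            ventilation_density_change(inhale, exhale, dvf, box_mask(shape))

    def test_jac_and_hu_identical_after_normalization(self, notexture_subject):
        # with spatially constant exhale HU the two estimators differ by a
        # constant factor, which percentile normalization removes
        sub = notexture_subject
        vi_hu = ventilation_density_change(
            sub.series.inhale, sub.series.exhale, sub.true_dvf, sub.exhale_mask
        )
        vi_jac = ventilation_jacobian(sub.true_dvf, sub.exhale_mask)
        interior = ndimage.binary_erosion(sub.exhale_mask.values, iterations=3)
        interior_mask = Mask(interior, sub.exhale_mask.spacing, sub.exhale_mask.origin)
        pp_hu = postprocess(vi_hu, interior_mask, filter_size=1)
        pp_jac = postprocess(vi_jac, interior_mask, filter_size=1)
        assert np.abs(pp_hu.values - pp_jac.values)[interior].max() < 1e-6


class TestPostprocess:
    def test_constant_becomes_one(self):
        mask = box_mask((8, 8, 8), margin=2)
        vi = VentilationImage(np.where(mask.values, 3.7, 0.0), mask, "JAC")
        out = postprocess(vi, mask, filter_size=1)
        assert np.allclose(out.values[mask.values], 1.0)
        assert out.normalized

    def test_percentile_is_one_after_normalization(self):
        rng = np.random.default_rng(1)
        mask = box_mask((10, 10, 10))
        vi = VentilationImage(
            np.where(mask.values, rng.random((10, 10, 10)), 0.0), mask, "JAC"
        )
        out = postprocess(vi, mask, filter_size=1)
        assert np.percentile(out.values[mask.values], 90) == pytest.approx(1.0, abs=1e-6)

    def test_median_idempotent_on_constant_interior(self):
        mask = box_mask((20, 20, 20), margin=1)
        vi = VentilationImage(np.where(mask.values, 2.0, 0.0), mask, "JAC")
        out = postprocess(vi, mask, filter_size=9)
        deep = np.zeros((20, 20, 20), dtype=bool)
        deep[6:14, 6:14, 6:14] = True
        assert np.allclose(out.values[deep], 1.0)

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(2)
        mask = box_mask((12, 12, 12))
        base = np.where(mask.values, rng.random((12, 12, 12)) + 0.1, 0.0)
        out1 = postprocess(VentilationImage(base, mask, "HU"), mask)
        out2 = postprocess(VentilationImage(17.3 * base, mask, "HU"), mask)
        # scaling commutes with normalization up to IEEE rounding; the
        # median filter preserves order, so outputs agree to machine epsilon
        np.testing.assert_allclose(out1.values, out2.values, rtol=1e-12, atol=1e-15)

    def test_normalize_precedes_median_filter(self):
        # pinned order: with normalize-then-filter the in-mask 90th
        # percentile of the output generally differs from 1; with
        # filter-then-normalize it would be exactly 1
        rng = np.random.default_rng(3)
        mask = box_mask((14, 14, 14))
        vi = VentilationImage(
            np.where(mask.values, rng.random((14, 14, 14)), 0.0), mask, "JAC"
        )
        out = postprocess(vi, mask, filter_size=5)
        pct = np.percentile(out.values[mask.values], 90)
        assert abs(pct - 1.0) > 1e-6

    def test_even_filter_size_rejected(self):
        mask = box_mask((8, 8, 8))
        vi = VentilationImage(np.where(mask.values, 1.0, 0.0), mask, "JAC")
        with pytest.raises(ParameterError):
            postprocess(vi, mask, filter_size=4)

    def test_nonpositive_norm_raises(self):
        mask = box_mask((8, 8, 8))
        vi = VentilationImage(np.where(mask.values, -1.0, 0.0), mask, "HU")
        with pytest.raises(DataError):
            postprocess(vi, mask)

    def test_negative_values_retained(self):
        rng = np.random.default_rng(4)
        mask = box_mask((10, 10, 10))
        values = np.where(mask.values, rng.normal(0.5, 1.0, (10, 10, 10)), 0.0)
        out = postprocess(VentilationImage(values, mask, "HU"), mask, filter_size=1)
        assert (out.values[mask.values] < 0).any()
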