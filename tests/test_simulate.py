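import numpy as np
import pytest

from floodmmi import (
    AutocorrelationFilter,
    CategoricalRaster,
    RealizationRun,
    adjusted_row,
    interior_edge_map,
    simulate_realization,
)
from floodmmi.metrics import AssessmentSite, structural_weight_array
from floodmmi.schemes import (
    UserProbabilityMatrix,
    binary_upm,
    landuse_scheme,
    landuse_upm,
    structural_weights,
)
from floodmmi.simulate import run_ensemble
from floodmmi.synthetic import SyntheticLandscapeConfig, generate_landscape

UNMANAGED_ROW = np.array([0.9310, 0.0324, 0.0168, 0.0178, 0.0020])


class TestInteriorEdgeMap:
    def test_uniform_raster_is_all_interior(self):
        raster = CategoricalRaster(np.zeros((6, 6), dtype=np.int32))
        assert interior_edge_map(raster).all()

    def test_single_differing_pixel_marks_three_by_three_block(self):
        data = np.zeros((7, 7), dtype=np.int32)
        data[3, 3] = 1
        interior = interior_edge_map(CategoricalRaster(data))
        expected = np.ones((7, 7), dtype=bool)
        expected[2:5, 2:5] = False
        assert np.array_equal(interior, expected)

    def test_checkerboard_is_all_edge(self):
        data = np.indices((6, 6)).sum(axis=0) % 2
        interior = interior_edge_map(CategoricalRaster(data.astype(np.int32)))
        assert not interior.any()

    def test_border_pixels_can_be_interior(self):
        # Off-grid neighbours count as same-class: a uniform half-plane's
        # border rows are interior, only the class boundary is edge.
        data = np.zeros((6, 6), dtype=np.int32)
        data[:, 3:] = 1
        interior = interior_edge_map(CategoricalRaster(data))
        assert interior[0, 0] and interior[5, 5]
        assert not interior[0, 2] and not interior[0, 3]


class TestAdjustedRow:
    def test_zero_gradient_is_identity(self):
        filt = AutocorrelationFilter(total_gradient=0.0)
        out = adjusted_row(UNMANAGED_ROW, 0, True, filt)
        assert np.array_equal(out, UNMANAGED_ROW)

    def test_interior_shift_closed_form(self):
        # Retention 0.9310 + 0.05 = 0.9810; off-diagonal mass rescaled by
        # 0.0190/0.0690 so the row still sums to 1.
        filt = AutocorrelationFilter(total_gradient=0.10)
        out = adjusted_row(UNMANAGED_ROW, 0, True, filt)
        assert out[0] == pytest.approx(0.9810)
        scale = 0.0190 / 0.0690
        assert np.allclose(out[1:], UNMANAGED_ROW[1:] * scale)
        assert out.sum() == pytest.approx(1.0)

    def test_edge_shift_lowers_retention(self):
        filt = AutocorrelationFilter(total_gradient=0.10)
        out = adjusted_row(UNMANAGED_ROW, 0, False, filt)
        assert out[0] == pytest.approx(0.8810)
        assert out.sum() == pytest.approx(1.0)

    def test_clamped_at_one_zeroes_off_diagonals(self):
        row = np.array([0.98, 0.01, 0.01])
        filt = AutocorrelationFilter(total_gradient=0.10)
        out = adjusted_row(row, 0, True, filt)
        assert out[0] == 1.0
        assert np.all(out[1:] == 0.0)

    def test_degenerate_certain_row_unchanged(self):
        row = np.array([1.0, 0.0])
        filt = AutocorrelationFilter(total_gradient=0.10)
        assert np.array_equal(adjusted_row(row, 0, False, filt), row)

    def test_multiplicative_mode_scales_error_mass(self):
        filt = AutocorrelationFilter(total_gradient=0.10, mode="multiplicative")
        out = adjusted_row(UNMANAGED_ROW, 0, True, filt)
        # misclassification mass 0.0690 * 0.95 = 0.06555
        assert out[0] == pytest.approx(1.0 - 0.0690 * 0.95)
        assert out.sum() == pytest.approx(1.0)

    def test_invalid_row_rejected(self):
        filt = AutocorrelationFilter(total_gradient=0.10)
        with pytest.raises(ValueError, match="probability"):
            adjusted_row(np.array([0.7, 0.7]), 0, True, filt)

    def test_filter_validation(self):
        with pytest.raises(ValueError, match="total_gradient"):
            AutocorrelationFilter(total_gradient=1.0)
        with pytest.raises(ValueError, match="mode"):
            AutocorrelationFilter(mode="geometric")
        filt = AutocorrelationFilter(total_gradient=0.2)
        assert filt.interior_shift == 0.1 and filt.edge_shift == -0.1


class TestSimulateRealization:
    def test_identity_upm_reproduces_input(self, rng):
        raster = CategoricalRaster(rng.integers(0, 3, size=(20, 20)).astype(np.int32))
        upm = UserProbabilityMatrix(probs=np.eye(3), labels=("a", "b", "c"))
        for seed in (0, 1, 99):
            out = simulate_realization(raster, upm, seed=seed)
            assert np.array_equal(out.data, raster.data)

    def test_deterministic_for_fixed_seed(self):
        raster = CategoricalRaster(np.zeros((30, 30), dtype=np.int32))
        upm = landuse_upm()
        a = simulate_realization(raster, upm, seed=17)
        b = simulate_realization(raster, upm, seed=17)
        assert np.array_equal(a.data, b.data)

    def test_nodata_untouched_and_pixels_conserved(self):
        data = np.zeros((10, 10), dtype=np.int32)
        data[0, :] = -9999
        raster = CategoricalRaster(data)
        out = simulate_realization(raster, landuse_upm(), seed=3)
        assert np.all(out.data[0, :] == -9999)
        assert out.valid_mask.sum() == raster.valid_mask.sum()
        assert out.shape == raster.shape

    def test_missing_upm_row_rejected(self):
        raster = CategoricalRaster(np.full((4, 4), 5, dtype=np.int32))
        with pytest.raises(ValueError, match="without a UPM row"):
            simulate_realization(raster, landuse_upm(), seed=0)

    def test_class_proportions_converge_to_upm_expectation(self):
        # Spatially random map, f=0: realized class shares approach p'= p U.
        config = SyntheticLandscapeConfig(
            grid_rows=50, grid_cols=50, patch_scale=0.0, seed=8
        )
        raster = generate_landscape(config)
        upm = landuse_upm()
        p_mapped = np.array([(raster.data == k).mean() for k in range(5)])
        expected = p_mapped @ upm.probs
        sums = np.zeros(5)
        n_real = 200
        for i in range(n_real):
            out = simulate_realization(raster, upm, seed=1000 + i)
            for k in range(5):
                sums[k] += (out.data == k).mean()
        realized = sums / n_real
        # 3 SD of the mean of n_real multinomial proportions per class
        n_pix = raster.data.size
        sd = np.sqrt(expected * (1 - expected) / (n_pix * n_real))
        assert np.all(np.abs(realized - expected) <= 3 * sd + 1e-9)

    def test_gradient_raises_interior_retention_lowers_edge(self):
        config = SyntheticLandscapeConfig(
            grid_rows=64, grid_cols=64, patch_scale=5.0, seed=4,
            class_labels=(0, 1), class_proportions=(0.6, 0.4),
        )
        raster = generate_landscape(config)
        upm = binary_upm()
        interior = interior_edge_map(raster)

        def retention(filt, n_real=200):
            kept_int = kept_edge = 0
            n_int = interior.sum() * n_real
            n_edge = (~interior).sum() * n_real
            for i in range(n_real):
                out = simulate_realization(raster, upm, filt, seed=i, interior=interior)
                same = out.data == raster.data
                kept_int += same[interior].sum()
                kept_edge += same[~interior].sum()
            return kept_int / n_int, kept_edge / n_edge

        r0_int, r0_edge = retention(AutocorrelationFilter(0.0))
        r10_int, r10_edge = retention(AutocorrelationFilter(0.10))
        r20_int, r20_edge = retention(AutocorrelationFilter(0.20))
        assert r0_int < r10_int < r20_int
        assert r0_edge > r10_edge > r20_edge


class TestRunEnsemble:
    def _inputs(self):
        config = SyntheticLandscapeConfig(
            grid_rows=48, grid_cols=48, patch_scale=4.0, seed=6
        )
        pert = generate_landscape(config)
        binary = CategoricalRaster((pert.data != 0).astype(np.int32))
        fp = np.zeros((48, 48), dtype=bool)
        fp[18:30, 8:40] = True
        bf = np.zeros((48, 48), dtype=bool)
        bf[12:18, 8:40] = True
        bf[30:36, 8:40] = True
        site = AssessmentSite(site_id="s1", floodplain_mask=fp, buffer_mask=bf)
        lw = {i: w for i, w in enumerate(landuse_scheme().weight_array())}
        sw = structural_weight_array(structural_weights())
        return pert, binary, site, lw, sw

    def test_identity_upms_reproduce_naive_scores(self):
        pert, binary, site, lw, sw = self._inputs()
        id5 = UserProbabilityMatrix(probs=np.eye(5), labels=tuple("abcde"))
        id2 = UserProbabilityMatrix(probs=np.eye(2), labels=("u", "m"))
        run = RealizationRun(n_realizations=1, master_seed=0)
        out = run_ensemble(run, pert, binary, [site], lw, sw, id5, id2, edge_width=2)
        for dist in out["s1"].values():
            assert dist.simulated[0] == pytest.approx(dist.naive)
            assert dist.bias == pytest.approx(0.0)

    def test_same_master_seed_gives_identical_distributions(self):
        pert, binary, site, lw, sw = self._inputs()
        run = RealizationRun(n_realizations=5, master_seed=42)
        kwargs = dict(edge_width=2)
        a = run_ensemble(run, pert, binary, [site], lw, sw,
                         landuse_upm(), binary_upm(), **kwargs)
        b = run_ensemble(run, pert, binary, [site], lw, sw,
                         landuse_upm(), binary_upm(), **kwargs)
        for m in a["s1"]:
            assert np.array_equal(a["s1"][m].simulated, b["s1"][m].simulated)

    def test_homogeneous_unmanaged_landscape_degrades_under_error(self):
        # Misclassification can only pull a perfect landscape down.
        shape = (48, 48)
        pert = CategoricalRaster(np.zeros(shape, dtype=np.int32))
        binary = CategoricalRaster(np.zeros(shape, dtype=np.int32))
        _, _, site, lw, sw = self._inputs()
        run = RealizationRun(n_realizations=20, master_seed=7)
        out = run_ensemble(run, pert, binary, [site], lw, sw,
                           landuse_upm(), binary_upm(), edge_width=2)
        idx = out["s1"]["index"]
        assert idx.naive == 1.0
        assert idx.mean < 1.0
        assert idx.bias > 0
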