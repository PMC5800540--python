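import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import oracles
from betamorph import (
    BinaryMask,
    ConstantImageError,
    PipelineParams,
    SimConfig,
    ThresholdSpec,
    auto_threshold,
    calibrate_fixed_threshold,
    clear_outside,
    close_mask,
    dice,
    generate_section,
    insulin_roi,
    measure_area,
    particle_analysis,
    threshold_mask,
    tissue_boundary,
)


# ---------------------------------------------------------------------------
# automatic thresholding


class TestAutoThreshold:
    def test_symmetric_bimodal_midpoint(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[:5] = 200
        assert auto_threshold(img) == 125

    def test_constant_image_raises(self):
        with pytest.raises(ConstantImageError):
            auto_threshold(np.full((8, 8), 7, dtype=np.uint8))

    def test_restriction_to_constant_region_raises(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[0, 0] = 100
        roi = BinaryMask(np.zeros((8, 8), dtype=bool) | (img == 0), 1.0)
        with pytest.raises(ConstantImageError):
            auto_threshold(img, restrict_to=roi)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_fixpoint_on_gaussian_mixture(self, seed):
        rng = np.random.default_rng(seed)
        n = 48 * 48
        vals = np.concatenate(
            [rng.normal(40, 10, n // 2), rng.normal(180, 10, n - n // 2)]
        )
        img = np.clip(np.rint(vals), 0, 255).astype(np.uint8).reshape(48, 48)
        t = auto_threshold(img)
        fixpoints = oracles.intermeans_fixpoints(img)
        assert t in fixpoints

    def test_restricted_histogram_ignores_outside(self):
        img = np.full((20, 20), 250, dtype=np.uint8)
        img[:10, :10] = 40
        img[10:, :10] = 180
        roi = BinaryMask(np.zeros((20, 20), dtype=bool), 1.0)
        roi.mask[:, :10] = True  # only the 40/180 half enters the histogram
        t = auto_threshold(img, restrict_to=roi)
        assert t in oracles.intermeans_fixpoints(img[:, :10])
        assert t < 200


class TestThresholdMask:
    def test_t255_empty_and_t0_strict(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert not threshold_mask(img, 255, 1.0).mask.any()
        m0 = threshold_mask(img, 0, 1.0)
        assert int(m0.mask.sum()) == int((img >= 1).sum())

    def test_invalid_threshold_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(Exception):
            threshold_mask(img, -1, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        for t in (0, 17, 128, 254):
            got = int(threshold_mask(img, t, 1.0).mask.sum())
            want = sum(1 for v in img.ravel() if v > t)
            assert got == want

    @given(st.integers(0, 6))
    @settings(max_examples=7, derandomize=True, deadline=None)
    def test_foreground_shrinks_as_threshold_increases(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        prev = threshold_mask(img, 0, 1.0).mask
        for t in range(1, 256, 16):
            cur = threshold_mask(img, t, 1.0).mask
            assert not (cur & ~prev).any()  # cur is a subset of prev
            prev = cur


# ---------------------------------------------------------------------------
# closing


class TestCloseMask:
    def test_radius_zero_is_identity(self, rng):
        m = BinaryMask(rng.random((30, 30)) < 0.3, 1.0)
        assert np.array_equal(close_mask(m, 0).mask, m.mask)

    def test_two_squares_bridged_by_radius_30(self):
        grid = np.zeros((60, 80), dtype=bool)
        grid[25:35, 10:20] = True
        grid[25:35, 35:45] = True  # 15-px gap
        closed = close_mask(BinaryMask(grid, 1.0), 30)
        _, n = ndimage.label(closed.mask, structure=np.ones((3, 3)))
        assert n == 1
        # and matches the brute-force disk closing oracle
        assert np.array_equal(closed.mask, oracles.brute_closing(grid, 30))

    @pytest.mark.parametrize("seed,radius", [(s, r) for s in range(4) for r in (1, 3, 7)])
    def test_matches_bruteforce_oracle(self, seed, radius):
        rng = np.random.default_rng(seed)
        grid = rng.random((40, 40)) < 0.15
        got = close_mask(BinaryMask(grid, 1.0), radius).mask
        assert np.array_equal(got, oracles.brute_closing(grid, radius))

    @given(st.integers(0, 9), st.integers(0, 8))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_extensive_and_idempotent(self, seed, radius):
        rng = np.random.default_rng(seed)
        m = BinaryMask(rng.random((32, 32)) < 0.2, 1.0)
        once = close_mask(m, radius)
        assert not (m.mask & ~once.mask).any()  # output superset of input
        twice = close_mask(once, radius)
        assert np.array_equal(once.mask, twice.mask)


# ---------------------------------------------------------------------------
# tissue boundary / clear outside


class TestTissueBoundary:
    def test_recovers_true_tissue_on_clean_section(self, clean_config, default_params):
        micro, truth = generate_section(clean_config, 11)
        roi = tissue_boundary(
            micro.nuclear_channel, default_params, micro.pixel_size_mm
        )
        assert dice(roi.mask, truth.tissue_mask) >= 0.95
        assert roi.provenance == "auto"

    def test_blank_channel_raises(self, default_params):
        with pytest.raises(ConstantImageError):
            tissue_boundary(
                np.zeros((64, 64), dtype=np.uint8), default_params, 0.002
            )

    def test_nucleus_dots_become_confluent_region(self, default_params):
        # bright dots on a 20-px lattice: gaps < 2 x 30 px all get included
        img = np.full((120, 120), 10, dtype=np.uint8)
        img[20:101:20, 20:101:20] = 200
        roi = tissue_boundary(img, default_params, 0.002)
        _, n = ndimage.label(roi.mask, structure=np.ones((3, 3)))
        assert n == 1
        # interior lattice gaps are filled
        assert roi.mask[30, 30] and roi.mask[50, 90]


class TestClearOutside:
    def test_full_roi_identity_and_empty_roi_zero(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        full = BinaryMask(np.ones((16, 16), dtype=bool), 1.0)
        empty = BinaryMask(np.zeros((16, 16), dtype=bool), 1.0)
        assert np.array_equal(clear_outside(img, full), img)
        assert not clear_outside(img, empty).any()

    def test_speckles_outside_tissue_are_cleared(self, artifact_config, default_params):
        micro, truth = generate_section(artifact_config, 5)
        outside_speckle = truth.confounder_masks["speckle"] & ~truth.tissue_mask
        if not outside_speckle.any():
            pytest.skip("no outside-tissue speckles at this seed")
        roi = tissue_boundary(
            micro.nuclear_channel, default_params, micro.pixel_size_mm
        )
        cleared = clear_outside(micro.insulin_channel, roi)
        outside_roi_speckle = outside_speckle & ~roi.mask
        assert (cleared[outside_roi_speckle] == 0).all()


# ---------------------------------------------------------------------------
# insulin ROI


class TestInsulinRoi:
    def test_recovers_beta_mask_on_clean_section(self, clean_config, default_params):
        micro, truth = generate_section(clean_config, 3)
        tissue = tissue_boundary(
            micro.nuclear_channel, default_params, micro.pixel_size_mm
        )
        roi = insulin_roi(micro.insulin_channel, tissue, default_params)
        assert dice(roi.mask, truth.beta_mask) >= 0.90

    def test_fixed_threshold_255_empty(self, clean_config, default_params):
        micro, _ = generate_section(clean_config, 3)
        tissue = tissue_boundary(
            micro.nuclear_channel, default_params, micro.pixel_size_mm
        )
        params = dataclasses.replace(
            default_params, threshold_spec=ThresholdSpec("fixed", 255)
        )
        roi = insulin_roi(micro.insulin_channel, tissue, params)
        assert not roi.mask.any()

    def test_dim_islets_are_excluded_by_auto_threshold(
        self, clean_config, default_params
    ):
        # gap kept above the closing diameter so a dim islet cannot be
        # swallowed by a bridge to a neighbouring bright islet
        cfg = dataclasses.replace(
            clean_config, dim_islet_fraction=0.5, dim_intensity_scale=0.3,
            islet_count_mean=3.0, min_islet_gap_mm=0.050,
        )
        found_dim = 0
        for seed in range(6):
            micro, truth = generate_section(cfg, seed)
            islets = truth.per_islet_table
            # weak positivity is only sub-threshold when bright signal
            # anchors the automatic threshold high
            if not (islets["intensity_class"] == "dim").any():
                continue
            if not (islets["intensity_class"] == "bright").any():
                continue
            tissue = tissue_boundary(
                micro.nuclear_channel, default_params, micro.pixel_size_mm
            )
            roi = insulin_roi(micro.insulin_channel, tissue, default_params)
            for _, islet in islets[islets["intensity_class"] == "dim"].iterrows():
                found_dim += 1
                r, c = int(islet["center_row"]), int(islet["center_col"])
                assert not roi.mask[r, c]  # dim islet center not detected
        assert found_dim > 0


class TestCalibrateFixedThreshold:
    def test_perfect_agreement_fixpoint(self, rng):
        img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        ref = img > 100
        assert calibrate_fixed_threshold([(img, ref)]) == 100

    def test_median_of_per_field_optima(self, rng):
        fields = []
        for cut in (90, 100, 110):
            img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
            fields.append((img, img > cut))
        assert calibrate_fixed_threshold(fields) == 100

    @pytest.mark.parametrize("seed", range(4))
    def test_noisy_fields_match_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        clean_ref = img > 120
        noisy_ref = clean_ref ^ (rng.random((32, 32)) < 0.05)
        if not noisy_ref.any():
            noisy_ref[0, 0] = True
        got = calibrate_fixed_threshold([(img, noisy_ref)])
        assert got == oracles.best_dice_threshold(img, noisy_ref)

    def test_empty_field_list_rejected(self):
        with pytest.raises(Exception):
            calibrate_fixed_threshold([])


# ---------------------------------------------------------------------------
# particles / areas


class TestParticleAnalysis:
    def test_single_component_arithmetic(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[5:15, 5:15] = True  # 100 px
        table = particle_analysis(BinaryMask(grid, 0.001), 6.5e-5)
        assert len(table) == 1
        assert table.loc[0, "pixel_count"] == 100
        assert table.loc[0, "area_mm2"] == pytest.approx(1.0e-4)
        assert table.loc[0, "equiv_diameter_mm"] == pytest.approx(
            2 * np.sqrt(1.0e-4 / np.pi)
        )
        assert bool(table.loc[0, "kept"])

    def test_cutoff_above_everything_keeps_nothing(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[2:4, 2:4] = True
        grid[10:13, 10:13] = True
        table = particle_analysis(BinaryMask(grid, 0.001), 1.0)
        assert not table["kept"].any()
        assert measure_area(table) == 0.0

    def test_empty_mask_empty_table(self):
        table = particle_analysis(BinaryMask(np.zeros((8, 8), dtype=bool), 1.0), 0.0)
        assert len(table) == 0
        assert measure_area(table) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((40, 40)) < 0.25
        table = particle_analysis(BinaryMask(grid, 0.01), 0.0)
        labels, n = oracles.flood_fill_label(grid)
        assert len(table) == n
        for _, row in table.iterrows():
            lab = int(row["label"])
            assert int((labels == lab).sum()) == int(row["pixel_count"])

    @pytest.mark.parametrize("seed", range(3))
    def test_area_conservation_without_filter(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((30, 30)) < 0.3
        mask = BinaryMask(grid, 0.002)
        table = particle_analysis(mask, 0.0)
        assert measure_area(table) == pytest.approx(measure_area(mask), rel=1e-12)


class TestMeasureArea:
    def test_empty_mask_zero(self):
        assert measure_area(BinaryMask(np.zeros((5, 5), dtype=bool), 1.0)) == 0.0

    def test_two_kept_particles_sum(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[1:3, 1:6] = True  # 10 px
        grid[10:14, 10:15] = True  # 20 px
        table = particle_analysis(BinaryMask(grid, 0.001), 0.0)
        assert measure_area(table) == pytest.approx(3.0e-5)
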