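import numpy as np
import pytest

from periquant import (
    DegenerateInputError,
    FixtureSpec,
    SimulationConfig,
    UndefinedFractionError,
    ValidationError,
    analyze_image,
    analyze_masks,
    density_fractions,
    dilate,
    kernel_px_for_width,
    make_fixture,
    mask_area,
    neighborhood_areas,
    run_simulation_study,
)

from conftest import SMALL_RING, oracle_dilate


class TestKernelForWidth:
    @pytest.mark.parametrize(
        "width,scale,expected",
        [(10, 1.5, 31), (20, 1.5, 61), (30, 1.5, 91), (40, 1.5, 121), (50, 1.5, 151), (10, 0.5, 11)],
    )
    def test_series(self, width, scale, expected):
        assert kernel_px_for_width(width, scale) == expected

    def test_always_odd(self):
        r = np.random.default_rng(0)
        for _ in range(50):
            k = kernel_px_for_width(r.uniform(0.1, 80), r.uniform(0.1, 4))
            assert k % 2 == 1 and k >= 1

    @pytest.mark.parametrize("args", [(0, 1.5), (-5, 1.5), (10, 0), (10, -1)])
    def test_invalid(self, args):
        with pytest.raises(ValidationError):
            kernel_px_for_width(*args)


class TestDilate:
    def test_empty(self):
        assert not dilate(np.zeros((9, 9), bool), 5).any()

    def test_unit_kernel_identity(self):
        mask = np.random.default_rng(1).random((12, 12)) > 0.5
        np.testing.assert_array_equal(dilate(mask, 1), mask)

    def test_single_pixel_kernel5(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        out = dilate(mask, 5)
        assert mask_area(out) == 25
        assert out[2:7, 2:7].all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            dilate(np.zeros((4, 4), bool), 4)

    @pytest.mark.parametrize("kernel", [1, 3, 5, 9])
    def test_chebyshev_oracle(self, kernel):
        for seed in range(6):
            mask = np.random.default_rng(seed).random((24, 24)) > 0.9
            np.testing.assert_array_equal(dilate(mask, kernel), oracle_dilate(mask, kernel))


class TestNeighborhoodAreas:
    def test_saturation(self):
        a_t = np.ones((10, 10), bool)
        a_n, a_d = neighborhood_areas(a_t, a_t, 3)
        assert not a_n.any() and not a_d.any()

    def test_unit_kernel(self):
        a_t = np.ones((10, 10), bool)
        structure = np.zeros((10, 10), bool)
        structure[4:6, 4:6] = True
        a_n, a_d = neighborhood_areas(structure, a_t, 1)
        assert not a_n.any()
        np.testing.assert_array_equal(a_d, a_t & ~structure)

    def test_large_kernel_covers_frame(self):
        a_t = np.ones((20, 20), bool)
        structure = np.zeros((20, 20), bool)
        structure[10, 10] = True
        a_n, a_d = neighborhood_areas(structure, a_t, 31)
        assert not a_d.any()
        assert mask_area(a_n) == 400 - 1

    def test_empty_structure_rejected(self):
        with pytest.raises(DegenerateInputError):
            neighborhood_areas(np.zeros((5, 5), bool), np.ones((5, 5), bool), 3)

    def test_partition_identity_random(self):
        r = np.random.default_rng(3)
        for _ in range(10):
            a_t = r.random((24, 24)) > 0.2
            structure = (r.random((24, 24)) > 0.92) & a_t
            if not structure.any():
                continue
            for k in (1, 3, 7):
                a_n, a_d = neighborhood_areas(structure, a_t, k)
                assert mask_area(a_n) + mask_area(a_d) + mask_area(structure) == mask_area(a_t)
                assert not (a_n & a_d).any()
                assert not (a_n & structure).any()

    def test_clip_flag(self):
        a_t = np.zeros((20, 20), bool)
        a_t[:, :10] = True
        structure = np.zeros((20, 20), bool)
        structure[10, 8] = True
        clipped, _ = neighborhood_areas(structure, a_t, 7)
        unclipped, _ = neighborhood_areas(structure, a_t, 7, clip_to_specimen=False)
        assert (clipped <= a_t).all()
        assert (unclipped & ~a_t).any()


class TestDensityFractions:
    def test_saturation_and_void(self):
        a_n = np.zeros((10, 10), bool)
        a_n[:5] = True
        a_d = ~a_n
        f_n, f_d = density_fractions(a_n.copy(), a_n, a_d)
        assert f_n == 1.0 and f_d == 0.0

    def test_empty_cells(self):
        a_n = np.zeros((10, 10), bool)
        a_n[:5] = True
        f_n, f_d = density_fractions(np.zeros((10, 10), bool), a_n, ~a_n)
        assert f_n == 0.0 and f_d == 0.0

    def test_pixel_counting(self):
        # 100-px neighborhood with 10 red; 1000-px residual with 10 red
        a_n = np.zeros((40, 40), bool)
        a_n[0, :] = True
        a_n[1, :] = True
        a_n[2, :20] = True
        a_d = np.zeros((40, 40), bool)
        a_d[10:35, :] = True
        a_r = np.zeros((40, 40), bool)
        a_r[0, :10] = True
        a_r[20, :10] = True
        f_n, f_d = density_fractions(a_r, a_n, a_d)
        assert f_n == pytest.approx(0.10)
        assert f_d == pytest.approx(0.01)
        assert f_n / f_d == pytest.approx(10.0)

    def test_undefined_denominators(self):
        full = np.ones((5, 5), bool)
        empty = np.zeros((5, 5), bool)
        with pytest.raises(UndefinedFractionError) as err:
            density_fractions(empty, empty, full)
        assert err.value.denominator == "a_n"
        with pytest.raises(UndefinedFractionError) as err:
            density_fractions(empty, full, empty)
        assert err.value.denominator == "a_d"


class TestAnalyze:
    def test_five_widths_monotone_areas(self, ring_fixture):
        image, roi, _ = ring_fixture
        results = analyze_image(image, roi, [4, 8, 12, 16, 20])
        assert len(results) == 5
        areas_n = [r.area_N for r in results]
        areas_d = [r.area_D for r in results]
        assert areas_n == sorted(areas_n)
        assert areas_d == sorted(areas_d, reverse=True)

    def test_partition_per_width(self, ring_fixture):
        image, roi, _ = ring_fixture
        for r in analyze_image(image, roi, [10, 20]):
            assert r.area_N + r.area_D + r.area_B == r.area_T

    def test_red_conservation(self, ring_fixture):
        image, roi, truth = ring_fixture
        for r in analyze_image(image, roi, [10, 20]):
            assert r.area_NR + r.area_DR + r.area_RB == r.area_R
            assert r.area_R == mask_area(truth["a_r"])

    def test_widths_must_increase(self, ring_fixture):
        image, roi, _ = ring_fixture
        with pytest.raises(ValidationError):
            analyze_image(image, roi, [20, 10])

    def test_empty_specimen_rejected(self, ring_fixture):
        image, _, _ = ring_fixture
        from periquant import RoiSpec

        rect = [(-0.5, -0.5), (-0.5, 95.5), (95.5, 95.5), (95.5, -0.5)]
        roi = RoiSpec(include_polygons=[rect], exclude_polygons=[rect])
        with pytest.raises(DegenerateInputError):
            analyze_image(image, roi, [10])

    def test_planted_band_only_cells_give_zero_f_d(self):
        # construct masks directly: all cells within the 10 um band
        a_t = np.ones((80, 80), bool)
        a_b = np.zeros((80, 80), bool)
        a_b[38:42, 38:42] = True
        a_r = np.zeros((80, 80), bool)
        a_r[36, 36] = True  # Chebyshev distance 2 from structure
        for r in analyze_masks(a_r, a_b, a_t, [10, 20], 1.5):
            assert r.F_D == 0.0
            assert r.F_N > 0.0

    def test_uniform_cells_ratio_near_one(self, ring_geometry):
        # simulation oracle: ratio of a uniform fixture within 3 SDs of 1
        a_t, a_b = ring_geometry
        config = SimulationConfig(
            seed_counts=(60,), replicates_per_count=40,
            target_cell_area_px=9, rng_seed=5,
        )
        study = run_simulation_study(a_t, a_b, [10], config, 1.5)
        sd = float(study.summary["sd_ratio"].iloc[0])
        spec = FixtureSpec(
            frame=(160, 160),
            structure_params={"radius_px": 22, "thickness_px": 3},
            n_cells=60, cell_area_px=9, rng_seed=21,
        )
        image, roi, _ = make_fixture(spec)
        result = analyze_image(image, roi, [10])[0]
        assert abs(result.ratio - 1.0) <= 3 * sd
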