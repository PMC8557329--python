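import math

import numpy as np
import pandas as pd
import pytest
import tifffile
from shapely.geometry import Point, Polygon

from dysquant import simulate
from dysquant.simulate import (
    MAX_AU,
    PRESETS,
    FiberSpec,
    PhenotypePreset,
    RenderConfig,
    SimulationError,
    build_fiber_specs,
    generate_geometry,
    render_section,
    sample_fibers,
    simulate_section,
)


class TestGenerateGeometry:
    def test_single_fiber_inside_frame(self):
        polys = generate_geometry(1, (64, 64), gap=2, seed=0, margin=5)
        assert len(polys) == 1
        minx, miny, maxx, maxy = polys[0].bounds
        assert minx >= 0 and miny >= 0 and maxx <= 64 and maxy <= 64

    def test_deterministic(self):
        a = generate_geometry(100, (1024, 1024), gap=2, seed=7)
        b = generate_geometry(100, (1024, 1024), gap=2, seed=7)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.equals(pb)

    def test_no_pairwise_overlap(self):
        polys = generate_geometry(100, (1024, 1024), gap=2, seed=7)
        assert len(polys) >= 90
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert polys[i].intersection(polys[j]).area == 0.0

    def test_gap_separation(self):
        gap = 3.0
        polys = generate_geometry(60, (768, 768), gap=gap, seed=2)
        # neighbouring cells were each shrunk by gap/2
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert polys[i].distance(polys[j]) >= 0.9 * gap

    def test_too_small_raises(self):
        with pytest.raises(SimulationError, match="area"):
            generate_geometry(100, (64, 64), gap=2, seed=0)

    def test_bad_args(self):
        with pytest.raises(SimulationError):
            generate_geometry(0, (256, 256), gap=2, seed=0)
        with pytest.raises(SimulationError):
            generate_geometry(10, (256, 256), gap=0.5, seed=0)


class TestSampleFibers:
    def test_ctrl_all_high_coverage(self):
        draws = sample_fibers(PRESETS["CTRL"], 500, seed=0)
        assert all(cov >= 0.75 for cov, _ in draws)

    def test_dmd_bin_fractions_converge(self):
        draws = sample_fibers(PRESETS["DMD"], 10_000, seed=1)
        cov = np.array([c for c, _ in draws])
        fracs = [
            ((cov >= lo) & (cov < hi)).mean()
            for lo, hi in [(0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.01)]
        ]
        for got, want in zip(fracs, (0.52, 0.30, 0.12, 0.06)):
            assert abs(got - want) <= 0.02

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_preset_fidelity(self, name):
        draws = sample_fibers(PRESETS[name], 5_000, seed=3)
        cov = np.array([c for c, _ in draws])
        fracs = [
            ((cov >= lo) & (cov < hi)).mean()
            for lo, hi in [(0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.01)]
        ]
        for got, want in zip(fracs, PRESETS[name].bin_fractions):
            assert abs(got - want) <= 0.02

    def test_zero_cv_constant_intensity(self):
        preset = PhenotypePreset("flat", (0.25, 0.25, 0.25, 0.25), 1234.0, 0.0)
        draws = sample_fibers(preset, 50, seed=0)
        assert all(inten == 1234.0 for _, inten in draws)

    def test_deterministic(self):
        assert sample_fibers(PRESETS["DMD"], 100, seed=9) == sample_fibers(
            PRESETS["DMD"], 100, seed=9
        )

    def test_intensity_in_range(self):
        draws = sample_fibers(PRESETS["CTRL"], 2_000, seed=4)
        assert all(0 <= inten <= MAX_AU for _, inten in draws)


class TestPresetValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            PhenotypePreset("bad", (0.5, 0.5, 0.5, 0.5), 100.0, 0.1)

    def test_negative_fraction(self):
        with pytest.raises(SimulationError):
            PhenotypePreset("bad", (-0.1, 0.4, 0.4, 0.3), 100.0, 0.1)

    def test_intensity_range(self):
        with pytest.raises(SimulationError):
            PhenotypePreset("bad", (0, 0, 0, 1.0), 1e6, 0.1)


class TestRenderSection:
    def test_noiseless_full_coverage_identity(self, noiseless_config, disk_fiber):
        spec = FiberSpec(1, disk_fiber, true_coverage=1.0, true_intensity=20_000.0)
        image, truth = render_section([spec], noiseless_config)
        dys = image.dystrophin
        on = dys > 0
        assert on.any()
        assert set(np.unique(dys[on])) == {20_000}
        lam_on = image.laminin > 0
        # dystrophin signal sits exactly on the rendered laminin band
        assert np.array_equal(on, lam_on)

    def test_deterministic(self, disk_fiber):
        config = RenderConfig(image_size=(256, 256), seed=3)
        spec = FiberSpec(1, disk_fiber, 0.6, 30_000.0, 1.0)
        img1, _ = render_section([spec], config)
        img2, _ = render_section([spec], config)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_half_coverage_ring_fraction(self, noiseless_config, disk_fiber):
        spec = FiberSpec(1, disk_fiber, true_coverage=0.5, true_intensity=10_000.0)
        image, _ = render_section([spec], noiseless_config)
        ring = image.laminin > 0
        frac = (image.dystrophin[ring] > 0).mean()
        assert abs(frac - 0.5) <= 0.02

    def test_dtype_and_range(self, dmd_section):
        image, _ = dmd_section
        assert image.pixels.dtype == np.uint16
        assert image.pixels.max() <= MAX_AU

    def test_ground_truth_rows(self, dmd_section):
        image, truth = dmd_section
        assert truth["fiber_id"].is_unique
        assert len(truth) >= 0.9 * 150
        assert set(truth.columns) == {
            "fiber_id",
            "true_coverage",
            "true_intensity",
            "cx",
            "cy",
            "area_px",
        }

    def test_intensity_monotonicity(self, noiseless_config, disk_fiber):
        means = []
        for intensity in (1_000.0, 10_000.0, 40_000.0):
            spec = FiberSpec(1, disk_fiber, 1.0, intensity)
            image, _ = render_section([spec], noiseless_config)
            ring = image.laminin > 0
            means.append(image.dystrophin[ring].mean())
        assert means == sorted(means)

    def test_out_of_frame_raises(self, noiseless_config):
        poly = Point(250, 250).buffer(20)
        with pytest.raises(SimulationError, match="frame"):
            render_section([FiberSpec(1, poly, 1.0, 100.0)], noiseless_config)

    def test_duplicate_ids_raise(self, noiseless_config, disk_fiber):
        specs = [
            FiberSpec(1, disk_fiber, 1.0, 100.0),
            FiberSpec(1, Point(60, 60).buffer(10), 1.0, 100.0),
        ]
        with pytest.raises(SimulationError, match="duplicate"):
            render_section(specs, noiseless_config)

    def test_clipping_not_an_error(self, disk_fiber):
        config = RenderConfig(
            image_size=(256, 256), noise_sd=10_000.0, blur_sigma=0.0, seed=1
        )
        spec = FiberSpec(1, disk_fiber, 1.0, 65_000.0)
        image, _ = render_section([spec], config)
        assert image.pixels.max() <= MAX_AU


class TestFiberSpecValidation:
    def test_coverage_range(self, disk_fiber):
        with pytest.raises(SimulationError):
            FiberSpec(1, disk_fiber, true_coverage=1.5)

    def test_intensity_range(self, disk_fiber):
        with pytest.raises(SimulationError):
            FiberSpec(1, disk_fiber, true_intensity=-3.0)


class TestSimulateSection:
    def test_deterministic_end_to_end(self):
        img1, t1 = simulate_section("DMD", 60, seed=13, image_size=(640, 640))
        img2, t2 = simulate_section("DMD", 60, seed=13, image_size=(640, 640))
        assert np.array_equal(img1.pixels, img2.pixels)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_preset(self):
        with pytest.raises(SimulationError, match="unknown preset"):
            simulate_section("nosuch", 10, seed=0)


class TestIO:
    def test_tiff_roundtrip(self, tmp_path, dmd_section):
        image, truth = dmd_section
        path = tmp_path / "section.ome.tif"
        simulate.write_section(str(path), image)
        back = tifffile.imread(str(path))
        assert np.array_equal(back, image.pixels)
        csv = tmp_path / "truth.csv"
        simulate.write_ground_truth(str(csv), truth)
        back_truth = pd.read_csv(csv)
        assert list(back_truth.columns) == list(truth.columns)
        assert len(back_truth) == len(truth)
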