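import math

import numpy as np
import pandas as pd
import pytest
import tifffile
from scipy import ndimage

from evtem.detect import (
    DetectionConfig,
    detect_particles,
    filter_regions,
    find_maxima,
    fit_ellipse,
    process_folder,
    segment_from_maxima,
)
from evtem.io_calib import CalibrationInfo, ImageFrame
from evtem.synthetic import (
    DiameterDistribution,
    SceneParams,
    match_to_truth,
    simulate_scene,
)
from conftest import disc_mask, ellipse_mask


def two_particle_scene(d1=36.0, d2=44.0, noise=0.0, seed=1):
    return simulate_scene(
        SceneParams(
            seed=seed,
            n_particles=2,
            noise_sd=noise,
            cup_probability=0.0,
            aspect_range=(1.0, 1.0),
            diameters=DiameterDistribution("fixed", values=(d1, d2)),
        )
    )


class TestFindMaxima:
    def test_constant_image_has_no_maxima(self):
        frame = ImageFrame(np.full((64, 64), 100, dtype=np.uint8), 1.0)
        assert find_maxima(frame, 0.0) == []
        assert find_maxima(frame, 10.0) == []

    def test_two_separated_cores_give_two_seeds(self):
        sc = two_particle_scene()
        seeds = find_maxima(sc.frame, 30.0)
        # cores plus possibly the flat background plateau
        core_seeds = []
        for t in sc.truth:
            tx, ty = t.center_px
            near = [s for s in seeds if math.hypot(s[1] - tx, s[0] - ty) <= 2.0]
            core_seeds.append(near)
        assert all(len(n) == 1 for n in core_seeds)

    def test_amplitude_below_tolerance_excluded(self):
        sc = two_particle_scene()
        full_range = float(sc.frame.pixels.max()) - float(sc.frame.pixels.min())
        assert find_maxima(sc.frame, full_range + 5) == []

    def test_sorted_by_descending_peak_intensity(self):
        img = np.full((40, 40), 50, dtype=np.uint8)
        img[10, 10] = 200
        img[30, 30] = 150
        frame = ImageFrame(img, 1.0)
        seeds = find_maxima(frame, 20.0)
        assert seeds[0] == (10, 10)
        assert (30, 30) in seeds

    def test_plateau_contributes_single_seed_at_centroid(self):
        img = np.full((40, 40), 50, dtype=np.uint8)
        img[10:14, 20:24] = 200  # 4x4 flat plateau
        frame = ImageFrame(img, 1.0)
        seeds = find_maxima(frame, 20.0)
        plateau_seeds = [s for s in seeds if img[s] == 200]
        assert len(plateau_seeds) == 1
        r, c = plateau_seeds[0]
        assert abs(r - 11.5) <= 1 and abs(c - 21.5) <= 1

    def test_negative_tolerance_rejected(self):
        frame = ImageFrame(np.zeros((8, 8), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            find_maxima(frame, -1.0)

    def test_inverted_polarity_finds_dark_particles(self):
        sc = simulate_scene(
            SceneParams(seed=4, invert=True, cup_probability=0.0, noise_sd=0.0)
        )
        seeds = find_maxima(sc.frame, 30.0, invert=True)
        hits = 0
        for t in sc.truth:
            tx, ty = t.center_px
            if any(math.hypot(s[1] - tx, s[0] - ty) <= 2.0 for s in seeds):
                hits += 1
        assert hits == len(sc.truth)


class TestSegmentFromMaxima:
    def test_empty_seed_list_gives_all_zero(self, default_config):
        frame = ImageFrame(np.random.default_rng(0).integers(0, 255, (32, 32)).astype(np.uint8), 1.0)
        labels = segment_from_maxima(frame, [], default_config)
        assert labels.shape == frame.shape
        assert not labels.any()

    def test_seed_outside_frame_rejected(self, default_config):
        frame = ImageFrame(np.zeros((32, 32), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="outside"):
            segment_from_maxima(frame, [(40, 4)], default_config)

    def test_isolated_core_matches_level_set_oracle(self, default_config):
        """Region pixel count agrees within 10% with directly thresholding
        the noise-free render at the seg_fraction level."""
        sc = two_particle_scene()
        img = sc.frame.pixels.astype(float)
        seeds = find_maxima(sc.frame, 30.0)
        labels = segment_from_maxima(sc.frame, seeds, default_config)
        bg = float(np.median(img))
        for t in sc.truth:
            tx, ty = t.center_px
            seed = min(seeds, key=lambda s: math.hypot(s[1] - tx, s[0] - ty))
            lab = labels[seed]
            assert lab > 0
            peak = img[seed]
            level = bg + default_config.seg_fraction * (peak - bg)
            r = t.d_true_nm / 2.0 + 3
            r0, r1 = int(ty - r), int(ty + r) + 1
            c0, c1 = int(tx - r), int(tx + r) + 1
            oracle = int((img[r0:r1, c0:c1] >= level).sum())
            got = int((labels == lab).sum())
            assert got == pytest.approx(oracle, rel=0.10)

    def test_overlapping_cores_split_by_watershed(self, default_config):
        """Two particles closer than their combined radii are separated
        into two labels with a watershed gap between them."""
        params = SceneParams(
            seed=3,
            image_size_px=(70, 70),  # small frame forces the pair together
            n_particles=2,
            noise_sd=0.0,
            cup_probability=0.0,
            aspect_range=(1.0, 1.0),
            allow_overlap=True,
            min_gap_px=24.0,
            diameters=DiameterDistribution("fixed", values=(40.0, 40.0)),
        )
        sc = simulate_scene(params)
        d = math.hypot(
            sc.truth[0].center_px[0] - sc.truth[1].center_px[0],
            sc.truth[0].center_px[1] - sc.truth[1].center_px[1],
        )
        assert d < 40.0  # genuinely overlapping outer outlines
        seeds = find_maxima(sc.frame, 30.0)
        labels = segment_from_maxima(sc.frame, seeds, default_config)
        core_labels = set()
        for t in sc.truth:
            tx, ty = t.center_px
            seed = min(seeds, key=lambda s: math.hypot(s[1] - tx, s[0] - ty))
            core_labels.add(int(labels[seed]))
        assert len(core_labels) == 2 and 0 not in core_labels
        a, b = core_labels
        grown = ndimage.binary_dilation(
            labels == a, structure=np.ones((3, 3), bool)
        )
        # regions touch at most across the 1-px watershed line, never overlap
        assert not np.any((labels == a) & (labels == b))
        assert np.any(grown & ~(labels == a))


class TestFilterRegions:
    @staticmethod
    def _frame_with_labels(shapes):
        labels = np.zeros((128, 128), dtype=np.int32)
        for lab, (mask, r0, c0) in enumerate(shapes, start=1):
            h, w = mask.shape
            labels[r0 : r0 + h, c0 : c0 + w][mask] = lab
        frame = ImageFrame(np.full((128, 128), 128, dtype=np.uint8), 1.0)
        return labels, frame

    def test_size_bounds_inclusive_and_exclusive(self):
        labels, frame = self._frame_with_labels(
            [(disc_mask(3), 10, 10), (disc_mask(10), 40, 40), (disc_mask(30), 60, 60)]
        )
        cfg = DetectionConfig(min_size_nm2=100.0, max_size_nm2=1000.0)
        kept = filter_regions(labels, frame, cfg)
        assert kept == [2]  # 29 px too small, 2821 px too large

    def test_line_region_fails_circularity(self):
        line = np.ones((1, 30), dtype=bool)
        labels, frame = self._frame_with_labels([(line, 20, 20), (disc_mask(10), 60, 60)])
        cfg = DetectionConfig(min_size_nm2=10.0, max_size_nm2=2000.0, min_circularity=0.5)
        assert filter_regions(labels, frame, cfg) == [2]

    def test_border_exclusion_flag(self):
        mask = disc_mask(10)
        labels, frame = self._frame_with_labels([(mask, 0, 50)])  # touches row 0
        cfg_excl = DetectionConfig(min_size_nm2=10.0, max_size_nm2=2000.0, min_circularity=0.0)
        assert filter_regions(labels, frame, cfg_excl) == []
        cfg_incl = DetectionConfig(
            min_size_nm2=10.0, max_size_nm2=2000.0, min_circularity=0.0, exclude_border=False
        )
        assert filter_regions(labels, frame, cfg_incl) == [1]


class TestFitEllipse:
    def test_disc_is_nearly_circular(self):
        coords = np.argwhere(disc_mask(20))
        e = fit_ellipse(coords, 1.0)
        assert e.major_nm / e.minor_nm == pytest.approx(1.0, rel=0.02)

    def test_two_to_one_ellipse_recovered(self):
        coords = np.argwhere(ellipse_mask(30, 15))  # 2:1, major along x
        e = fit_ellipse(coords, 1.0)
        assert e.major_nm / e.minor_nm == pytest.approx(2.0, rel=0.05)
        assert min(e.angle_deg, 180.0 - e.angle_deg) < 3.0

    def test_area_preserved_exactly(self):
        coords = np.argwhere(ellipse_mask(12, 7))
        e = fit_ellipse(coords, 1.0)
        ellipse_area = math.pi * (e.major_nm / 2) * (e.minor_nm / 2)
        assert ellipse_area == pytest.approx(e.area_nm2, rel=1e-3)
        assert e.area_nm2 == len(coords)

    def test_three_pixel_l_region(self):
        coords = np.array([[0, 0], [1, 0], [1, 1]])
        e = fit_ellipse(coords, 1.0)
        assert e.major_nm >= e.minor_nm > 0
        assert e.area_nm2 == 3.0
        assert 0.0 <= e.angle_deg < 180.0

    def test_collinear_region_floors_minor_axis(self):
        coords = np.array([[0, i] for i in range(12)])
        with pytest.warns(UserWarning, match="collinear"):
            e = fit_ellipse(coords, 1.0)
        assert e.minor_nm == pytest.approx(1.0)

    def test_nm_scaling(self):
        coords = np.argwhere(disc_mask(10))
        e1 = fit_ellipse(coords, 1.0)
        e2 = fit_ellipse(coords, 0.5)
        assert e2.major_nm == pytest.approx(e1.major_nm * 0.5)
        assert e2.area_nm2 == pytest.approx(e1.area_nm2 * 0.25)


class TestDetectParticles:
    def test_blank_noisy_frame_yields_empty_table(self, default_config):
        sc = simulate_scene(SceneParams(seed=8, n_particles=0, noise_sd=0.02))
        table = detect_particles(sc.frame, default_config)
        assert len(table) == 0

    def test_all_in_range_particles_found_and_matched(self, default_config):
        sc = simulate_scene(
            SceneParams(
                seed=17,
                n_particles=15,
                diameters=DiameterDistribution("normal", 36.0, 6.0),
            )
        )
        table = detect_particles(sc.frame, default_config)
        assert len(table) == 15
        matches, precision, recall = match_to_truth(table.records, sc.truth, 3.0)
        assert precision == 1.0 and recall == 1.0

    def test_below_min_size_particles_reduce_count_exactly(self, default_config):
        vals = (30.0, 35.0, 40.0, 28.0, 33.0, 38.0, 42.0, 36.0, 31.0, 39.0, 34.0, 37.0, 10.0, 10.0, 10.0)
        sc = simulate_scene(
            SceneParams(
                seed=7,
                n_particles=15,
                diameters=DiameterDistribution("fixed", values=vals),
            )
        )
        assert len(sc.truth) == 15
        table = detect_particles(sc.frame, default_config)
        # the three 10 nm particles render 7.4 nm cores (~43 nm^2 < 75)
        assert len(table) == 12

    def test_determinism(self, default_config, clean_scene):
        t1 = detect_particles(clean_scene.frame, default_config)
        t2 = detect_particles(clean_scene.frame, default_config)
        pd.testing.assert_frame_equal(t1.to_dataframe(), t2.to_dataframe())

    def test_scale_equivariance(self, clean_scene):
        """Doubling nm_per_px (with size bounds rescaled accordingly)
        doubles nm outputs and quadruples nm^2 outputs exactly, leaving
        pixel-level quantities unchanged."""
        k = 2.0
        f1 = clean_scene.frame
        f2 = ImageFrame(f1.pixels, f1.nm_per_px * k, f1.source, f1.bit_depth)
        c1 = DetectionConfig()
        c2 = DetectionConfig(
            min_size_nm2=c1.min_size_nm2 * k**2, max_size_nm2=c1.max_size_nm2 * k**2
        )
        t1 = detect_particles(f1, c1)
        t2 = detect_particles(f2, c2)
        assert len(t1) == len(t2) > 0
        for a, b in zip(t1.records, t2.records):
            assert b.ellipse.center_px == a.ellipse.center_px
            assert b.circularity == a.circularity
            assert b.d_linear_nm == pytest.approx(a.d_linear_nm * k, rel=1e-12)
            assert b.d_area_nm == pytest.approx(a.d_area_nm * k, rel=1e-12)
            assert b.area_nm2 == pytest.approx(a.area_nm2 * k**2, rel=1e-12)

    def test_records_carry_consistent_measures(self, default_config, clean_scene):
        table = detect_particles(clean_scene.frame, default_config)
        for r in table.records:
            assert r.area_nm2 > 0
            assert r.d_area_nm == pytest.approx(math.sqrt(4 * r.area_nm2 / math.pi))
            assert 0 < r.circularity <= 1.05
            assert r.d_linear_nm > 0
            ellipse_area = math.pi * (r.ellipse.major_nm / 2) * (r.ellipse.minor_nm / 2)
            assert ellipse_area == pytest.approx(r.area_nm2, rel=1e-3)


class TestProcessFolder:
    @pytest.fixture
    def scene_folder(self, tmp_path):
        src = tmp_path / "images"
        src.mkdir()
        for k in range(3):
            sc = simulate_scene(SceneParams(seed=50 + k, n_particles=10))
            tifffile.imwrite(src / f"scene_{k}.tif", sc.frame.pixels)
        return src

    def test_per_image_and_combined_outputs(self, scene_folder, tmp_path, default_config):
        out = tmp_path / "out"
        cal = CalibrationInfo(nm_per_px=1.0)
        combined = process_folder(scene_folder, default_config, out, cal)
        csvs = sorted(p.name for p in out.glob("*.csv"))
        assert csvs == ["combined.csv", "scene_0.csv", "scene_1.csv", "scene_2.csv"]
        n_parts = sum(
            len(pd.read_csv(out / f"scene_{k}.csv")) for k in range(3)
        )
        assert len(pd.read_csv(out / "combined.csv")) == n_parts == len(combined)
        assert (out / "run_log.json").exists()

    def test_corrupt_image_skipped_with_log(self, scene_folder, tmp_path, default_config, caplog):
        (scene_folder / "bad.tif").write_bytes(b"II*\x00nope")
        out = tmp_path / "out"
        cal = CalibrationInfo(nm_per_px=1.0)
        import logging

        with caplog.at_level(logging.WARNING):
            process_folder(scene_folder, default_config, out, cal)
        assert "bad.tif" in caplog.text
        assert not (out / "bad.csv").exists()

    def test_no_readable_images_is_error(self, tmp_path, default_config):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(IOError):
            process_folder(empty, default_config, tmp_path / "o", CalibrationInfo(1.0))

    def test_rerun_is_byte_identical(self, scene_folder, tmp_path, default_config):
        cal = CalibrationInfo(nm_per_px=1.0)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        process_folder(scene_folder, default_config, out1, cal)
        process_folder(scene_folder, default_config, out2, cal)
        for p1 in sorted(out1.iterdir()):
            assert p1.read_bytes() == (out2 / p1.name).read_bytes()
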