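"""Chip layout, bead loading, rendering and dataset export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beadquant as bq
from beadquant.synthetic import read_yolo_annotations, write_yolo_annotations


class TestLayout:
    def test_pitch_is_pillar_diameter_plus_spacing(self):
        layout = bq.build_layout(50, 14, n_rows=2, n_cols=2)
        assert layout.trap_pitch == 64.0

    def test_single_site_per_zone(self):
        layout = bq.build_layout(50, 14, n_rows=1, n_cols=1)
        assert layout.n_sites == 2
        assert len(layout.trap_sites("test")) == 1
        assert len(layout.trap_sites("reference")) == 1

    def test_every_site_center_inside_its_zone_rect(self):
        layout = bq.build_layout(50, 14, n_rows=5, n_cols=8)
        assert layout.n_sites == 80
        for zone in ("test", "reference"):
            x0, y0, x1, y1 = layout.zone_rects[zone]
            sites = layout.trap_sites(zone)
            assert len(sites) == 40
            for x, y in sites:
                assert x0 <= x < x1 and y0 <= y < y1

    def test_zone_rects_are_disjoint(self):
        layout = bq.build_layout()
        tx0, _, tx1, _ = layout.zone_rects["test"]
        rx0, _, rx1, _ = layout.zone_rects["reference"]
        assert tx1 <= rx0 or rx1 <= tx0

    @pytest.mark.parametrize("bad", [
        dict(pillar_diameter=0), dict(pillar_spacing=-1), dict(n_rows=0),
        dict(zone_gap=0),
    ])
    def test_nonpositive_geometry_rejected(self, bad):
        with pytest.raises(bq.ValidationError):
            bq.build_layout(**bad)


class TestPlaceBeads:
    def test_deterministic_fill(self, layout):
        beads, escaped = bq.place_beads(layout, layout.n_sites, p_trap=1.0, seed=0)
        assert len(beads) == layout.n_sites
        assert escaped == 0
        sites = {(b.zone, b.site_index) for b in beads}
        assert len(sites) == layout.n_sites

    def test_zero_injected(self, layout):
        beads, escaped = bq.place_beads(layout, 0, p_trap=0.5, seed=0)
        assert beads == [] and escaped == 0

    def test_diversion_guarantees_trapping_and_geometric_first_site(self):
        """With sites to spare every bead eventually traps, and the first
        bead's landing site index follows a geometric law (mean 2, 1-based)."""
        layout = bq.build_layout(n_rows=10, n_cols=5)  # 100 sites
        first_sites = []
        for seed in range(2000):
            beads, escaped = bq.place_beads(layout, 10, p_trap=0.5, seed=seed)
            assert len(beads) == 10 and escaped == 0
            order = {("test", i): i for i in range(50)}
            order.update({("reference", i): 50 + i for i in range(50)})
            first = min(order[(b.zone, b.site_index)] for b in beads
                        if b.bead_id == 0)
            first_sites.append(first + 1)  # 1-based
        mean = np.mean(first_sites)
        se = np.std(first_sites, ddof=1) / np.sqrt(len(first_sites))
        assert abs(mean - 2.0) < 3 * se + 1e-9

    @given(
        n_injected=st.integers(0, 120),
        p_trap=st.floats(0, 1),
        doublet=st.floats(0, 0.5),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bead_conservation(self, n_injected, p_trap, doublet, seed):
        layout = bq.build_layout(n_rows=3, n_cols=4)
        beads, escaped = bq.place_beads(layout, n_injected, p_trap, doublet, seed)
        assert len(beads) + escaped == n_injected

    @given(p_trap=st.floats(0.1, 1), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_monodispersion_without_doublets(self, p_trap, seed):
        layout = bq.build_layout(n_rows=3, n_cols=4)
        beads, _ = bq.place_beads(layout, 30, p_trap, doublet_prob=0.0, seed=seed)
        sites = [(b.zone, b.site_index) for b in beads]
        assert len(sites) == len(set(sites))


class TestRendering:
    def test_empty_scene_is_constant_offset(self, layout):
        imaging = bq.ImagingConfig(psf_sigma=0.0)
        noise = bq.NoiseModel.noiseless(background_fl=100.0)
        fl, truths = bq.render_fluorescence(layout, [], imaging, noise,
                                            {"test": (0, 0)}, seed=0)
        assert truths == []
        assert np.all(fl.data == 100 + 1800)

    def test_single_bead_additive_construction(self, layout):
        """Noise off, no blur: in-mask pixels are exactly
        background + black level + true mean."""
        imaging = bq.ImagingConfig(psf_sigma=0.0, black_level=1800)
        noise = bq.NoiseModel.noiseless(background_fl=0.0)
        beads, _ = bq.place_beads(layout, 1, p_trap=1.0, seed=0, zone="test")
        fl, truths = bq.render_fluorescence(
            layout, beads, imaging, noise, {"test": (3000.0, 0.0)}, seed=0)
        (t,) = truths
        assert t.true_mean_fl == 3000.0
        cx, cy = t.center_px(imaging.pixel_size)
        r = imaging.bead_radius_px
        yy, xx = np.mgrid[0:fl.shape[0], 0:fl.shape[1]]
        mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
        assert np.all(fl.data[mask] == 4800)
        assert np.all(fl.data[~mask] == 1800)

    def test_noiseless_rendering_reproducible(self, layout, imaging, noiseless):
        beads, _ = bq.place_beads(layout, 10, p_trap=1.0, seed=3)
        means = {"test": (1500.0, 0.1), "reference": (3000.0, 0.1)}
        a = bq.render_pair(layout, beads, imaging, noiseless, means, seed=5)
        b = bq.render_pair(layout, beads, imaging, noiseless, means, seed=5)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_shot_noise_is_unbiased(self):
        """Over many noise draws the in-mask mean matches the noiseless value
        to within 3 standard errors."""
        layout = bq.build_layout(n_rows=1, n_cols=1)
        imaging = bq.ImagingConfig(psf_sigma=0.0)
        beads, _ = bq.place_beads(layout, 1, p_trap=1.0, seed=0, zone="test")
        noiseless = bq.NoiseModel.noiseless()
        fl0, truths = bq.render_fluorescence(
            layout, beads, imaging, noiseless, {"test": (3000.0, 0.0)}, seed=0)
        t = truths[0]
        x0, y0, x1, y1 = t.bbox
        cx, cy = t.center_px(imaging.pixel_size)
        r = imaging.bead_radius_px
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
        expected = float(fl0.data[y0:y1, x0:x1][mask].mean())

        shot = bq.NoiseModel.noiseless(shot_noise=True)
        means = []
        for seed in range(500):
            fl, _ = bq.render_fluorescence(
                layout, beads, imaging, shot, {"test": (3000.0, 0.0)}, seed=seed)
            means.append(float(fl.data[y0:y1, x0:x1][mask].mean()))
        mean = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean - expected) < 3 * se

    def test_bead_outside_frame_is_named(self, layout, noiseless):
        imaging = bq.ImagingConfig(image_shape=(50, 50))
        bead = bq.BeadTruth(7, (400.0, 400.0), 7.5, "test")
        with pytest.raises(bq.ValidationError, match="bead 7"):
            bq.render_fluorescence(layout, [bead], imaging, noiseless,
                                   {"test": (100.0, 0.0)}, seed=0)


class TestDilutionSeries:
    def test_noiseless_signals_are_exact(self):
        ds = bq.simulate_dilution_series([0, 10, 20], slope=2, intercept=100,
                                         noise_sd=0, n_reps=1, n_blanks=2, seed=0)
        assert np.array_equal(ds.signals, [100, 120, 140])
        assert np.array_equal(ds.blank_signals, [100, 100])
        assert float(np.std(ds.blank_signals, ddof=1)) == 0.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(bq.ValidationError):
            bq.simulate_dilution_series([0, 1], slope=0, intercept=0,
                                        noise_sd=1, seed=0)

    def test_fitted_slope_recovers_truth(self):
        ds = bq.simulate_dilution_series([5, 10, 20, 40, 80], slope=2,
                                         intercept=100, noise_sd=5,
                                         n_reps=50, n_blanks=5, seed=42)
        fit = bq.fit_calibration(ds)
        x = ds.concentrations
        resid_se = 5 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - 2.0) < 3 * resid_se


class TestExport:
    @pytest.fixture(scope="class")
    @staticmethod
    def scenes(layout, imaging, noiseless):
        out = []
        for seed in range(10):
            beads, _ = bq.place_beads(layout, 8, p_trap=1.0, seed=seed)
            out.append(bq.render_pair(layout, beads, imaging, noiseless,
                                      {"test": (1500.0, 0.1),
                                       "reference": (3000.0, 0.1)}, seed=seed))
        return out

    def test_split_sizes_7_2_1(self, scenes, tmp_path):
        manifest = bq.export_dataset(scenes, tmp_path, (7, 2, 1), seed=0)
        splits = manifest["splits"]
        assert [len(splits[k]) for k in ("train", "val", "test")] == [7, 2, 1]
        union = set().union(*(splits[k] for k in splits))
        assert union == set(manifest["images"])
        assert len(union) == sum(len(v) for v in splits.values())

    def test_exported_files_exist_and_read_back(self, scenes, tmp_path):
        import tifffile

        bq.export_dataset(scenes[:2], tmp_path, (1, 1), seed=0)
        bf = tifffile.imread(tmp_path / "scene_0000_bf.tif")
        assert bf.dtype == np.uint16
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "manifest.json").exists()

    def test_centered_bead_annotation_identity(self, tmp_path):
        """A centred bead box spanning half the image encodes as 0.5s."""
        truth = bq.BeadTruth(0, (0, 0), 7.5, "test", bbox=(25, 25, 75, 75))
        path = tmp_path / "ann.txt"
        write_yolo_annotations(path, [truth], (100, 100))
        line = path.read_text().strip()
        assert line == "0 0.5000000000 0.5000000000 0.5000000000 0.5000000000"

    def test_annotation_round_trip_is_pixel_exact(self, scenes, tmp_path):
        for i, (bf, _, truths) in enumerate(scenes):
            path = tmp_path / f"rt_{i}.txt"
            write_yolo_annotations(path, truths, bf.shape)
            boxes = read_yolo_annotations(path, bf.shape)
            assert boxes == [t.bbox for t in truths]
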