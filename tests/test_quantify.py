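"""Positional migration, zone assignment, and the RFR."""

import numpy as np
import pytest

import beadquant as bq
from beadquant.detect import Detection
from beadquant.quantify import ZoneSummary

from conftest import brute_force_circle_mean


def make_detection(cx, cy, radius):
    x0, y0 = int(np.floor(cx - radius)) - 1, int(np.floor(cy - radius)) - 1
    x1, y1 = int(np.ceil(cx + radius)) + 1, int(np.ceil(cy + radius)) + 1
    return Detection((cx, cy), radius, (x0, y0, x1, y1), 1.0)


class TestMigrateAndMeasure:
    def test_constant_image_gives_constant_means(self):
        img = np.full((100, 100), 1234, dtype=np.uint16)
        dets = [make_detection(30, 30, 10), make_detection(70, 60, 10)]
        for m in bq.migrate_and_measure(dets, img):
            assert m.mean_fl == 1234.0
            assert m.saturated_fraction == 0.0

    def test_noiseless_bead_with_black_level_subtraction(self, noiseless):
        layout = bq.build_layout(n_rows=1, n_cols=1)
        imaging = bq.ImagingConfig(psf_sigma=0.0, black_level=1800)
        beads, _ = bq.place_beads(layout, 1, p_trap=1.0, seed=0, zone="test")
        fl, truths = bq.render_fluorescence(
            layout, beads, imaging, noiseless, {"test": (3000.0, 0.0)}, seed=0)
        t = truths[0]
        cx, cy = t.center_px(imaging.pixel_size)
        det = make_detection(cx, cy, imaging.bead_radius_px)
        (m,) = bq.migrate_and_measure([det], fl, black_level_subtract=1800.0)
        assert m.mean_fl == 3000.0

    def test_matches_brute_force_pixel_loop(self):
        """Migrated means equal an independent per-pixel loop exactly on
        50 random circular regions."""
        rng = np.random.default_rng(9)
        img = rng.integers(0, 4000, (120, 160)).astype(np.uint16)
        for _ in range(50):
            cx = float(rng.uniform(20, 140))
            cy = float(rng.uniform(20, 100))
            r = float(rng.uniform(3, 12))
            det = make_detection(cx, cy, r)
            (m,) = bq.migrate_and_measure([det], img)
            expected, n = brute_force_circle_mean(img, cx, cy, r)
            assert m.n_pixels == n
            assert m.mean_fl == expected

    def test_full_box_rule_uses_every_box_pixel(self):
        img = np.arange(100, dtype=np.uint16).reshape(10, 10)
        det = Detection((5, 5), 2, (2, 2, 8, 8), 1.0)
        (m,) = bq.migrate_and_measure([det], img, mask_rule="full_box")
        assert m.mean_fl == float(img[2:8, 2:8].mean())
        assert m.n_pixels == 36

    def test_saturation_is_reported(self):
        img = np.full((40, 40), 65535, dtype=np.uint16)
        (m,) = bq.migrate_and_measure([make_detection(20, 20, 5)], img)
        assert m.saturated_fraction == 1.0

    def test_shape_mismatch_rejected(self):
        img = np.zeros((50, 50), dtype=np.uint16)
        with pytest.raises(bq.ValidationError):
            bq.migrate_and_measure([make_detection(20, 20, 5)], img,
                                   bf_shape=(60, 60))

    def test_empty_mask_rejected(self):
        img = np.zeros((50, 50), dtype=np.uint16)
        det = Detection((20.0, 20.0), 0.2, (18, 18, 22, 22), 1.0)
        with pytest.raises(bq.ValidationError):
            bq.migrate_and_measure([det], img)


class TestAssignZones:
    def _measurement(self, cx, cy):
        return bq.BeadMeasurement(0, (cx, cy), 15.0, "unassigned", 1.0, 10, 0.0)

    def test_center_inside_test_rect(self, layout, imaging):
        x0, y0, _, _ = layout.zone_rects["test"]
        m = self._measurement((x0 + 10) / 0.5, (y0 + 10) / 0.5)
        (out,) = bq.assign_zones([m], layout, imaging.pixel_size)
        assert out.zone == "test"

    def test_center_outside_both_rects(self, layout, imaging):
        (out,) = bq.assign_zones([self._measurement(1.0, 1.0)], layout,
                                 imaging.pixel_size)
        assert out.zone == "unassigned"

    def test_half_open_membership_matches_point_oracle(self, layout, imaging):
        """Min edges belong to the rect, max edges do not; checked on a grid
        of exact boundary points against an inline point-in-rect oracle."""
        ps = imaging.pixel_size
        rects_px = {z: tuple(v / ps for v in r)
                    for z, r in layout.zone_rects.items()}

        def oracle(cx, cy):
            for z, (x0, y0, x1, y1) in rects_px.items():
                if x0 <= cx < x1 and y0 <= cy < y1:
                    return z
            return "unassigned"

        probe = []
        for x0, y0, x1, y1 in rects_px.values():
            xs = [x0, x1, (x0 + x1) / 2, x0 - 0.5, x1 - 0.5]
            ys = [y0, y1, (y0 + y1) / 2, y0 - 0.5, y1 - 0.5]
            probe.extend((cx, cy) for cx in xs for cy in ys)
        ms = [self._measurement(cx, cy) for cx, cy in probe]
        out = bq.assign_zones(ms, layout, ps)
        for (cx, cy), m in zip(probe, out):
            assert m.zone == oracle(cx, cy), (cx, cy)


class TestZoneSummaryAndRFR:
    def _measurements(self, values, zone="test"):
        return [bq.BeadMeasurement(i, (0, 0), 15, zone, v, 10, 0.0)
                for i, v in enumerate(values)]

    def test_hand_arithmetic(self):
        s = bq.summarize_zone(self._measurements([10, 20, 30]), "test")
        assert s.V == 20.0
        assert s.sd == pytest.approx(10.0)
        assert s.n_beads == 3

    def test_single_bead_has_no_sd(self):
        s = bq.summarize_zone(self._measurements([42]), "test")
        assert (s.V, s.sd) == (42.0, None)

    def test_empty_zone_is_invalid_run(self):
        with pytest.raises(bq.EmptyZoneError):
            bq.summarize_zone(self._measurements([1], zone="reference"), "test")

    def test_rfr_half(self):
        r = bq.compute_rfr(ZoneSummary("test", 50.0, None, 1),
                           ZoneSummary("reference", 100.0, None, 1))
        assert r.rfr == 50.0

    def test_self_ratio_is_exactly_100(self):
        s = ZoneSummary("test", 1234.567, 1.0, 7)
        assert bq.compute_rfr(s, s).rfr == 100.0

    def test_failed_reference_is_invalid_run(self):
        with pytest.raises(bq.InvalidRunError):
            bq.compute_rfr(ZoneSummary("test", 10.0, None, 1),
                           ZoneSummary("reference", 0.0, None, 1))

    def test_rendered_ratio_recovered_without_noise(self, layout, imaging,
                                                    noiseless, default_params):
        """Zone intensity means in ratio r give RFR = 100r% on a noiseless
        scene (blur cancels between zones; offsets subtracted)."""
        beads, _ = bq.place_beads(layout, layout.n_sites, p_trap=1.0, seed=21)
        bf, fl, truths = bq.render_pair(
            layout, beads, imaging, noiseless,
            {"test": (1200.0, 0.0), "reference": (3000.0, 0.0)}, seed=21)
        dets = bq.detect_beads(bf, default_params)
        ms = bq.migrate_and_measure(dets, fl,
                                    black_level_subtract=imaging.black_level)
        ms = bq.assign_zones(ms, layout, imaging.pixel_size)
        r = bq.compute_rfr(bq.summarize_zone(ms, "test"),
                           bq.summarize_zone(ms, "reference"))
        assert r.rfr == pytest.approx(100 * 1200 / 3000, rel=5e-3)

    def test_scale_equivariance(self):
        """Scaling all above-offset intensities by c leaves the RFR unchanged."""
        rng = np.random.default_rng(5)
        test_vals = rng.uniform(500, 1500, 10)
        ref_vals = rng.uniform(2000, 3000, 10)

        def rfr(scale):
            t = bq.summarize_zone(self._measurements(scale * test_vals), "test")
            r = bq.summarize_zone(
                self._measurements(scale * ref_vals, zone="reference"),
                "reference")
            return bq.compute_rfr(t, r).rfr

        assert rfr(3.7) == pytest.approx(rfr(1.0), rel=1e-12)
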