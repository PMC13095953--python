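"""Detect beads in a bright-field micrograph and score against ground truth.

The reference detector correlates the image with a disk template of the
bead radius, rejects candidates whose radial-gradient radius estimate does
not match (this removes the 50 µm pillars), and suppresses duplicate peaks.
"""

import beadquant as bq

layout = bq.build_layout()
imaging = bq.ImagingConfig()  # 0.5 µm/px -> a 15 µm bead is 15 px in radius

beads, _ = bq.place_beads(layout, layout.n_sites, p_trap=1.0, seed=42)
bf, fl, truths = bq.render_pair(
    layout, beads, imaging, bq.NoiseModel.noiseless(),
    {"test": (1500.0, 0.1), "reference": (3000.0, 0.1)}, seed=42,
)

params = bq.DetectorParams(expected_radius=imaging.bead_radius_px)
detections = bq.detect_beads(bf, params)
metrics = bq.match_and_score(detections, truths, iou_cutoff=0.5)

print(f"{len(truths)} beads in scene, {len(detections)} detected")
print(f"confidence range: {min(d.confidence for d in detections):.3f}"
      f" - {max(d.confidence for d in detections):.3f}")
print(f"TP={metrics.tp} FP={metrics.fp} FN={metrics.fn} "
      f"precision={metrics.precision:.3f} recall={metrics.recall:.3f} "
      f"accuracy={metrics.accuracy:.3f}")
# accuracy = TP/(TP+FP+FN): 1.000 means every bead was found, no pillar or
# background patch was mistaken for a bead.
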