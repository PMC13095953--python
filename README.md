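# beadquant

Automated, self-validated quantification of microbead immunoassay
micrographs.

In bead-based assays for extracellular-vesicle surface markers (e.g.
PD-L1, ERBB3), 15 µm capture beads are trapped one-per-site in a
micropillar array (50 µm pillars, 14 µm spacing) on a microfluidic chip
and imaged twice: a bright-field micrograph in which every bead is
visible, and a fluorescence micrograph in which only the immunolabel
signal appears.  The chip carries two zones processed identically in
parallel — a *test* zone with the sample and a *positive-reference*
zone with a control of consistently high expression — so the readout can
be normalised on-chip.  `beadquant` implements the full analysis:

1. **Detection** — beads are located in the bright-field image by a
   deterministic matched-filter detector (normalised cross-correlation
   with a disk template, radius-based rejection of pillars, greedy
   non-maximum suppression).  Any learned detector can be plugged in
   behind the same `image in -> detections out` contract.
2. **Positional migration** — each detected boundary is transferred to
   the paired fluorescence image and the mean grayscale intensity is
   computed inside the circular bead region.
3. **Self-validated ratio** — per-bead means are averaged per zone
   (V_MDF for the test zone, V_MPF for the positive reference) and
   reported as the Relative Fluorescence Ratio

   ```
   RFR = V_MDF / V_MPF × 100%
   ```

   A failed reference (no beads, non-positive mean) voids the run
   instead of producing a number.
4. **Evaluation, calibration and QC** — IoU matching with
   precision/recall/F1 and accuracy = TP/(TP+FP+FN), 7:2:1 dataset
   splitting, dilution-series linear fits with R², the blank + 3σ limit
   of detection, and bead-retention efficiency.
5. **Synthetic scenes** — a simulator renders paired micrographs of the
   trap array (sequential self-regulated bead loading, per-zone
   intensity distributions, PSF blur, shot/read noise, constant camera
   black level of 1800 on the 16-bit scale) with full ground truth, so
   every stage is testable without instrument data.

## Worked example

```python
import beadquant as bq

config = bq.AssayConfig(
    markers=[
        bq.MarkerConfig("PD-L1", test_mean=1500.0, reference_mean=3000.0, cv=0.1),
        bq.MarkerConfig("ERBB3", test_mean=2400.0, reference_mean=3000.0, cv=0.1),
    ],
    black_level_subtract="auto",
    seed=7,
)
report = bq.run_selfvalidated_assay(config)
```

which prints (see `examples/03_selfvalidated_rfr.py`):

```
PD-L1: RFR = 48.5%  (V_MDF = 1444, V_MPF = 2976, n = 20/20 beads)
ERBB3: RFR = 76.8%  (V_MDF = 2182, V_MPF = 2839, n = 20/20 beads)
detection accuracy: 1.000, bead retention: 66.7%
```

PD-L1 was simulated at half the reference zone's true intensity and
ERBB3 at 80%, so the reported ratios scatter around 50% and 80%; all 40
beads were detected (accuracy 1.000 means no false positives or
misses), and the retention figure reflects that 60 beads were injected
into 40 trap sites.  The `examples/` directory holds one short script
per capability (simulation/export, detection/evaluation, the RFR assay,
calibration/LOD), each printing the numbers it computes.

A thin CLI mirrors the stages:

```sh
beadquant simulate --out data/ --seed 1 --split 7:2:1
beadquant detect --image bf.tif --expected-radius 15 --out det.csv
beadquant quantify --bf bf.tif --fl fl.tif --detections det.csv \
    --layout chip.yaml --marker PD-L1
beadquant calibrate --series series.csv --k-sigma 3
beadquant run --config assay.yaml
```

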