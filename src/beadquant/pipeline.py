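"""Sample-in, answer-out orchestration of the self-validated assay.

One call (or one ``beadquant run``) takes a configuration describing the
chip, the camera, and the markers to read out; detects beads once in the
bright-field channel; migrates the boundaries onto every marker's
fluorescence image; summarises the test and positive-reference zones;
and reports one Relative Fluorescence Ratio per marker.  A failed
positive reference (no beads, or non-positive mean) voids the run with
an ``invalid-run`` error instead of reporting a number — that is the
self-validation contract.

Micrograph pairs can be simulated (full ground truth, detection metrics
and retention QC included in the report) or loaded from disk, either as
one pair covering both zones or as one pair per zone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .calibrate import QCMetrics, retention_efficiency
from .detect import DetectorParams, detect_beads
from .errors import ValidationError
from .evaluate import DetectionMetrics, match_and_score
from .io import measurements_to_frame, read_micrograph
from .quantify import (RFRResult, ZoneSummary, assign_zones, compute_rfr,
                       migrate_and_measure, summarize_zone)
from .synthetic import (ChipLayout, ImagingConfig, NoiseModel, place_beads,
                        render_brightfield, render_fluorescence)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerConfig:
    """One fluorescence readout channel (e.g. PD-L1 or ERBB3).

    Simulated mode draws per-bead intensities from zone-specific
    lognormals with means ``test_mean`` / ``reference_mean`` and
    coefficient of variation ``cv``.  Image mode instead points at
    micrograph files: either one bright-field/fluorescence pair covering
    both zones, or a separate pair per zone.
    """

    name: str
    test_mean: float | None = None
    reference_mean: float | None = None
    cv: float = 0.1
    bf_image: str | None = None
    fl_image: str | None = None
    zone_images: Mapping[str, Mapping[str, str]] | None = None  # zone -> {bf, fl}


@dataclass
class AssayConfig:
    """Everything one self-validated run needs, with simulation defaults."""

    markers: list[MarkerConfig]
    layout: ChipLayout = field(default_factory=ChipLayout)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    detector: DetectorParams | None = None  # default: radius from imaging
    mask_rule: str = "inscribed_circle"
    black_level_subtract: float | str | None = None  # grayscale units or "auto"
    simulated: bool = True
    n_injected_per_zone: int = 30
    p_trap: float = 0.8
    doublet_prob: float = 0.0
    seed: int | None = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("config must declare at least one marker")
        if self.simulated and self.seed is None:
            raise ValidationError("simulated mode requires a seed")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError("marker names must be unique")

    @property
    def detector_params(self) -> DetectorParams:
        if self.detector is not None:
            return self.detector
        return DetectorParams(expected_radius=self.imaging.bead_radius_px)

    def subtract_value(self) -> float:
        """Resolve the black-level handling flag to a grayscale offset."""
        if self.black_level_subtract in (None, 0, 0.0, False):
            return 0.0
        if self.black_level_subtract == "auto":
            return self.imaging.black_level + self.noise.background_fl
        return float(self.black_level_subtract)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AssayConfig":
        raw = dict(raw)
        markers = [
            m if isinstance(m, MarkerConfig) else MarkerConfig(**m)
            for m in raw.pop("markers", [])
        ]
        kwargs = {}
        for key, typ in (("layout", ChipLayout), ("imaging", ImagingConfig),
                         ("noise", NoiseModel), ("detector", DetectorParams)):
            if key in raw:
                val = raw.pop(key)
                if isinstance(val, Mapping):
                    val = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in val.items()}
                    val = typ(**val)
                kwargs[key] = val
        kwargs.update(raw)
        return cls(markers=markers, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class MarkerReport:
    rfr: RFRResult
    test_summary: ZoneSummary
    reference_summary: ZoneSummary
    n_unassigned: int = 0


@dataclass
class AssayReport:
    """The validated output of one run: per-marker RFRs plus metadata."""

    markers: dict[str, MarkerReport]
    detection_metrics: DetectionMetrics | None
    qc: QCMetrics | None
    seed: int | None
    config_hash: str
    version: str = __version__

    def to_dict(self) -> dict:
        out = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "markers": {},
            "detection_metrics": (
                dataclasses.asdict(self.detection_metrics)
                if self.detection_metrics else None
            ),
            "qc": dataclasses.asdict(self.qc) if self.qc else None,
        }
        for name, rep in self.markers.items():
            out["markers"][name] = {
                "rfr": dataclasses.asdict(rep.rfr),
                "test": dataclasses.asdict(rep.test_summary),
                "reference": dataclasses.asdict(rep.reference_summary),
                "n_unassigned": rep.n_unassigned,
            }
        return out

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AssayReport":
        markers = {
            name: MarkerReport(
                rfr=RFRResult(**m["rfr"]),
                test_summary=ZoneSummary(**m["test"]),
                reference_summary=ZoneSummary(**m["reference"]),
                n_unassigned=m.get("n_unassigned", 0),
            )
            for name, m in raw["markers"].items()
        }
        dm = raw.get("detection_metrics")
        qc = raw.get("qc")
        return cls(
            markers=markers,
            detection_metrics=DetectionMetrics(**dm) if dm else None,
            qc=QCMetrics(**qc) if qc else None,
            seed=raw.get("seed"),
            config_hash=raw.get("config_hash", ""),
            version=raw.get("version", __version__),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssayReport":
        return cls.from_dict(json.loads(text))


def _measure_marker(detections, fl, config: AssayConfig, bf_shape,
                    zone: str | None = None):
    measurements = migrate_and_measure(
        detections, fl,
        mask_rule=config.mask_rule,
        black_level_subtract=config.subtract_value(),
        bf_shape=bf_shape,
    )
    if zone is None:
        return assign_zones(measurements, config.layout, config.imaging.pixel_size)
    return [dataclasses.replace(m, zone=zone) for m in measurements]


def _run_simulated(config: AssayConfig) -> tuple[AssayReport, dict]:
    ss = np.random.SeedSequence(config.seed)
    seed_place_t, seed_place_r, seed_bf, seed_markers = ss.spawn(4)
    beads_t, esc_t = place_beads(
        config.layout, config.n_injected_per_zone, config.p_trap,
        config.doublet_prob, np.random.default_rng(seed_place_t), zone="test",
    )
    beads_r, esc_r = place_beads(
        config.layout, config.n_injected_per_zone, config.p_trap,
        config.doublet_prob, np.random.default_rng(seed_place_r), zone="reference",
    )
    beads = [dataclasses.replace(b, bead_id=i)
             for i, b in enumerate(beads_t + beads_r)]
    logger.info("placed %d beads (%d escaped)", len(beads), esc_t + esc_r)

    bf = render_brightfield(config.layout, beads, config.imaging, config.noise,
                            np.random.default_rng(seed_bf))
    detections = detect_beads(bf, config.detector_params)
    logger.info("detected %d beads in bright-field", len(detections))

    marker_reports: dict[str, MarkerReport] = {}
    measurement_frames: dict[str, object] = {}
    truths = None
    for marker, child in zip(config.markers,
                             seed_markers.spawn(len(config.markers))):
        if marker.test_mean is None or marker.reference_mean is None:
            raise ValidationError(
                f"marker {marker.name!r} lacks simulated zone intensities"
            )
        fl, marker_truths = render_fluorescence(
            config.layout, beads, config.imaging, config.noise,
            {"test": (marker.test_mean, marker.cv),
             "reference": (marker.reference_mean, marker.cv)},
            np.random.default_rng(child), channel=marker.name,
        )
        truths = truths or marker_truths
        assigned = _measure_marker(detections, fl, config, bf.shape)
        n_unassigned = sum(m.zone == "unassigned" for m in assigned)
        test_summary = summarize_zone(assigned, "test")
        ref_summary = summarize_zone(assigned, "reference")
        marker_reports[marker.name] = MarkerReport(
            rfr=compute_rfr(test_summary, ref_summary, marker.name),
            test_summary=test_summary,
            reference_summary=ref_summary,
            n_unassigned=n_unassigned,
        )
        measurement_frames[marker.name] = measurements_to_frame(assigned)

    metrics = match_and_score(detections, truths) if truths else None
    n_total = 2 * config.n_injected_per_zone
    qc = retention_efficiency(len(beads), n_total) if n_total else None
    report = AssayReport(
        markers=marker_reports,
        detection_metrics=metrics,
        qc=qc,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    return report, measurement_frames


def _run_from_images(config: AssayConfig) -> tuple[AssayReport, dict]:
    detection_cache: dict[str, list] = {}

    def detect_cached(path: str):
        if path not in detection_cache:
            bf = read_micrograph(path, config.imaging.pixel_size)
            detection_cache[path] = (detect_beads(bf, config.detector_params),
                                     bf.shape)
        return detection_cache[path]

    marker_reports: dict[str, MarkerReport] = {}
    measurement_frames: dict[str, object] = {}
    for marker in config.markers:
        if marker.zone_images:  # one micrograph pair per zone
            assigned = []
            for zone, pair in marker.zone_images.items():
                dets, bf_shape = detect_cached(pair["bf"])
                fl = read_micrograph(pair["fl"], config.imaging.pixel_size,
                                     channel=marker.name)
                assigned.extend(
                    _measure_marker(dets, fl, config, bf_shape, zone=zone)
                )
        elif marker.bf_image and marker.fl_image:  # both zones in one pair
            dets, bf_shape = detect_cached(marker.bf_image)
            fl = read_micrograph(marker.fl_image, config.imaging.pixel_size,
                                 channel=marker.name)
            assigned = _measure_marker(dets, fl, config, bf_shape)
        else:
            raise ValidationError(f"marker {marker.name!r} names no images")
        n_unassigned = sum(m.zone == "unassigned" for m in assigned)
        test_summary = summarize_zone(assigned, "test")
        ref_summary = summarize_zone(assigned, "reference")
        marker_reports[marker.name] = MarkerReport(
            rfr=compute_rfr(test_summary, ref_summary, marker.name),
            test_summary=test_summary,
            reference_summary=ref_summary,
            n_unassigned=n_unassigned,
        )
        measurement_frames[marker.name] = measurements_to_frame(assigned)
    report = AssayReport(
        markers=marker_reports, detection_metrics=None, qc=None,
        seed=config.seed, config_hash=config.config_hash(),
    )
    return report, measurement_frames


def run_selfvalidated_assay(config: AssayConfig) -> AssayReport:
    """Execute detect -> migrate -> assign -> summarise -> RFR per marker.

    Both zones pass through identical parameters; the bright-field
    detection is performed once and reused across markers.  When
    ``config.out_dir`` is set, the report (JSON) and per-marker
    measurement CSVs are written there.
    """
    if config.simulated:
        report, frames = _run_simulated(config)
    else:
        report, frames = _run_from_images(config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        for name, frame in frames.items():
            frame.to_csv(out / f"measurements_{name}.csv", index=False)
    return report
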