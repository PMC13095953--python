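"""Positional migration and self-validated ratio quantification.

Bead boundaries found in the bright-field image are transferred
("migrated") onto the paired fluorescence image, where each bead's mean
grayscale intensity is read out inside its circular region.  Beads are
segregated into the chip's test and positive-reference zones; each
zone's value V is the average of its per-bead means (V_MDF for the test
zone, V_MPF for the positive reference), and the final readout is the
Relative Fluorescence Ratio

    RFR = V_MDF / V_MPF x 100%,

so any systematic factor common to both parallel zones — illumination,
exposure, reagent batch — cancels in the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .detect import Detection
from .errors import EmptyZoneError, InvalidRunError, ValidationError
from .synthetic import ChipLayout, Micrograph

logger = logging.getLogger(__name__)

MASK_RULES = ("inscribed_circle", "full_box")


@dataclass(frozen=True)
class BeadMeasurement:
    """One bead's migrated fluorescence readout (pixel coordinates)."""

    bead_id: int
    center: tuple[float, float]
    radius: float
    zone: str  # "test" | "reference" | "unassigned"
    mean_fl: float
    n_pixels: int
    saturated_fraction: float


@dataclass(frozen=True)
class ZoneSummary:
    """Per-zone average of per-bead mean intensities.

    ``V`` is V_MDF for the test zone and V_MPF for the reference zone;
    ``sd`` is the sample standard deviation (n-1), absent for n = 1.
    """

    zone: str
    V: float
    sd: float | None
    n_beads: int


@dataclass(frozen=True)
class RFRResult:
    """The self-validated Relative Fluorescence Ratio for one marker."""

    marker: str
    rfr: float  # percent
    v_mdf: float
    v_mpf: float
    n_test: int
    n_ref: int


def _image_data(image) -> tuple[np.ndarray, float | None]:
    if isinstance(image, Micrograph):
        return image.data, float(image.max_value)
    data = np.asarray(image)
    if np.issubdtype(data.dtype, np.integer):
        return data, float(np.iinfo(data.dtype).max)
    return data, None


def migrate_and_measure(
    detections: Sequence[Detection],
    fl_image,
    mask_rule: str = "inscribed_circle",
    black_level_subtract: float = 0.0,
    bf_shape: tuple[int, int] | None = None,
) -> list[BeadMeasurement]:
    """Transfer detected boundaries to the fluorescence image and measure.

    For each detection the pixel set is either the inscribed circle
    (pixels whose centres lie within ``radius`` of the detection centre;
    the default, matching readout "within the same circular region") or
    the full bounding box.  ``mean_fl`` is the arithmetic mean of those
    pixels minus ``black_level_subtract`` (0 disables the camera-offset
    correction); ``saturated_fraction`` is the fraction of mask pixels at
    the bit-depth maximum.  ``bf_shape``, when given, asserts that the
    fluorescence frame matches the bright-field frame the detections
    came from.
    """
    if mask_rule not in MASK_RULES:
        raise ValidationError(f"mask_rule must be one of {MASK_RULES}")
    data, max_value = _image_data(fl_image)
    if data.ndim != 2:
        raise ValidationError("fluorescence image must be single-channel 2-D")
    if bf_shape is not None and tuple(bf_shape) != data.shape:
        raise ValidationError(
            f"fluorescence shape {data.shape} != bright-field shape {tuple(bf_shape)}"
        )
    h, w = data.shape
    out: list[BeadMeasurement] = []
    for i, det in enumerate(detections):
        x0, y0, x1, y1 = (int(v) for v in det.bbox)
        x0c, y0c = max(x0, 0), max(y0, 0)
        x1c, y1c = min(x1, w), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            raise ValidationError(f"detection {i} lies outside the fluorescence frame")
        patch = data[y0c:y1c, x0c:x1c]
        if mask_rule == "inscribed_circle":
            cx, cy = det.center
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= det.radius**2
            if not mask.any():
                raise ValidationError(
                    f"detection {i}: circular mask is empty (radius {det.radius})"
                )
            pixels = patch[mask]
        else:
            pixels = patch.ravel()
        mean_fl = float(pixels.mean(dtype=float)) - black_level_subtract
        saturated = float(np.mean(pixels == max_value)) if max_value is not None else 0.0
        out.append(
            BeadMeasurement(
                bead_id=i,
                center=det.center,
                radius=det.radius,
                zone="unassigned",
                mean_fl=mean_fl,
                n_pixels=int(pixels.size),
                saturated_fraction=saturated,
            )
        )
    return out


def assign_zones(
    measurements: Sequence[BeadMeasurement],
    layout: ChipLayout,
    pixel_size: float,
) -> list[BeadMeasurement]:
    """Label each bead with the zone whose rectangle contains its centre.

    Zone rectangles are half-open (min edge inclusive, max edge
    exclusive) after µm -> pixel conversion, so the zones tile without
    double counting.  Centres in neither rectangle are labelled
    "unassigned", logged, and excluded from zone summaries downstream.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    rects_px = {
        zone: tuple(v / pixel_size for v in rect)
        for zone, rect in layout.zone_rects.items()
    }
    out = []
    n_unassigned = 0
    for m in measurements:
        cx, cy = m.center
        zone = "unassigned"
        for label, (x0, y0, x1, y1) in rects_px.items():
            if x0 <= cx < x1 and y0 <= cy < y1:
                zone = label
                break
        if zone == "unassigned":
            n_unassigned += 1
        out.append(replace(m, zone=zone))
    if n_unassigned:
        logger.warning(
            "%d of %d beads fall outside both zones and are excluded",
            n_unassigned, len(measurements),
        )
    return out


def summarize_zone(measurements: Sequence[BeadMeasurement], zone: str) -> ZoneSummary:
    """Average the per-bead mean intensities of one zone.

    An empty zone is an invalid run: with no reference (or test) beads
    the self-validated ratio cannot be formed.
    """
    values = np.array([m.mean_fl for m in measurements if m.zone == zone], dtype=float)
    if values.size == 0:
        raise EmptyZoneError(f"zone {zone!r} contains no beads; run is invalid")
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return ZoneSummary(zone=zone, V=float(values.mean()), sd=sd, n_beads=int(values.size))


def compute_rfr(test_summary: ZoneSummary, reference_summary: ZoneSummary,
                marker: str = "marker") -> RFRResult:
    """Relative Fluorescence Ratio: 100 x V_MDF / V_MPF (percent).

    A non-positive reference value means the on-chip positive control
    failed, which voids the run rather than yielding a ratio.
    """
    v_mdf, v_mpf = test_summary.V, reference_summary.V
    if v_mpf <= 0:
        raise InvalidRunError(
            f"positive reference failed (V_MPF = {v_mpf}); run is invalid"
        )
    return RFRResult(
        marker=marker,
        rfr=100.0 * (v_mdf / v_mpf),  # ratio first, so a self-ratio is exactly 100
        v_mdf=v_mdf,
        v_mpf=v_mpf,
        n_test=test_summary.n_beads,
        n_ref=reference_summary.n_beads,
    )
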