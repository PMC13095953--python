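"""Microbead detection in bright-field micrographs.

The trapped beads are rigid spheres of strictly uniform size imaged under
constant illumination, so a classical matched filter suffices as a
reference detector: normalised cross-correlation against a disk template
locates candidate centres, a radial-gradient radius estimate rejects
objects of the wrong size (notably the 50 µm pillars, whose edges can
partially match a small disk), and greedy non-maximum suppression removes
duplicate peaks.  Any learned detector (e.g. a YOLO model) can stand in
for the reference algorithm by satisfying the same one-call contract,
``image in -> list of Detection out`` (:class:`Detector`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .boxes import iou
from .errors import ValidationError
from .synthetic import Micrograph


@dataclass(frozen=True)
class Detection:
    """A located bead candidate: centre/radius in pixels, half-open bbox,
    and a confidence score in [0, 1] (here, the template-match score)."""

    center: tuple[float, float]
    radius: float
    bbox: tuple[int, int, int, int]
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class DetectorParams:
    """Reference-detector tuning.

    ``expected_radius`` is the bead radius in pixels (15 µm bead at
    0.5 µm/px -> 15 px).  Candidates whose radial-gradient radius
    estimate deviates from it by more than ``radius_tolerance`` (as a
    fraction) are rejected.  ``polarity`` states whether beads appear
    dark or bright against the background.
    """

    expected_radius: float
    match_threshold: float = 0.6
    nms_iou: float = 0.5
    radius_tolerance: float = 0.3
    polarity: str = "dark"
    box_margin: int = 1

    def __post_init__(self) -> None:
        if self.expected_radius <= 0:
            raise ValidationError("expected_radius must be positive")
        for name in ("match_threshold", "nms_iou", "radius_tolerance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.polarity not in ("dark", "bright"):
            raise ValidationError("polarity must be 'dark' or 'bright'")


@runtime_checkable
class Detector(Protocol):
    """Pluggable detector contract: bright-field image in, detections out."""

    def __call__(self, bf_image, params: DetectorParams) -> list[Detection]: ...


def _as_array(image) -> np.ndarray:
    data = image.data if isinstance(image, Micrograph) else np.asarray(image)
    if data.ndim != 2:
        raise ValidationError("detector requires a single-channel 2-D image")
    return data.astype(float)


def _disk_template(radius: float, margin: int = 2) -> np.ndarray:
    side = int(np.ceil(2 * radius)) + 2 * margin
    c = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    return ((xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 <= radius**2).astype(float)


def _radial_profile(img: np.ndarray, cx: float, cy: float, r_max: int,
                    n_angles: int = 48) -> np.ndarray:
    """Mean intensity on circles of radius 0..r_max around (cx, cy)."""
    radii = np.arange(0, r_max + 1, dtype=float)
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    # sample coordinates are (row, col); pixel centres at integer indices here
    rr = radii[:, None]
    rows = cy + rr * np.sin(angles)[None, :]
    cols = cx + rr * np.cos(angles)[None, :]
    samples = ndimage.map_coordinates(img, [rows.ravel(), cols.ravel()],
                                      order=1, mode="nearest")
    return samples.reshape(len(radii), n_angles).mean(axis=1)


def estimate_radius(img: np.ndarray, cx: float, cy: float, r_max: int) -> float:
    """Estimate an object's radius as the radial-gradient peak location.

    For a disk the angle-averaged profile steps at the rim, so the
    absolute radial derivative peaks at the radius.  Flat surroundings
    (e.g. the interior of a much larger pillar) give a near-zero gradient
    everywhere and hence an uninformative small estimate.
    """
    profile = _radial_profile(img, cx, cy, r_max)
    grad = np.abs(np.diff(profile))
    if grad.max() <= 0:
        return 0.0
    return float(np.argmax(grad)) + 0.5


def non_max_suppression(detections: Sequence[Detection], nms_iou: float = 0.5
                        ) -> list[Detection]:
    """Greedy NMS: keep the best remaining detection, drop overlaps.

    Detections are ordered by descending confidence with a deterministic
    tie-break (smaller y, then smaller x); each kept detection suppresses
    all later ones overlapping it with IoU >= ``nms_iou``.
    """
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, d.center[1], d.center[0])
    )
    kept: list[Detection] = []
    for det in ordered:
        if all(iou(det.bbox, k.bbox) < nms_iou for k in kept):
            kept.append(det)
    return kept


def detect_beads(bf_image, params: DetectorParams) -> list[Detection]:
    """Detect beads in a bright-field image with the reference detector.

    Pipeline: normalised cross-correlation with a disk template of
    ``expected_radius`` (polarity-adjusted so beads score positively);
    local maxima above ``match_threshold`` become candidates scored by
    their correlation; candidates whose estimated radius deviates from
    the expected one by more than ``radius_tolerance`` are rejected;
    survivors pass through greedy non-maximum suppression.  The result
    is sorted by descending confidence and fully deterministic.
    """
    img = _as_array(bf_image)
    r = params.expected_radius
    if 2 * r >= min(img.shape):
        raise ValidationError("expected_radius is too large for this image")

    template = _disk_template(r)
    score = match_template(img, template, pad_input=True, mode="edge")
    if params.polarity == "dark":
        score = -score

    peaks = peak_local_max(
        score,
        min_distance=max(1, int(round(r))),
        threshold_abs=params.match_threshold,
        exclude_border=False,
    )

    r_max = int(np.ceil(2 * r))
    side = 2 * (int(np.ceil(r)) + params.box_margin)
    detections: list[Detection] = []
    for row, col in peaks:
        est = estimate_radius(img, float(col), float(row), r_max)
        if abs(est - r) > params.radius_tolerance * r:
            continue
        cx, cy = col + 0.5, row + 0.5
        x0 = int(round(cx - side / 2))
        y0 = int(round(cy - side / 2))
        detections.append(
            Detection(
                center=(cx, cy),
                radius=r,
                bbox=(x0, y0, x0 + side, y0 + side),
                confidence=float(np.clip(score[row, col], 0.0, 1.0)),
            )
        )
    return non_max_suppression(detections, params.nms_iou)
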