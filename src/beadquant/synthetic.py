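"""Synthetic micrograph scenes for a micropillar bead-trap chip.

The simulator emulates the imaging side of a self-validated microbead
immunoassay: 15 µm beads trapped monodispersed in a micropillar array
(50 µm pillars, 14 µm inter-pillar spacing, so one trap per 64 µm of
pitch), imaged as a paired bright-field / fluorescence micrograph.  The
chip carries two zones — a "test" zone and an on-chip "reference" zone
loaded with a positive control — and every bead carries a known ground
truth, so detection, positional migration and ratio quantification can
all be scored without instrument data.

Geometry is an idealised rectangular trap lattice; bead loading follows
the chip's self-regulated sequential trapping (an occupied trap raises
local hydraulic resistance and diverts the next bead laterally to the
next empty trap).  Optics are a flat background plus per-object disks,
Gaussian blur, optional Poisson shot noise, Gaussian read noise, and a
constant camera black level added to the fluorescence channel.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .boxes import circle_bbox
from .errors import ValidationError

ZONES = ("test", "reference")

# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class ChipLayout:
    """Trap-site lattice and zone rectangles of the micropillar chip.

    Lengths are physical micrometres; the layout lives in the same
    top-left-origin frame as the micrographs.  ``trap_pitch`` (pillar
    diameter + inter-pillar spacing) is the lattice constant: trap sites
    sit at cell centres, pillars at cell corners.  The two zones are
    side-by-side rectangles separated by ``zone_gap``.
    """

    pillar_diameter: float = 50.0
    pillar_spacing: float = 14.0
    n_rows: int = 4
    n_cols: int = 5
    zone_gap: float = 64.0
    origin: tuple[float, float] = (32.0, 32.0)

    def __post_init__(self) -> None:
        if self.pillar_diameter <= 0 or self.pillar_spacing <= 0:
            raise ValidationError("pillar geometry must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("lattice must have at least one row and column")
        if self.zone_gap <= 0:
            raise ValidationError("zone_gap must be positive")

    @property
    def trap_pitch(self) -> float:
        return self.pillar_diameter + self.pillar_spacing

    @property
    def zone_rects(self) -> dict[str, tuple[float, float, float, float]]:
        """Half-open ``(x0, y0, x1, y1)`` rectangles in µm, keyed by zone."""
        ox, oy = self.origin
        w = self.n_cols * self.trap_pitch
        h = self.n_rows * self.trap_pitch
        return {
            "test": (ox, oy, ox + w, oy + h),
            "reference": (ox + w + self.zone_gap, oy, ox + 2 * w + self.zone_gap, oy + h),
        }

    @property
    def n_sites(self) -> int:
        return 2 * self.n_rows * self.n_cols

    def trap_sites(self, zone: str) -> np.ndarray:
        """Trap-site centres (µm) of one zone in serpentine flow order.

        Flow traverses rows top to bottom, alternating column direction,
        mirroring how an advancing bead front sweeps the array.
        """
        x0, y0, _, _ = self.zone_rects[zone]
        p = self.trap_pitch
        sites = []
        for r in range(self.n_rows):
            cols = range(self.n_cols) if r % 2 == 0 else range(self.n_cols - 1, -1, -1)
            for c in cols:
                sites.append((x0 + (c + 0.5) * p, y0 + (r + 0.5) * p))
        return np.asarray(sites, dtype=float)

    def pillar_centers(self, zone: str) -> np.ndarray:
        """Pillar centres (µm) of one zone: every lattice-cell corner."""
        x0, y0, _, _ = self.zone_rects[zone]
        p = self.trap_pitch
        xs = x0 + p * np.arange(self.n_cols + 1)
        ys = y0 + p * np.arange(self.n_rows + 1)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def extent(self) -> tuple[float, float]:
        """(width, height) in µm of the layout plus symmetric margins."""
        _, _, x1, _ = self.zone_rects["reference"]
        _, _, _, y1 = self.zone_rects["test"]
        return (x1 + self.origin[0], y1 + self.origin[1])


def build_layout(
    pillar_diameter: float = 50.0,
    pillar_spacing: float = 14.0,
    n_rows: int = 4,
    n_cols: int = 5,
    zone_gap: float = 64.0,
    origin: tuple[float, float] = (32.0, 32.0),
) -> ChipLayout:
    """Construct a validated two-zone trap lattice.

    Defaults follow the chip: 50 µm pillars, 14 µm spacing (64 µm pitch),
    20 traps per zone so a default scene holds ~40 beads.
    """
    return ChipLayout(pillar_diameter, pillar_spacing, n_rows, n_cols, zone_gap, origin)


@dataclass(frozen=True)
class ImagingConfig:
    """Camera/optics description shared by simulation and quantification.

    ``black_level`` is the constant offset the camera adds to every
    recorded fluorescence pixel (the microscope's black-balance setting,
    1800 grayscale units on the 16-bit scale); it is modelled as purely
    additive.  ``psf_sigma`` is the Gaussian blur scale in pixels.
    """

    pixel_size: float = 0.5
    image_shape: tuple[int, int] | None = None
    bit_depth: int = 16
    black_level: float = 1800.0
    psf_sigma: float = 1.0
    bead_diameter: float = 15.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")
        if not (0 <= self.black_level < self.max_value):
            raise ValidationError("black_level must be below the representable maximum")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.bead_diameter / self.pixel_size < 4:
            raise ValidationError("bead must span at least 4 pixels")
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma must be >= 0")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def bead_radius_px(self) -> float:
        return 0.5 * self.bead_diameter / self.pixel_size

    def shape_for(self, layout: ChipLayout) -> tuple[int, int]:
        """Image shape (rows, cols) covering the layout, unless overridden."""
        if self.image_shape is not None:
            return self.image_shape
        w, h = layout.extent()
        return (int(math.ceil(h / self.pixel_size)), int(math.ceil(w / self.pixel_size)))


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise and object contrast for scene rendering.

    Shot noise resamples the photon-borne part of each pixel (background
    plus object signal, not the black level) from a Poisson law; read
    noise is additive Gaussian.  Bright-field beads and pillars are
    rendered as dark disks (negative contrast) on a bright background,
    the typical appearance of polystyrene beads and PDMS pillars.
    """

    read_noise_sd: float = 30.0
    shot_noise: bool = True
    background_bf: float = 30000.0
    background_fl: float = 0.0
    bead_bf_contrast: float = -9000.0
    pillar_bf_contrast: float = -15000.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        if self.background_bf < 0 or self.background_fl < 0:
            raise ValidationError("backgrounds must be >= 0")

    @classmethod
    def noiseless(cls, **overrides) -> "NoiseModel":
        """Deterministic rendering: no shot noise, no read noise."""
        kwargs = dict(read_noise_sd=0.0, shot_noise=False)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class BeadTruth:
    """Ground truth for one simulated bead.

    ``true_mean_fl`` is the bead's noiseless in-mask mean fluorescence
    above background and black level; it and ``bbox`` are filled in at
    render time.
    """

    bead_id: int
    center: tuple[float, float]  # µm
    radius: float  # µm
    zone: str
    site_index: int = -1
    true_mean_fl: float | None = None
    bbox: tuple[int, int, int, int] | None = None

    def center_px(self, pixel_size: float) -> tuple[float, float]:
        return (self.center[0] / pixel_size, self.center[1] / pixel_size)


@dataclass(frozen=True)
class Micrograph:
    """Single-channel grayscale raster with its physical calibration."""

    data: np.ndarray
    pixel_size: float
    bit_depth: int
    channel: str = "bright-field"

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValidationError("micrograph must be a single-channel 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


# ---------------------------------------------------------------------------
# bead loading


def place_beads(
    layout: ChipLayout,
    n_injected: int,
    p_trap: float = 0.8,
    doublet_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
    zone: str | None = None,
) -> tuple[list[BeadTruth], int]:
    """Load beads into trap sites by self-regulated sequential trapping.

    Each injected bead sweeps the empty sites in serpentine flow order and
    lodges in the current one with probability ``p_trap``; otherwise the
    transverse flow diverts it onward to the next empty site.  Occupied
    sites are always skipped (their longitudinal resistance diverts
    arrivals), so a bead escapes only once every downstream site is full.
    With ``doublet_prob`` > 0 an arriving bead may instead pile onto an
    occupied site it passes, breaking monodispersion.

    Returns the placed beads (``true_mean_fl`` unset) and the count of
    escaped beads; placements + escapes always equal ``n_injected``.
    ``zone`` restricts loading to one zone; by default the test zone is
    loaded first, then the reference zone, each with half the sites.
    """
    if not 0 <= p_trap <= 1 or not 0 <= doublet_prob <= 1:
        raise ValidationError("p_trap and doublet_prob must lie in [0, 1]")
    if n_injected < 0:
        raise ValidationError("n_injected must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    zones = ZONES if zone is None else (zone,)
    sites: list[tuple[str, int, tuple[float, float]]] = []
    for z in zones:
        for i, (x, y) in enumerate(layout.trap_sites(z)):
            sites.append((z, i, (float(x), float(y))))

    occupied: list[bool] = [False] * len(sites)
    doubled: list[bool] = [False] * len(sites)
    beads: list[BeadTruth] = []
    radius = 7.5  # µm; overridden at render time by ImagingConfig.bead_diameter
    n_escaped = 0
    for bead_id in range(n_injected):
        placed = False
        for j, (z, site_i, (x, y)) in enumerate(sites):
            if occupied[j]:
                if doublet_prob > 0 and not doubled[j] and rng.random() < doublet_prob:
                    doubled[j] = True
                    beads.append(BeadTruth(bead_id, (x + radius, y), radius, z, site_i))
                    placed = True
                    break
                continue
            if p_trap >= 1.0 or rng.random() < p_trap:
                occupied[j] = True
                beads.append(BeadTruth(bead_id, (x, y), radius, z, site_i))
                placed = True
                break
        if not placed:
            n_escaped += 1
    return beads, n_escaped


# ---------------------------------------------------------------------------
# rendering


def _add_disk(img: np.ndarray, cx: float, cy: float, radius: float, value: float) -> None:
    """Add ``value`` to pixels whose centres fall within the disk (in place)."""
    h, w = img.shape
    x0, y0, x1, y1 = circle_bbox(cx, cy, radius)
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] += value


def _finalize(img: np.ndarray, imaging: ImagingConfig, noise: NoiseModel,
              rng: np.random.Generator, offset: float) -> np.ndarray:
    """Blur, apply shot/read noise and the constant offset, clip, quantise."""
    if imaging.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, imaging.psf_sigma, mode="nearest")
    if noise.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    img = img + offset
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
    return np.clip(np.rint(img), 0, imaging.max_value).astype(imaging.dtype)


def _check_in_frame(beads: Sequence[BeadTruth], imaging: ImagingConfig,
                    shape: tuple[int, int]) -> None:
    h, w = shape
    for b in beads:
        cx, cy = b.center_px(imaging.pixel_size)
        r = imaging.bead_radius_px
        x0, y0, x1, y1 = circle_bbox(cx, cy, r)
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValidationError(
                f"bead {b.bead_id} at {b.center} µm extends outside the image frame"
            )


def _draw_true_means(
    beads: Sequence[BeadTruth],
    zone_intensity_means: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
) -> list[float]:
    """Per-bead true fluorescence: lognormal about the zone mean with given CV."""
    values = []
    for b in beads:
        try:
            mean, cv = zone_intensity_means[b.zone]
        except KeyError as exc:
            raise ValidationError(f"no intensity distribution for zone {b.zone!r}") from exc
        if mean < 0 or cv < 0:
            raise ValidationError("zone intensity mean and CV must be >= 0")
        if cv == 0 or mean == 0:
            values.append(float(mean))
        else:
            sigma2 = math.log1p(cv * cv)
            mu = math.log(mean) - 0.5 * sigma2
            values.append(float(rng.lognormal(mu, math.sqrt(sigma2))))
    return values


def render_brightfield(
    layout: ChipLayout,
    beads: Sequence[BeadTruth],
    imaging: ImagingConfig,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> Micrograph:
    """Render the bright-field channel: pillars and beads as contrast disks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = imaging.shape_for(layout)
    _check_in_frame(beads, imaging, shape)
    img = np.full(shape, noise.background_bf, dtype=float)
    ps = imaging.pixel_size
    pillar_r = 0.5 * layout.pillar_diameter / ps
    for zone in ZONES:
        for px, py in layout.pillar_centers(zone):
            _add_disk(img, px / ps, py / ps, pillar_r, noise.pillar_bf_contrast)
    for b in beads:
        cx, cy = b.center_px(ps)
        _add_disk(img, cx, cy, imaging.bead_radius_px, noise.bead_bf_contrast)
    data = _finalize(img, imaging, noise, rng, offset=0.0)
    return Micrograph(data, ps, imaging.bit_depth, "bright-field")


def render_fluorescence(
    layout: ChipLayout,
    beads: Sequence[BeadTruth],
    imaging: ImagingConfig,
    noise: NoiseModel,
    zone_intensity_means: Mapping[str, tuple[float, float]],
    seed: int | np.random.Generator = 0,
    channel: str = "fluorescence",
) -> tuple[Micrograph, list[BeadTruth]]:
    """Render one fluorescence channel and return truths with realised means.

    Each bead's disk is raised by a ``true_mean_fl`` drawn from its zone's
    (mean, CV) lognormal; the image is background + disks, blurred, with
    optional shot noise, plus the constant black level, plus read noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = imaging.shape_for(layout)
    _check_in_frame(beads, imaging, shape)
    true_means = _draw_true_means(beads, zone_intensity_means, rng)
    img = np.full(shape, noise.background_fl, dtype=float)
    ps = imaging.pixel_size
    out_truths: list[BeadTruth] = []
    for b, tm in zip(beads, true_means):
        cx, cy = b.center_px(ps)
        r = imaging.bead_radius_px
        _add_disk(img, cx, cy, r, tm)
        out_truths.append(
            replace(
                b,
                radius=0.5 * imaging.bead_diameter,
                true_mean_fl=tm,
                bbox=circle_bbox(cx, cy, r),
            )
        )
    data = _finalize(img, imaging, noise, rng, offset=imaging.black_level)
    return Micrograph(data, ps, imaging.bit_depth, channel), out_truths


def render_pair(
    layout: ChipLayout,
    beads: Sequence[BeadTruth],
    imaging: ImagingConfig,
    noise: NoiseModel,
    zone_intensity_means: Mapping[str, tuple[float, float]],
    seed: int = 0,
) -> tuple[Micrograph, Micrograph, list[BeadTruth]]:
    """Render a paired bright-field + fluorescence micrograph with truth.

    ``zone_intensity_means`` maps zone label to ``(mean, cv)`` of the
    per-bead true fluorescence distribution.
    """
    ss = np.random.SeedSequence(seed)
    rng_bf, rng_fl = (np.random.default_rng(s) for s in ss.spawn(2))
    bf = render_brightfield(layout, beads, imaging, noise, rng_bf)
    fl, truths = render_fluorescence(
        layout, beads, imaging, noise, zone_intensity_means, rng_fl
    )
    return bf, fl, truths


# ---------------------------------------------------------------------------
# dilution series


@dataclass
class CalibrationDataset:
    """A concentration/signal dilution series with blank replicates."""

    concentrations: np.ndarray  # particles/µL, one per record
    signals: np.ndarray  # grayscale units
    replicates: np.ndarray  # replicate index per record
    blank_signals: np.ndarray  # signals at zero concentration

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=int)
        self.blank_signals = np.asarray(self.blank_signals, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be >= 0")

    def to_frame(self):
        import pandas as pd

        series = pd.DataFrame(
            {
                "concentration": np.concatenate(
                    [self.concentrations, np.zeros(len(self.blank_signals))]
                ),
                "signal": np.concatenate([self.signals, self.blank_signals]),
                "replicate": np.concatenate(
                    [self.replicates, np.arange(len(self.blank_signals))]
                ),
                "is_blank": np.concatenate(
                    [
                        np.zeros(len(self.signals), dtype=bool),
                        np.ones(len(self.blank_signals), dtype=bool),
                    ]
                ),
            }
        )
        return series

    @classmethod
    def from_frame(cls, frame) -> "CalibrationDataset":
        blanks = frame[frame["is_blank"].astype(bool)]
        series = frame[~frame["is_blank"].astype(bool)]
        return cls(
            series["concentration"].to_numpy(),
            series["signal"].to_numpy(),
            series["replicate"].to_numpy(),
            blanks["signal"].to_numpy(),
        )


def simulate_dilution_series(
    concentrations: Sequence[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    n_reps: int = 3,
    n_blanks: int = 3,
    seed: int | np.random.Generator = 0,
) -> CalibrationDataset:
    """Simulate a linear dilution series plus blank-control replicates.

    Signals follow ``intercept + slope * concentration`` with Gaussian
    noise of SD ``noise_sd``; blanks are drawn at concentration zero,
    emulating a cell-culture-medium blank control.
    """
    if slope <= 0:
        raise ValidationError("slope must be positive")
    if n_reps < 1 or n_blanks < 2:
        raise ValidationError("need n_reps >= 1 and n_blanks >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = np.repeat(np.asarray(concentrations, dtype=float), n_reps)
    reps = np.tile(np.arange(n_reps), len(concentrations))
    signals = intercept + slope * conc
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, signals.shape)
    blanks = np.full(n_blanks, float(intercept))
    if noise_sd > 0:
        blanks = blanks + rng.normal(0.0, noise_sd, n_blanks)
    return CalibrationDataset(conc, signals, reps, blanks)


# ---------------------------------------------------------------------------
# dataset export (detector training/evaluation format)


def write_yolo_annotations(path: Path, truths: Sequence[BeadTruth],
                           image_shape: tuple[int, int]) -> None:
    """Write one ``class cx cy w h`` line per bead, normalised to [0, 1]."""
    h, w = image_shape
    lines = []
    for t in truths:
        if t.bbox is None:
            raise ValidationError(f"bead {t.bead_id} has no bbox; render the scene first")
        x0, y0, x1, y1 = t.bbox
        cx, cy = (x0 + x1) / (2 * w), (y0 + y1) / (2 * h)
        bw, bh = (x1 - x0) / w, (y1 - y0) / h
        if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < bw <= 1 and 0 < bh <= 1):
            raise ValidationError(f"bead {t.bead_id} annotation falls outside [0, 1]")
        lines.append(f"0 {cx:.10f} {cy:.10f} {bw:.10f} {bh:.10f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_annotations(path: Path, image_shape: tuple[int, int]
                          ) -> list[tuple[int, int, int, int]]:
    """Read YOLO annotation lines back into half-open pixel boxes."""
    h, w = image_shape
    boxes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, cx, cy, bw, bh = (float(v) for v in line.split())
        x0 = round(w * (cx - bw / 2))
        y0 = round(h * (cy - bh / 2))
        x1 = round(w * (cx + bw / 2))
        y1 = round(h * (cy + bh / 2))
        boxes.append((x0, y0, x1, y1))
    return boxes


def export_dataset(
    scenes: Sequence[tuple[Micrograph, Micrograph, Sequence[BeadTruth]]],
    out_dir: Path,
    split_ratios: Sequence[float] = (7, 2, 1),
    seed: int = 0,
) -> dict:
    """Write scenes to disk as a detector train/val/test dataset.

    Per scene: 16-bit TIFF bright-field and fluorescence images, a YOLO
    annotation file for the bright-field image, and rows in a shared
    truth CSV.  Scenes are partitioned into train/validation/test splits
    (default 7:2:1) by seeded shuffle with largest-remainder rounding;
    the returned manifest (also written as JSON) records the disjoint,
    exhaustive split membership and per-image saturation flags.
    """
    from .evaluate import split_dataset

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene_ids = [f"scene_{i:04d}" for i in range(len(scenes))]
    images: dict[str, dict] = {}
    truth_rows = []
    for sid, (bf, fl, truths) in zip(scene_ids, scenes):
        bf_path = out_dir / f"{sid}_bf.tif"
        fl_path = out_dir / f"{sid}_fl.tif"
        tifffile.imwrite(bf_path, bf.data)
        tifffile.imwrite(fl_path, fl.data)
        write_yolo_annotations(out_dir / f"{sid}.txt", truths, bf.shape)
        for t in truths:
            truth_rows.append(
                {
                    "scene": sid,
                    "bead_id": t.bead_id,
                    "zone": t.zone,
                    "x_um": t.center[0],
                    "y_um": t.center[1],
                    "radius_um": t.radius,
                    "true_mean_fl": t.true_mean_fl,
                }
            )
        images[sid] = {
            "bright_field": bf_path.name,
            "fluorescence": fl_path.name,
            "annotations": f"{sid}.txt",
            "n_beads": len(truths),
            "saturated": bool((fl.data == fl.max_value).any()
                              or (bf.data == bf.max_value).any()),
        }
    with open(out_dir / "truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["scene", "bead_id", "zone", "x_um", "y_um", "radius_um",
                        "true_mean_fl"],
        )
        writer.writeheader()
        writer.writerows(truth_rows)
    subsets = split_dataset(scene_ids, split_ratios, seed)
    names = (["train", "val", "test"] if len(subsets) == 3
             else [f"split_{i}" for i in range(len(subsets))])
    manifest = {
        "images": images,
        "splits": dict(zip(names, subsets)),
        "split_ratios": list(split_ratios),
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
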