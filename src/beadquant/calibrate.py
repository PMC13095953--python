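"""Calibration fitting, limit of detection, and retention QC.

The dilution-series calibration is an ordinary least-squares line of
signal on concentration with its coefficient of determination.  The
limit of detection follows the blank + k*sigma convention (k = 3 by
default): the concentration at which the fitted line first exceeds the
blank mean by k blank standard deviations,

    LOD = (blank_mean + k * blank_sd - intercept) / slope,

floored at zero.  Retention efficiency is the percentage of injected
beads held in the incubation chamber rather than washed out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .synthetic import CalibrationDataset


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted concentration-signal line, optionally with blank/LOD data.

    Units: slope in grayscale units per (particles/µL), intercept and
    blank statistics in grayscale units, LOD in particles/µL.
    """

    slope: float
    intercept: float
    r_squared: float
    log_concentration: bool = False
    blank_mean: float | None = None
    blank_sd: float | None = None
    k_sigma: float = 3.0
    lod: float | None = None


@dataclass(frozen=True)
class QCMetrics:
    """Bead-retention quality control, optionally replicate-aggregated."""

    retention_pct: float
    n_retained: int
    n_total: int
    replicate_mean: float | None = None
    replicate_sd: float | None = None


def fit_calibration(dataset: CalibrationDataset,
                    log_concentration: bool = False) -> CalibrationFit:
    """Ordinary least squares of signal on concentration.

    With ``log_concentration`` the predictor is log10(concentration)
    (zero concentrations are rejected).  R² = 1 - SS_res/SS_tot.
    """
    x = np.asarray(dataset.concentrations, dtype=float)
    y = np.asarray(dataset.signals, dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("need at least 2 distinct concentrations to fit")
    if log_concentration:
        if np.any(x <= 0):
            raise ValidationError("log-scale fitting requires positive concentrations")
        x = np.log10(x)
    res = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        log_concentration=log_concentration,
    )


def estimate_lod(fit: CalibrationFit, blank_signals: Sequence[float],
                 k_sigma: float = 3.0) -> CalibrationFit:
    """Attach blank statistics and the blank + k*sigma detection limit.

    The LOD is the concentration where the fitted line reaches
    ``blank_mean + k_sigma * blank_sd``; negative extrapolations are
    floored at zero.  Requires a positive slope and >= 2 blanks.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 2:
        raise ValidationError("need at least 2 blank replicates for an LOD")
    if fit.slope <= 0:
        raise ValidationError("LOD requires a positive calibration slope")
    if k_sigma <= 0:
        raise ValidationError("k_sigma must be positive")
    blank_mean = float(blanks.mean())
    blank_sd = float(blanks.std(ddof=1))
    critical = blank_mean + k_sigma * blank_sd
    x_at_critical = (critical - fit.intercept) / fit.slope
    lod = 10.0**x_at_critical if fit.log_concentration else max(0.0, x_at_critical)
    return replace(fit, blank_mean=blank_mean, blank_sd=blank_sd,
                   k_sigma=float(k_sigma), lod=float(lod))


def calibrate(dataset: CalibrationDataset, k_sigma: float = 3.0,
              log_concentration: bool = False) -> CalibrationFit:
    """Fit the line and estimate the LOD from the dataset's blanks."""
    fit = fit_calibration(dataset, log_concentration=log_concentration)
    return estimate_lod(fit, dataset.blank_signals, k_sigma=k_sigma)


def retention_efficiency(n_retained, n_total) -> QCMetrics:
    """Percentage of beads retained in the chamber versus total injected.

    Scalars give a single percentage; equal-length sequences are treated
    as replicates, reporting pooled counts plus the mean ± sample SD of
    the per-replicate percentages.
    """
    retained = np.atleast_1d(np.asarray(n_retained, dtype=float))
    total = np.atleast_1d(np.asarray(n_total, dtype=float))
    if retained.shape != total.shape:
        raise ValidationError("n_retained and n_total must have matching shapes")
    if np.any(total <= 0):
        raise ValidationError("n_total must be positive")
    if np.any(retained < 0) or np.any(retained > total):
        raise ValidationError("need 0 <= n_retained <= n_total")
    pcts = 100.0 * retained / total
    pooled = 100.0 * retained.sum() / total.sum()
    if retained.size > 1:
        return QCMetrics(
            retention_pct=float(pooled),
            n_retained=int(retained.sum()),
            n_total=int(total.sum()),
            replicate_mean=float(pcts.mean()),
            replicate_sd=float(pcts.std(ddof=1)),
        )
    return QCMetrics(retention_pct=float(pcts[0]), n_retained=int(retained[0]),
                     n_total=int(total[0]))
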