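"""Intensity histograms, Gaussian population fits and size calibration.

The sizing chain: histogram the background-adjusted molecule
intensities, locate population peaks, seed a Gaussian per peak from its
full width at half maximum (sigma = FWHM / 2*sqrt(2 ln 2)), refine by
least squares restricted to a window around the seed, then regress known
plasmid size (bp) on fitted population mean intensity (a.u.).  The
resulting linear calibration maps any intensity to base pairs with a
prediction-interval error band.  Calibration curves are condition-keyed:
buffer composition and dye ratio change the intensity-per-bp slope, so a
curve must only be applied to data acquired under its own condition.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "IntensityHistogram",
    "PopulationFit",
    "CalibrationCurve",
    "SizeEstimate",
    "UnresolvedPeakError",
    "FWHM_TO_SIGMA",
    "build_histogram",
    "find_peaks",
    "init_gaussian",
    "fit_population",
    "fit_calibration",
    "intensity_to_size",
]

logger = logging.getLogger(__name__)

#: FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class UnresolvedPeakError(ValueError):
    """A peak's FWHM cannot be measured (edge-truncated or merged)."""


@dataclass
class IntensityHistogram:
    bin_edges: np.ndarray  # length n_bins + 1, strictly increasing, a.u.
    counts: np.ndarray  # integer counts per bin
    n_total: int  # molecules inside the histogram range
    source: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class PopulationFit:
    mean: float  # mu, a.u.
    sd: float  # sigma, a.u.
    amplitude: float  # peak height, counts
    n_molecules: int  # molecules inside the fit window
    fit_window: Tuple[float, float]  # (lo, hi), a.u.
    size_bp: Optional[float] = None  # filled after calibration
    size_error_bp: Optional[float] = None


@dataclass
class CalibrationCurve:
    """Linear intensity -> size map with prediction-interval machinery.

    ``size = slope * intensity + intercept``; the stored sufficient
    statistics (n, x_mean, s_xx, residual_sd) reproduce the prediction
    interval for any new intensity without the raw points.
    """

    slope: float  # bp per a.u.
    intercept: float  # bp
    r_squared: float
    residual_sd: float  # bp
    n_points: int
    x_mean: float  # a.u.
    s_xx: float  # sum (x - x_mean)^2 (or sum x^2 if through origin)
    x_range: Tuple[float, float]
    condition: str = "default"
    through_origin: bool = False
    ci_level: float = 0.99

    def to_json(self, path: Optional[Path] = None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        d["x_range"] = tuple(d["x_range"])
        return cls(**d)


@dataclass
class SizeEstimate:
    size_bp: float
    error_bp: float  # prediction-interval half-width at the curve's ci_level
    extrapolated: bool
    valid: bool  # false if the predicted size is negative


def build_histogram(
    intensities: Sequence[float],
    n_bins: int | str = 100,
    hist_range: Optional[Tuple[float, float]] = None,
    source: str = "",
) -> IntensityHistogram:
    """Bin molecule intensities; values outside the range are logged.

    ``n_bins`` is a fixed bin count or ``"auto"`` (Freedman-Diaconis).
    The default range starts at 0 (negative adjusted intensities are
    background noise, excluded here rather than clipped upstream).
    """
    x = np.asarray(list(intensities), dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite intensities to histogram")
    if hist_range is None:
        hist_range = (0.0, float(x.max()) * 1.02 + 1e-12)
    bins = "fd" if n_bins == "auto" else n_bins
    counts, edges = np.histogram(x, bins=bins, range=hist_range)
    n_out = int(((x < hist_range[0]) | (x > hist_range[1])).sum())
    if n_out:
        logger.info("%d of %d intensities outside histogram range", n_out, x.size)
    return IntensityHistogram(
        bin_edges=edges, counts=counts, n_total=int(counts.sum()), source=source
    )


def find_peaks(
    hist: IntensityHistogram,
    prominence_frac: float = 0.05,
    min_distance_bins: int = 3,
    smooth: int = 3,
) -> List[float]:
    """Locate population peaks as local maxima of the (lightly smoothed)
    histogram exceeding a prominence threshold, ordered by position."""
    counts = hist.counts.astype(float)
    if counts.size < 3:
        raise ValueError("histogram needs at least 3 bins")
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        counts = np.convolve(counts, kernel, mode="same")
    if counts.max() <= 0:
        return []
    prominence = prominence_frac * counts.max()
    idx, _ = signal.find_peaks(counts, prominence=prominence, distance=min_distance_bins)
    return [float(c) for c in hist.centers[idx]]


def _nearest_bin(hist: IntensityHistogram, position: float) -> int:
    return int(np.clip(np.searchsorted(hist.bin_edges, position) - 1, 0, hist.counts.size - 1))


def init_gaussian(hist: IntensityHistogram, peak: float) -> Tuple[float, float, float]:
    """Seed (mu0, sigma0, amplitude0) for a peak from its FWHM.

    Walks outward from the peak bin to the half-maximum crossings
    (linear interpolation between bin centers); raises
    :class:`UnresolvedPeakError` if either crossing runs off the
    histogram edge, which signals a truncated or merged population.
    """
    counts = hist.counts.astype(float)
    centers = hist.centers
    i0 = _nearest_bin(hist, peak)
    # snap to the local maximum within +-2 bins of the nominal position
    lo_snap, hi_snap = max(i0 - 2, 0), min(i0 + 3, counts.size)
    i0 = lo_snap + int(np.argmax(counts[lo_snap:hi_snap]))
    height = counts[i0]
    if height <= 0:
        raise UnresolvedPeakError(f"no counts at peak {peak!r}")
    half = height / 2.0

    def _cross(direction: int) -> float:
        i = i0
        while 0 <= i + direction < counts.size:
            j = i + direction
            if counts[j] <= half:
                # interpolate between centers[i] (above) and centers[j] (below)
                c1, c2 = counts[i], counts[j]
                frac = (c1 - half) / (c1 - c2) if c1 != c2 else 0.5
                return centers[i] + frac * (centers[j] - centers[i])
            i = j
        raise UnresolvedPeakError(
            f"half-maximum not reached {'right' if direction > 0 else 'left'} of peak at {peak:g}"
        )

    left = _cross(-1)
    right = _cross(+1)
    fwhm = right - left
    if fwhm <= 0:
        raise UnresolvedPeakError(f"non-positive FWHM at peak {peak:g}")
    return float(centers[i0]), float(fwhm * FWHM_TO_SIGMA), float(height)


def _gauss(x: np.ndarray, mu: float, sd: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_population(
    intensities: Sequence[float],
    init: Tuple[float, float, float],
    window_sigmas: float = 2.0,
    min_molecules: int = 20,
    n_bins: int = 25,
) -> PopulationFit:
    """Refine one population by least squares on binned counts inside
    ``mu0 +- window_sigmas * sigma0``.

    Restricting the fit to the window isolates the population from its
    neighbours, so overlapping tails of other populations outside the
    window do not bias the mean.  Failure to converge raises; it is never
    silent.
    """
    mu0, sd0, amp0 = init
    if sd0 <= 0:
        raise ValueError("initial sigma must be positive")
    x = np.asarray(list(intensities), dtype=float)
    lo, hi = mu0 - window_sigmas * sd0, mu0 + window_sigmas * sd0
    inside = x[(x >= lo) & (x <= hi)]
    n_in = int(inside.size)
    if n_in < min_molecules:
        raise ValueError(
            f"only {n_in} molecules in fit window [{lo:g}, {hi:g}] (minimum {min_molecules})"
        )
    counts, edges = np.histogram(inside, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    amp_guess = max(counts.max(), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers,
            counts.astype(float),
            p0=(mu0, sd0, amp_guess),
            bounds=([lo, 1e-9, 0.0], [hi, (hi - lo), np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise RuntimeError(f"Gaussian fit failed to converge near {mu0:g}") from exc
    mu, sd, amp = map(float, popt)
    return PopulationFit(
        mean=mu, sd=sd, amplitude=amp, n_molecules=n_in, fit_window=(lo, hi)
    )


def fit_calibration(
    points: Sequence[Tuple[float, float]],
    through_origin: bool = False,
    ci_level: float = 0.99,
    condition: str = "default",
) -> CalibrationCurve:
    """Ordinary least squares of known size (bp) on population mean
    intensity (a.u.).

    ``through_origin`` forces a zero intercept.  R^2 is always computed
    about the mean of y (centred total sum of squares), also for the
    coerced fit: this keeps the two fits on one comparable scale, on
    which forcing the origin can only lower R^2.  Residual SD and the
    sufficient statistics for prediction intervals are stored on the
    curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (intensity, size_bp) pairs")
    x, y = pts[:, 0], pts[:, 1]
    n = x.size
    min_pts = 1 if through_origin else 2
    if n < min_pts:
        raise ValueError(f"need at least {min_pts} points")
    if np.ptp(x) == 0 and not through_origin:
        raise ValueError("degenerate calibration: all intensities equal")
    if through_origin:
        sxx = float((x * x).sum())
        slope = float((x * y).sum() / sxx)
        intercept = 0.0
        fitted = slope * x
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum()) if n > 1 else float((y * y).sum())
        df = n - 1
        x_mean = 0.0
    else:
        x_mean = float(x.mean())
        sxx = float(((x - x_mean) ** 2).sum())
        slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * x_mean)
        fitted = slope * x + intercept
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        df = n - 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    residual_sd = math.sqrt(ss_res / df) if df > 0 else 0.0
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        residual_sd=residual_sd,
        n_points=int(n),
        x_mean=x_mean,
        s_xx=sxx,
        x_range=(float(x.min()), float(x.max())),
        condition=condition,
        through_origin=through_origin,
        ci_level=ci_level,
    )


def intensity_to_size(curve: CalibrationCurve, intensity: float) -> SizeEstimate:
    """Map an intensity to base pairs with a prediction-interval error.

    The error is the half-width of the prediction interval for a *new*
    observation at the curve's ``ci_level`` — wider than the confidence
    band of the regression mean, matching per-molecule estimation-error
    reporting.  Intensities outside the calibrated range are flagged as
    extrapolated; a negative predicted size is flagged invalid.
    """
    x = float(intensity)
    size = curve.slope * x + curve.intercept
    df = curve.n_points - (1 if curve.through_origin else 2)
    if df > 0 and curve.s_xx > 0:
        tcrit = stats.t.ppf(0.5 + curve.ci_level / 2.0, df)
        if curve.through_origin:
            lever = x * x / curve.s_xx
        else:
            lever = 1.0 / curve.n_points + (x - curve.x_mean) ** 2 / curve.s_xx
        half = float(tcrit * curve.residual_sd * math.sqrt(1.0 + lever))
    else:
        half = float("nan")
    lo, hi = curve.x_range
    margin = 0.05 * (hi - lo)
    extrapolated = x < lo - margin or x > hi + margin
    if extrapolated:
        logger.warning("intensity %g outside calibrated range [%g, %g]", x, lo, hi)
    return SizeEstimate(
        size_bp=float(size),
        error_bp=half,
        extrapolated=extrapolated,
        valid=size >= 0,
    )
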