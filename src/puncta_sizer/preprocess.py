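"""Quality control and image correction ahead of segmentation.

The focus/artifact screen is an automated surrogate for manual
inspection: a variance-of-Laplacian focus score plus a saturated-pixel
fraction, with configurable thresholds and a manual-exclusion list.
Shading (uneven illumination) is estimated retrospectively from the data
itself — a robust per-pixel average over many fields, heavily smoothed —
because no flat-field reference image is assumed to exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .config import QCConfig

__all__ = [
    "QCReport",
    "qc_field",
    "estimate_shading",
    "correct_shading",
    "denoise",
]


@dataclass
class QCReport:
    field_id: str
    passed: bool
    focus_score: float
    saturation_fraction: float
    artifact_flags: List[str] = field(default_factory=list)


def focus_score(image: np.ndarray) -> float:
    """Normalized variance of the Laplacian: higher = sharper.

    Normalizing by the squared mean makes the score invariant to overall
    brightness, so fields with different illumination are comparable.
    Constant images score exactly 0.
    """
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean <= 0:
        return 0.0
    lap = ndimage.laplace(img)
    return float(lap.var() / mean**2)


def qc_field(image: np.ndarray, config: QCConfig | None = None, field_id: str = "field") -> QCReport:
    """Score one field for focus and saturation artifacts.

    ``passed`` is true iff focus_score >= focus_min, the saturated-pixel
    fraction is <= saturation_max, the raster is finite, and the field is
    not on the manual exclusion list.  Degenerate inputs (all-zero image)
    fail with a flag rather than raising.
    """
    config = config or QCConfig()
    img = np.asarray(image, dtype=float)
    flags: List[str] = []
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")

    score = focus_score(img)
    sat_frac = float((img >= config.saturation_level).mean())

    if not img.any():
        flags.append("empty")
    if score < config.focus_min:
        flags.append("out_of_focus")
    if sat_frac > config.saturation_max:
        flags.append("saturation")
    if field_id in config.exclude:
        flags.append("manually_excluded")
    return QCReport(
        field_id=field_id,
        passed=not flags,
        focus_score=score,
        saturation_fraction=sat_frac,
        artifact_flags=flags,
    )


def estimate_shading(fields: Sequence[np.ndarray], smooth_sigma: float | None = None) -> np.ndarray:
    """Estimate the relative illumination profile from the data itself.

    Per-pixel median across fields (robust to sparse bright puncta),
    heavily Gaussian-smoothed so only the large-scale illumination
    pattern survives, then rescaled to mean 1.  The result is strictly
    positive and can be passed to :func:`correct_shading`.
    """
    if len(fields) == 0:
        raise ValueError("need at least one field")
    shape = np.asarray(fields[0]).shape
    for f in fields:
        if np.asarray(f).shape != shape:
            raise ValueError("field shapes differ")
    stack = np.stack([np.asarray(f, dtype=float) for f in fields])
    robust = np.median(stack, axis=0)
    if smooth_sigma is None:
        # wide enough to erase puncta, narrow enough not to flatten the
        # vignette itself (whose scale is a sizeable fraction of the field);
        # over-smoothing systematically underestimates the vignette depth
        smooth_sigma = max(shape) / 24.0
    smooth = ndimage.gaussian_filter(robust, smooth_sigma, mode="nearest")
    smooth = np.clip(smooth, np.finfo(float).tiny, None)
    shading = smooth / smooth.mean()
    return np.clip(shading, 1e-6, None)


def correct_shading(image: np.ndarray, shading: np.ndarray) -> np.ndarray:
    """Divide out a multiplicative illumination profile."""
    img = np.asarray(image, dtype=float)
    sh = np.asarray(shading, dtype=float)
    if img.shape != sh.shape:
        raise ValueError("image and shading shapes differ")
    if (sh <= 0).any():
        raise ValueError("shading field must be strictly positive")
    return img / sh


def denoise(image: np.ndarray, method: str = "median", size: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Shape-preserving noise filter: ``median`` (default, 3x3),
    ``gaussian`` (total intensity preserved) or ``none``."""
    img = np.asarray(image, dtype=float)
    if method == "none":
        return img.copy()
    if method == "median":
        return ndimage.median_filter(img, size=size, mode="nearest")
    if method == "gaussian":
        if sigma <= 0:
            return img.copy()
        return ndimage.gaussian_filter(img, sigma, mode="nearest")
    raise ValueError(f"unknown denoise method {method!r}")
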