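"""dCas9 colocalization by per-molecule Pearson correlation.

A DNA punctum is called colocalized when the pixelwise Pearson
correlation between the DNA channel and the dCas9 channel over the
molecule's pixels clears both a magnitude threshold (PCC > 0.25 by
default) and a significance threshold (one-sided p < 0.05 under the
t-transform of r).  The molecule mask is dilated by one pixel before
correlating to tolerate sub-pixel channel offsets and PSF bleed; a
constant channel-2 patch (no dCas9 signal at all) yields an undefined
PCC and is classified non-colocalized, the biologically negative case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import ndimage, stats

from .config import ColocThresholds
from .segment import PunctaRecord

__all__ = ["pixel_pcc", "pcc_pvalue", "classify", "coloc_summary", "SampleColocSummary"]


def pixel_pcc(ch1_values: Sequence[float], ch2_values: Sequence[float]) -> float:
    """Pearson correlation of two pixel-intensity vectors.

    Raises ``ValueError`` for length mismatch, n < 3 or a constant
    vector (undefined correlation — callers treat it as non-colocalized).
    """
    a = np.asarray(ch1_values, dtype=float)
    b = np.asarray(ch2_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel: PCC undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def pcc_pvalue(pcc: float, n: int) -> float:
    """One-sided p-value for positive correlation under the null r = 0,
    via t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= pcc <= 1.0:
        raise ValueError("PCC outside [-1, 1]")
    if pcc >= 1.0:
        return 0.0
    if pcc <= -1.0:
        return 1.0
    t = pcc * math.sqrt((n - 2) / (1.0 - pcc * pcc))
    return float(stats.t.sf(t, n - 2))


def classify(
    record: PunctaRecord,
    ch1_image: np.ndarray,
    ch2_image: np.ndarray,
    thresholds: ColocThresholds | None = None,
) -> PunctaRecord:
    """Populate ``ch2_pcc``, ``ch2_pvalue`` and ``colocalized`` in place.

    The pixel support is the molecule mask dilated by
    ``thresholds.dilate_px`` (0 = exact mask).  Undefined PCC (constant
    patch in either channel) is recorded as NaN and non-colocalized.
    """
    thresholds = thresholds or ColocThresholds()
    rr, cc = record.pixels
    shape = ch2_image.shape
    if rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError("record pixels outside channel-2 image")
    if thresholds.dilate_px > 0:
        d = thresholds.dilate_px
        r0 = max(int(rr.min()) - d, 0)
        c0 = max(int(cc.min()) - d, 0)
        r1 = min(int(rr.max()) + d + 1, shape[0])
        c1 = min(int(cc.max()) + d + 1, shape[1])
        mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        mask[rr - r0, cc - c0] = True
        mask = ndimage.binary_dilation(mask, np.ones((3, 3), dtype=bool), iterations=d)
        sr, sc = np.nonzero(mask)
        rr, cc = sr + r0, sc + c0
    v1 = np.asarray(ch1_image, dtype=float)[rr, cc]
    v2 = np.asarray(ch2_image, dtype=float)[rr, cc]
    try:
        r = pixel_pcc(v1, v2)
        p = pcc_pvalue(r, v1.size)
        record.ch2_pcc = r
        record.ch2_pvalue = p
        record.colocalized = bool(r > thresholds.pcc_min and p < thresholds.p_max)
    except ValueError:
        record.ch2_pcc = float("nan")
        record.ch2_pvalue = float("nan")
        record.colocalized = False
    return record


@dataclass
class SampleColocSummary:
    per_sample: Dict[str, float]  # sample id -> colocalization degree, %
    mean: float  # % across samples
    sd: float  # % across samples (0 if a single sample)


def coloc_summary(records_by_sample: Dict[str, List[PunctaRecord]]) -> SampleColocSummary:
    """Colocalization degree (% of molecules called colocalized) per
    sample, with the across-sample mean and SD."""
    per: Dict[str, float] = {}
    for sample, records in records_by_sample.items():
        if not records:
            raise ValueError(f"sample {sample!r} has no records")
        flags = [bool(r.colocalized) for r in records]
        per[sample] = 100.0 * sum(flags) / len(flags)
    values = np.array(list(per.values()))
    return SampleColocSummary(
        per_sample=per,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
    )
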