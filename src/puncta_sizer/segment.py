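"""Puncta detection and background-adjusted intensity extraction.

Two complementary masks are produced — an edge-based one (gradient
magnitude, automatic robust threshold, closed and filled) and a local
adaptive threshold (moving-window mean + k.SD) that catches dim spots on
residual illumination gradients — then merged by union.  Each connected
component becomes a molecule record whose integrated intensity is
adjusted by the median of a surrounding annulus, so the measurement is
invariant to additive background offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import segmentation as sk_segmentation

from .config import SegmentationConfig

__all__ = [
    "PunctaRecord",
    "edge_mask",
    "local_mask",
    "merge_masks",
    "label_and_measure",
    "records_to_dataframe",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PunctaRecord:
    """One detected molecule.

    ``adjusted_intensity = raw_integrated - area * local_background_per_px``
    is the sizing observable.  The channel-2 fields stay ``None`` until
    colocalization runs.
    """

    molecule_id: int
    field_id: str
    pixels: Tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area: int
    centroid: Tuple[float, float]
    raw_integrated: float
    local_background_per_px: float
    adjusted_intensity: float
    ch2_pcc: Optional[float] = None
    ch2_pvalue: Optional[float] = None
    colocalized: Optional[bool] = None


def edge_mask(image: np.ndarray, k: float = 6.0, erode: int = 2) -> np.ndarray:
    """Edge-based foreground mask.

    Sobel gradient magnitude is thresholded at ``median + k`` robust SDs
    (median absolute deviation scaled to a Gaussian SD) — an automatic
    threshold that returns an empty mask on constant or pure-noise
    images — then the edge rings are closed, their interiors filled, and
    the result eroded by ``erode`` px.  The erosion matters: the gradient
    halo of a bright punctum extends well past the spot core, and without
    it neighbouring molecules merge at 2-3x the distance they should.
    The trimmed tail intensity is recovered at measurement time via the
    dilated integration support.
    """
    img = np.asarray(image, dtype=float)
    gr = ndimage.sobel(img, axis=0)
    gc = ndimage.sobel(img, axis=1)
    grad = np.hypot(gr, gc)
    med = np.median(grad)
    mad = np.median(np.abs(grad - med))
    sigma = 1.4826 * mad
    if sigma == 0 and grad.max() == 0:
        return np.zeros(img.shape, dtype=bool)
    thresh = med + k * sigma if sigma > 0 else 0.5 * grad.max()
    edges = grad > thresh
    # small closing footprint: just enough to seal a diffraction-limited
    # edge ring without bridging neighbouring molecules
    closed = ndimage.binary_closing(edges, structure=_STRUCT8)
    filled = ndimage.binary_fill_holes(closed)
    if erode:
        filled = ndimage.binary_erosion(filled, structure=_STRUCT8, iterations=erode)
    return filled


def local_mask(image: np.ndarray, window: int = 31, k: float = 3.0) -> np.ndarray:
    """Local adaptive threshold: pixel > moving-window mean + k.SD.

    Robust to smooth illumination gradients that defeat a single global
    threshold; ``window`` (odd, px) and ``k`` come from config.
    """
    img = np.asarray(image, dtype=float)
    if window > min(img.shape):
        raise ValueError(f"window {window} larger than image {img.shape}")
    m = ndimage.uniform_filter(img, window, mode="nearest")
    m2 = ndimage.uniform_filter(img * img, window, mode="nearest")
    sd = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return img > m + k * sd


def merge_masks(
    edge: np.ndarray,
    local: np.ndarray,
    min_area: int = 4,
    remove_border: bool = True,
) -> np.ndarray:
    """Union of the two masks, then small-object and border filters.

    Border-touching components are removed because their truncated
    integrated intensity would bias sizing low.
    """
    if edge.shape != local.shape:
        raise ValueError("mask shapes differ")
    merged = np.logical_or(edge, local)
    labels, n = ndimage.label(merged, structure=_STRUCT8)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_area
        keep[0] = False
        merged = keep[labels]
    if remove_border:
        merged = sk_segmentation.clear_border(merged)
    return merged


def label_and_measure(
    image: np.ndarray,
    mask: np.ndarray,
    config: SegmentationConfig | None = None,
    field_id: str = "field",
    id_offset: int = 0,
) -> List[PunctaRecord]:
    """Label connected components and measure each one.

    Per component: the mask is first grown by ``measure_dilate`` px so
    the integration support captures the PSF tails the threshold cut off
    (pixels belonging to *other* components are never annexed);
    ``raw_integrated`` is the sum of pixel values over that support.  The
    local background per pixel is the *median* of an annulus a further
    ``annulus_gap`` px out and ``annulus_width`` px wide, excluding every
    foreground pixel in the field.  Components whose annulus is empty
    (no background pixels available) are dropped and counted in the log.
    """
    config = config or SegmentationConfig()
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask and image shapes differ")
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    records: List[PunctaRecord] = []
    if n == 0:
        return records
    slices = ndimage.find_objects(labels)
    pad = config.measure_dilate + config.annulus_gap + config.annulus_width + 1
    dropped = 0
    mol_id = id_offset
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rsl = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, img.shape[0]))
        csl = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, img.shape[1]))
        sub_lab = labels[rsl, csl]
        comp = sub_lab == lab
        if config.measure_dilate:
            comp = ndimage.binary_dilation(
                comp, _STRUCT8, iterations=config.measure_dilate
            ) & ((sub_lab == lab) | (sub_lab == 0))
        area = int(comp.sum())
        inner = ndimage.binary_dilation(comp, _STRUCT8, iterations=config.annulus_gap) if config.annulus_gap else comp
        outer = ndimage.binary_dilation(inner, _STRUCT8, iterations=config.annulus_width)
        ring = outer & ~inner & (sub_lab == 0)
        sub_img = img[rsl, csl]
        if not ring.any():
            dropped += 1
            continue
        bg = float(np.median(sub_img[ring]))
        raw = float(sub_img[comp].sum())
        rr, cc = np.nonzero(comp)
        w = sub_img[rr, cc] - bg
        wsum = w.sum()
        if wsum > 0:
            centroid = (
                float((rr * w).sum() / wsum) + rsl.start,
                float((cc * w).sum() / wsum) + csl.start,
            )
        else:
            centroid = (float(rr.mean()) + rsl.start, float(cc.mean()) + csl.start)
        records.append(
            PunctaRecord(
                molecule_id=mol_id,
                field_id=field_id,
                pixels=(rr + rsl.start, cc + csl.start),
                area=area,
                centroid=centroid,
                raw_integrated=raw,
                local_background_per_px=bg,
                adjusted_intensity=raw - area * bg,
            )
        )
        mol_id += 1
    if dropped:
        logger.info("%s: dropped %d components with empty background annulus", field_id, dropped)
    return records


def records_to_dataframe(records: List[PunctaRecord]) -> pd.DataFrame:
    """Flatten records to the per-molecule CSV table (pixels omitted)."""
    return pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "field_id": [r.field_id for r in records],
            "area": [r.area for r in records],
            "centroid_row": [r.centroid[0] for r in records],
            "centroid_col": [r.centroid[1] for r in records],
            "raw_integrated": [r.raw_integrated for r in records],
            "local_background_per_px": [r.local_background_per_px for r in records],
            "adjusted_intensity": [r.adjusted_intensity for r in records],
            "ch2_pcc": [r.ch2_pcc for r in records],
            "ch2_pvalue": [r.ch2_pvalue for r in records],
            "colocalized": [r.colocalized for r in records],
        }
    )
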