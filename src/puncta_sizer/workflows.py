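"""End-to-end workflows: image stack -> molecules -> calibration / analysis.

These functions tie the stages together in the order the method runs:
QC -> shading correction -> denoising -> dual-mask segmentation ->
background-adjusted intensities -> Gaussian population fits ->
calibration regression, and, for analysis runs, colocalization gating ->
background-histogram subtraction -> exact 1-D k-means population calls.
They are the substance behind the ``calibrate`` and ``analyze`` CLI
commands and are equally usable from Python on in-memory fields or
pre-extracted intensity tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import colocalize as _coloc
from . import populations as _pops
from . import preprocess as _pre
from . import segment as _seg
from . import sizing as _sizing
from .config import RunConfig
from .segment import PunctaRecord
from .sizing import CalibrationCurve, PopulationFit
from .synthetic import FieldImage

__all__ = [
    "CalibrationError",
    "extract_molecules",
    "calibrate_from_intensities",
    "calibrate_workflow",
    "analyze_workflow",
    "match_records_to_truth",
    "AnalysisReport",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """A calibration population could not be resolved; names the sizes."""


def extract_molecules(
    fields: Sequence[FieldImage],
    config: RunConfig,
) -> Tuple[List[PunctaRecord], List[_pre.QCReport], Dict[str, np.ndarray]]:
    """Run QC, shading correction, denoising and segmentation on a stack.

    Shading is estimated retrospectively from all QC-passing channel-1
    rasters.  Masks are computed on the denoised image; intensities are
    measured on the corrected (not denoised) image so the filter cannot
    bias the integrals.  Returns the molecule records, the QC reports,
    and the corrected channel images keyed by ``field_id`` (``_ch2``
    suffix for channel 2) for downstream colocalization.
    """
    reports = [_pre.qc_field(f.ch1, config.qc, f.field_id) for f in fields]
    passing = [f for f, r in zip(fields, reports) if r.passed]
    if not passing:
        raise RuntimeError("no field passed QC")
    shading = _pre.estimate_shading([f.ch1 for f in passing])
    seg = config.segmentation
    records: List[PunctaRecord] = []
    corrected: Dict[str, np.ndarray] = {}
    offset = 0
    for f in passing:
        ch1 = _pre.correct_shading(f.ch1, shading)
        ch2 = _pre.correct_shading(f.ch2, shading)
        corrected[f.field_id] = ch1
        corrected[f.field_id + "_ch2"] = ch2
        smooth = _pre.denoise(ch1, "median", size=3)
        mask = _seg.merge_masks(
            _seg.edge_mask(smooth),
            _seg.local_mask(smooth, seg.local_window, seg.local_k),
            min_area=seg.min_area,
            remove_border=seg.remove_border,
        )
        recs = _seg.label_and_measure(ch1, mask, seg, f.field_id, id_offset=offset)
        offset += len(recs)
        records.extend(recs)
    logger.info("extracted %d molecules from %d/%d fields", len(records), len(passing), len(fields))
    return records, reports, corrected


def calibrate_from_intensities(
    intensities: Sequence[float],
    known_sizes_bp: Sequence[int],
    config: RunConfig,
) -> Tuple[CalibrationCurve, List[PopulationFit]]:
    """Fit one Gaussian per calibration population and regress size on
    population mean intensity.

    Populations are matched to the known plasmid sizes by rank (both
    sorted ascending: brighter = larger).  If fewer resolvable peaks than
    known sizes are found, the failure names the sizes that could not be
    resolved; surplus peaks are discarded smallest-amplitude-first.
    """
    sizes = sorted(known_sizes_bp)
    if len(sizes) < (1 if config.sizing else 2):
        raise ValueError("need at least 2 known sizes")
    sz = config.sizing
    hist = _sizing.build_histogram(intensities, n_bins=sz.n_bins, source=config.condition)
    peaks = _sizing.find_peaks(hist, prominence_frac=sz.peak_prominence_frac)
    fits: List[PopulationFit] = []
    for peak in peaks:
        try:
            init = _sizing.init_gaussian(hist, peak)
            fits.append(
                _sizing.fit_population(
                    intensities,
                    init,
                    window_sigmas=sz.fit_window_sigmas,
                    min_molecules=sz.min_molecules,
                )
            )
        except (ValueError, _sizing.UnresolvedPeakError) as exc:
            logger.warning("peak at %g skipped: %s", peak, exc)
    if len(fits) < len(sizes):
        missing = sizes[len(fits):]
        raise CalibrationError(
            f"resolved {len(fits)} population(s) for {len(sizes)} known sizes; "
            f"unresolved size(s): {missing} bp"
        )
    if len(fits) > len(sizes):
        fits = sorted(fits, key=lambda f: f.amplitude, reverse=True)[: len(sizes)]
    fits = sorted(fits, key=lambda f: f.mean)
    points = [(f.mean, s) for f, s in zip(fits, sizes)]
    curve = _sizing.fit_calibration(
        points, through_origin=False, ci_level=sz.ci_level, condition=config.condition
    )
    for f, s in zip(fits, sizes):
        est = _sizing.intensity_to_size(curve, f.mean)
        f.size_bp = est.size_bp
        f.size_error_bp = est.error_bp
    return curve, fits


def calibrate_workflow(
    fields: Sequence[FieldImage],
    known_sizes_bp: Sequence[int],
    config: RunConfig,
) -> Tuple[CalibrationCurve, List[PopulationFit], pd.DataFrame]:
    """Image stack -> calibration curve (preprocess, segment, fit, regress)."""
    records, _, _ = extract_molecules(fields, config)
    table = _seg.records_to_dataframe(records)
    intensities = table["adjusted_intensity"].to_numpy()
    intensities = intensities[intensities > 0]
    curve, fits = calibrate_from_intensities(intensities, known_sizes_bp, config)
    return curve, fits, table


@dataclass
class AnalysisReport:
    """Everything the analyze workflow produces for one target sample."""

    target_table: pd.DataFrame
    background_table: pd.DataFrame
    difference: _pops.DifferenceHistogram
    calls: List[_pops.PopulationCall]
    coloc_target_pct: Optional[float] = None
    coloc_background_pct: Optional[float] = None
    notes: List[str] = field(default_factory=list)


def _classify_all(
    records: List[PunctaRecord], corrected: Dict[str, np.ndarray], config: RunConfig
) -> None:
    for rec in records:
        _coloc.classify(
            rec,
            corrected[rec.field_id],
            corrected[rec.field_id + "_ch2"],
            config.coloc,
        )


def analyze_workflow(
    target_fields: Sequence[FieldImage],
    background_fields: Sequence[FieldImage],
    curve: CalibrationCurve,
    config: RunConfig,
    coloc: bool = False,
) -> AnalysisReport:
    """Full target-vs-background analysis.

    Both samples run through the same extraction; with ``coloc`` the
    molecule sets are first gated to dCas9-colocalized records in each
    sample.  Histograms share bin edges, the background is rescaled to
    the target's field count, the residual is realized as bin-center
    intensities and clustered with exact 1-D k-means, and each cluster is
    sized through the calibration curve.
    """
    t_records, _, t_images = extract_molecules(target_fields, config)
    b_records, _, b_images = extract_molecules(background_fields, config)
    report_notes: List[str] = []
    coloc_t = coloc_b = None
    if coloc:
        _classify_all(t_records, t_images, config)
        _classify_all(b_records, b_images, config)
        coloc_t = 100.0 * np.mean([bool(r.colocalized) for r in t_records]) if t_records else 0.0
        coloc_b = 100.0 * np.mean([bool(r.colocalized) for r in b_records]) if b_records else 0.0
        t_used = [r for r in t_records if r.colocalized]
        b_used = [r for r in b_records if r.colocalized]
    else:
        t_used, b_used = t_records, b_records
    t_int = np.array([r.adjusted_intensity for r in t_used])
    b_int = np.array([r.adjusted_intensity for r in b_used])
    t_int = t_int[t_int > 0]
    b_int = b_int[b_int > 0]
    if t_int.size == 0:
        raise RuntimeError("no usable target molecules")
    hi = float(max(t_int.max(), b_int.max() if b_int.size else 0.0)) * 1.02
    sz = config.sizing
    t_hist = _sizing.build_histogram(t_int, sz.n_bins, (0.0, hi), source="target")
    if b_int.size == 0:
        report_notes.append("background sample empty after gating; no subtraction applied")
        b_hist = None
        diff = _pops.DifferenceHistogram(
            bin_edges=t_hist.bin_edges.copy(),
            residual=t_hist.counts.astype(float),
            bg_scale=0.0,
            clipped_mass=0.0,
            surviving_fraction=1.0,
            provenance=("target", "none"),
        )
    else:
        b_hist = _sizing.build_histogram(b_int, sz.n_bins, (0.0, hi), source="background")
        diff = _pops.subtract_background(
            t_hist, b_hist, target_fields=len(target_fields), bg_fields=len(background_fields)
        )
    try:
        values = _pops.residual_sample(diff)
        k = min(config.population_calling.k, values.size)
        calls = _pops.call_populations(
            values,
            k,
            curve,
            condition=config.condition,
            min_cluster_frac=config.population_calling.min_cluster_frac,
        )
    except ValueError:
        report_notes.append("residual empty: target indistinguishable from background")
        calls = []
    return AnalysisReport(
        target_table=_seg.records_to_dataframe(t_records),
        background_table=_seg.records_to_dataframe(b_records),
        difference=diff,
        calls=calls,
        coloc_target_pct=coloc_t,
        coloc_background_pct=coloc_b,
        notes=report_notes,
    )


def match_records_to_truth(
    records: Sequence[PunctaRecord],
    truths: pd.DataFrame,
    max_dist_px: float = 2.0,
) -> pd.DataFrame:
    """Greedy nearest-centroid matching of detected records to simulated
    ground truth within one field set; used to score recovery.

    Returns the truth table with ``matched`` plus the matched record's
    adjusted intensity and its relative error vs the true integral.
    """
    out = truths.copy().reset_index(drop=True)
    out["matched"] = False
    out["measured_intensity"] = np.nan
    for fid, group in out.groupby("field_id"):
        recs = [r for r in records if r.field_id == fid]
        if not recs:
            continue
        cents = np.array([r.centroid for r in recs])
        used = np.zeros(len(recs), dtype=bool)
        for idx, t in group.iterrows():
            d = np.linalg.norm(cents - np.array([t["row"], t["col"]]), axis=1)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= max_dist_px:
                used[j] = True
                out.loc[idx, "matched"] = True
                out.loc[idx, "measured_intensity"] = recs[j].adjusted_intensity
    out["rel_error"] = (out["measured_intensity"] - out["true_intensity"]) / out[
        "true_intensity"
    ]
    return out
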