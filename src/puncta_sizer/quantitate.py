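"""qPCR-derived copy-number, mass and surface-density arithmetic.

Ct values from a dilution series of a known plasmid give a standard
curve (Ct vs log10 copies); sample Ct values are converted to absolute
copies, gated against the no-template-control limit of detection, turned
into DNA mass (assuming a per-copy size in bp and an average 650 Da per
base pair), and finally into expected molecule densities on the imaging
surface — e.g. one vector per 15 um^2 corresponds to ~1000 vectors in a
1.5e4 um^2 field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "DensityEstimate",
    "AVOGADRO",
    "MEAN_BP_MASS_DA",
    "fit_standard_curve",
    "ct_to_copies",
    "lod_gate",
    "copies_to_mass_pg",
    "density_estimate",
    "amplification_efficiency",
    "summarize_conditions",
]

AVOGADRO = 6.02214076e23  # 1/mol
MEAN_BP_MASS_DA = 650.0  # g/mol per base pair of dsDNA (average)

#: Field of view implied by "one vector per 15 um^2 ~ 1000 per image"
DEFAULT_FIELD_AREA_UM2 = 1.5e4


@dataclass
class StandardCurve:
    slope: float  # Ct per log10 copies; negative for amplification
    intercept: float  # Ct at 1 copy
    r_squared: float
    copy_range: Tuple[float, float]  # (min, max) copies in the series

    @property
    def efficiency(self) -> float:
        """Amplification efficiency: 1.0 = perfect doubling per cycle
        (slope -log2(10) ~ -3.3219)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class DensityEstimate:
    copies: float
    mass_pg: float
    mass_fraction: float  # of the deposited sample mass
    density_per_um2: float
    expected_per_field: float


def fit_standard_curve(points: Sequence[Tuple[float, float]]) -> StandardCurve:
    """Least-squares line through (log10 copies, Ct) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (log10 copies, Ct) points")
    logc, ct = pts[:, 0], pts[:, 1]
    if np.ptp(logc) == 0:
        raise ValueError("degenerate series: all copy numbers equal")
    fit = stats.linregress(logc, ct)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        copy_range=(float(10.0 ** logc.min()), float(10.0 ** logc.max())),
    )


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: copies = 10**((Ct - intercept)/slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def amplification_efficiency(curve: StandardCurve) -> float:
    return curve.efficiency


def lod_gate(ct_values: Sequence[float], ntc_ct: float) -> List[bool]:
    """Flag conditions detectable above the no-template-control background.

    Lower Ct means more template, so a condition is included iff its Ct
    is strictly below the NTC's; a condition at or above the NTC Ct is
    indistinguishable from background and excluded.
    """
    if not math.isfinite(ntc_ct):
        raise ValueError("NTC Ct missing or non-finite")
    ct = np.asarray(list(ct_values), dtype=float)
    if not np.isfinite(ct).all():
        raise ValueError("non-finite Ct value")
    return [bool(c < ntc_ct) for c in ct]


def copies_to_mass_pg(
    copies: float, size_bp: float, mean_bp_mass_da: float = MEAN_BP_MASS_DA
) -> float:
    """DNA mass in picograms of ``copies`` molecules of ``size_bp`` length:
    copies x size_bp x (bp mass / Avogadro), in pg."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    grams = copies * size_bp * mean_bp_mass_da / AVOGADRO
    return grams * 1e12


def density_estimate(
    copies: float,
    deposition_area_um2: float,
    field_area_um2: float = DEFAULT_FIELD_AREA_UM2,
    size_bp: float = 2684.0,
    sample_mass_pg: float | None = None,
) -> DensityEstimate:
    """Surface density and per-field expectation for deposited molecules.

    ``copies / deposition_area`` gives the density per um^2; multiplying
    by the field of view's area gives the theoretical maximum number of
    molecules per image (every copy deposited, none lost).
    """
    if deposition_area_um2 <= 0 or field_area_um2 <= 0:
        raise ValueError("areas must be positive")
    density = copies / deposition_area_um2
    mass_pg = copies_to_mass_pg(copies, size_bp) if copies > 0 else 0.0
    return DensityEstimate(
        copies=float(copies),
        mass_pg=mass_pg,
        mass_fraction=(mass_pg / sample_mass_pg) if sample_mass_pg else float("nan"),
        density_per_um2=float(density),
        expected_per_field=float(density * field_area_um2),
    )


def summarize_conditions(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    ntc_ct: float,
    size_bp: float = 2684.0,
    sample_mass_pg: float | None = None,
    deposition_area_um2: float | None = None,
    field_area_um2: float = DEFAULT_FIELD_AREA_UM2,
) -> pd.DataFrame:
    """Per-condition copy/mass/density table from replicate Ct values.

    ``ct_table`` has columns ``condition`` and ``ct`` (one row per
    replicate).  Replicates are averaged per condition, gated against the
    no-template-control LoD, and the included conditions converted to
    copies, mass, optional mass fraction of the deposited sample, and —
    when a deposition area is given — the expected molecules per imaged
    field.  The full chain is reported even when inputs are mutually
    inconsistent, so discrepancies stay visible.
    """
    if not {"condition", "ct"} <= set(ct_table.columns):
        raise ValueError("ct_table needs 'condition' and 'ct' columns")
    mean_ct = ct_table.groupby("condition", sort=False)["ct"].mean()
    included = lod_gate(mean_ct.to_numpy(), ntc_ct)
    rows = []
    for (condition, ct), keep in zip(mean_ct.items(), included):
        copies = ct_to_copies(curve, float(ct)) if keep else float("nan")
        mass = copies_to_mass_pg(copies, size_bp) if keep else float("nan")
        rows.append(
            {
                "condition": condition,
                "mean_ct": float(ct),
                "included": keep,
                "copies": copies,
                "mass_pg": mass,
                "mass_fraction": (mass / sample_mass_pg)
                if keep and sample_mass_pg
                else float("nan"),
                "expected_per_field": (
                    copies / deposition_area_um2 * field_area_um2
                )
                if keep and deposition_area_um2
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
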