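"""Validated parameter types shared across the pipeline.

Every tunable of the simulation, preprocessing, segmentation, sizing,
colocalization and population-calling stages lives in one of the pydantic
models below, so a run is fully described by a single serializable
:class:`RunConfig` that can be echoed next to its outputs and replayed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PopulationSpec",
    "ImagingConfig",
    "QCConfig",
    "SegmentationConfig",
    "SizingConfig",
    "ColocThresholds",
    "PopulationsConfig",
    "RunConfig",
    "validate_fractions",
]


class _StrictModel(BaseModel):
    """Base for all configs: unknown keys are rejected, catching typos."""

    model_config = ConfigDict(extra="forbid")


class PopulationSpec(_StrictModel):
    """One DNA species in a simulated mixture.

    ``size_bp`` is the molecule length in base pairs; ``fraction`` its share
    of the mixture; ``intensity_cv`` the relative SD of the integrated
    YOYO-1 intensity of a single molecule (staining + photophysics
    variability); ``coloc_rate`` the probability that a molecule of this
    species carries a dCas9 (channel-2) spot.
    """

    size_bp: int = Field(gt=0)
    fraction: float = Field(ge=0.0, le=1.0)
    intensity_cv: float = Field(ge=0.0, default=0.05)
    coloc_rate: float = Field(ge=0.0, le=1.0, default=0.0)


def validate_fractions(populations: Sequence[PopulationSpec]) -> None:
    """Raise ``ValueError`` unless the population fractions sum to 1."""
    if not populations:
        raise ValueError("population list is empty")
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total!r}, expected 1")


class ImagingConfig(_StrictModel):
    """Virtual-microscope parameters for the synthetic field generator.

    The field area (``field_shape`` x ``pixel_area``) defaults to the
    ~1.5e4 um^2 per image implied by a maximal deposition of one vector per
    15 um^2 at ~1000 vectors per image; no direct pixel size is published,
    so this value is inferred and configurable.  ``em_gain_factor`` scales
    the shot-noise variance the way EM multiplication does
    (var = gain x signal); the exposure/EM-gain settings of the real
    camera are metadata only and do not enter the model.
    """

    field_shape: Tuple[int, int] = (512, 512)
    pixel_area: float = Field(gt=0.0, default=1.5e4 / (512 * 512))  # um^2, inferred
    psf_sigma: float = Field(gt=0.0, default=1.5)  # px
    intensity_per_bp: float = Field(ge=0.0, default=10.0)  # a.u. per bp, channel 1
    ch2_spot_intensity: float = Field(ge=0.0, default=3.0e4)  # a.u., integrated
    shading_amplitude: float = Field(ge=0.0, lt=1.0, default=0.15)
    background_level: float = Field(ge=0.0, default=200.0)  # a.u. per px
    read_noise_sd: float = Field(ge=0.0, default=10.0)  # a.u.
    em_gain_factor: float = Field(ge=0.0, default=2.0)  # 0 disables shot noise
    false_ch2_density: float = Field(ge=0.0, default=20.0)  # unattached spots/field
    seed: int = 0

    @model_validator(mode="after")
    def _check_shape(self) -> "ImagingConfig":
        rows, cols = self.field_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"field_shape must be positive, got {self.field_shape}")
        return self

    @property
    def field_area_um2(self) -> float:
        rows, cols = self.field_shape
        return rows * cols * self.pixel_area


class QCConfig(_StrictModel):
    """Automated surrogate for the manual focus/artifact inspection.

    Defaults are permissive; tighten ``focus_min`` for real data.
    ``exclude`` lists field ids to drop regardless of the metrics (the
    manual-override escape hatch).
    """

    focus_min: float = Field(ge=0.0, default=0.0)
    saturation_max: float = Field(ge=0.0, le=1.0, default=0.01)
    saturation_level: float = Field(gt=0.0, default=65535.0)
    exclude: Tuple[str, ...] = ()


class SegmentationConfig(_StrictModel):
    """Parameters of the edge + local-threshold puncta detector."""

    local_window: int = Field(gt=1, default=31)  # px, odd
    local_k: float = Field(gt=0.0, default=3.0)  # SD offset above local mean
    # the 3x3 median pre-filter correlates noise over ~3 px, so spurious
    # above-threshold clumps reach several pixels; real diffraction-limited
    # spots cover >= ~15 px, leaving a safe gap for this cutoff
    min_area: int = Field(ge=1, default=8)  # px
    measure_dilate: int = Field(ge=0, default=3)  # px added around the mask for integration
    annulus_gap: int = Field(ge=0, default=2)  # px between spot and background ring
    annulus_width: int = Field(ge=1, default=4)  # px
    remove_border: bool = True

    @model_validator(mode="after")
    def _odd_window(self) -> "SegmentationConfig":
        if self.local_window % 2 == 0:
            raise ValueError("local_window must be odd")
        return self


class SizingConfig(_StrictModel):
    """Histogramming, peak detection and Gaussian-fit parameters."""

    n_bins: int = Field(ge=3, default=100)
    peak_prominence_frac: float = Field(gt=0.0, le=1.0, default=0.05)
    fit_window_sigmas: float = Field(gt=0.0, default=2.0)
    min_molecules: int = Field(ge=3, default=20)
    ci_level: float = Field(gt=0.0, lt=1.0, default=0.99)


class ColocThresholds(_StrictModel):
    """PCC gate for calling a DNA punctum dCas9-colocalized."""

    pcc_min: float = Field(ge=-1.0, le=1.0, default=0.25)
    p_max: float = Field(gt=0.0, le=1.0, default=0.05)
    dilate_px: int = Field(ge=0, default=1)  # mask dilation before PCC


class PopulationsConfig(_StrictModel):
    """Background subtraction + 1-D k-means population calling."""

    k: int = Field(ge=1, default=2)
    min_cluster_frac: float = Field(ge=0.0, le=1.0, default=0.01)


class RunConfig(_StrictModel):
    """Complete description of one simulate/calibrate/analyze run."""

    workflow: Literal["simulate", "calibrate", "analyze"] = "simulate"
    populations: Tuple[PopulationSpec, ...] = ()
    imaging: ImagingConfig = ImagingConfig()
    qc: QCConfig = QCConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    sizing: SizingConfig = SizingConfig()
    coloc: ColocThresholds = ColocThresholds()
    population_calling: PopulationsConfig = PopulationsConfig()
    known_sizes_bp: Tuple[int, ...] = ()
    condition: str = "default"
    n_fields: int = Field(ge=1, default=10)
    molecules_per_field: float = Field(ge=0.0, default=120.0)
    seed: int = 0

    def to_json(self, path: Optional[Path] = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
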