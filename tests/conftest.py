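"""Shared fixtures: one synthetic calibration experiment reused across tests.

The calibration experiment mirrors the reference-plasmid design: a
three-plasmid mixture (2686, 5562, 12920 bp) imaged over enough fields
to give several hundred molecules per population.
"""

import numpy as np
import pytest

import puncta_sizer as ps

THREE_PLASMIDS = (2686, 5562, 12920)


@pytest.fixture(scope="session")
def three_plasmid_specs():
    return [
        ps.PopulationSpec(size_bp=s, fraction=1 / 3, intensity_cv=0.06)
        for s in THREE_PLASMIDS
    ]


@pytest.fixture(scope="session")
def calibration_experiment(three_plasmid_specs):
    """9 fields x ~120 molecules: >=300 molecules per population."""
    cfg = ps.RunConfig(seed=11, known_sizes_bp=THREE_PLASMIDS)
    imaging = ps.ImagingConfig(seed=11)
    fields, truth = ps.gen_experiment(three_plasmid_specs, imaging, 9, 120, seed=11)
    return fields, truth, cfg


@pytest.fixture(scope="session")
def calibration_result(calibration_experiment):
    fields, truth, cfg = calibration_experiment
    curve, fits, table = ps.calibrate_workflow(fields, list(THREE_PLASMIDS), cfg)
    return curve, fits, table


@pytest.fixture()
def quiet_field():
    """64x64 noise-free, shading-free field with one centered molecule."""
    import pandas as pd

    config = ps.ImagingConfig(
        field_shape=(64, 64),
        shading_amplitude=0.0,
        read_noise_sd=0.0,
        em_gain_factor=0.0,
        false_ch2_density=0.0,
    )
    truths = pd.DataFrame(
        {"row": [31.3], "col": [30.7], "true_intensity": [50000.0], "has_ch2": [False]}
    )
    field, truth = ps.gen_field(truths, config)
    return field, truth, config
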