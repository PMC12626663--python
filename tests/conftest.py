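"""Shared fixtures: small channel tables and synthetic cohorts.

All fixtures are generated programmatically; cohort fixtures are
session-scoped because rendering a multispectral cohort is the expensive
step shared by many tests.
"""

import numpy as np
import pandas as pd
import pytest

from autofluor.calibration import calibrate_block, fit_calibration
from autofluor.channels import ChannelSpec, ChannelTable, default_channel_table
from autofluor.features import extract_features
from autofluor.model import FeatureTable, masks_from_label_image
from autofluor.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def table34():
    return default_channel_table()


@pytest.fixture(scope="session")
def table4():
    """Tiny 4-channel table for fast unit tests."""
    bands = [(340, 420, 460), (370, 460, 500), (430, 540, 580), (490, 610, 650)]
    return ChannelTable([
        ChannelSpec(channel_id=f"Ex{e}Em{(lo + hi) // 2}", excitation_center_nm=e,
                    excitation_halfwidth_nm=5.0, emission_low_nm=lo,
                    emission_high_nm=hi, index=i)
        for i, (e, lo, hi) in enumerate(bands)
    ])


def small_two_group_config(seed=0, **overrides):
    """96x96 two-group cohort at the generator's spectral defaults."""
    kwargs = dict(
        groups=("A", "B"),
        patients_per_group=2,
        cells_per_patient=(4, 4),
        abundance_means={"A": {"NADH-like": 130.0, "FAD-like": 55.0},
                         "B": {"NADH-like": 95.0, "FAD-like": 80.0}},
        field_shape=(96, 96),
        cell_radius_px=(8.0, 13.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def cohort_feature_table(cfg, catalog=None):
    """Full chain: generate -> calibrate -> extract; returns (FeatureTable, Cohort)."""
    cohort = generate_cohort(cfg)
    model = fit_calibration(cohort.reference, cohort.channel_table)
    frames = []
    for block in cohort.blocks:
        cal = calibrate_block(block, model)
        label = cohort.label_images[block.sample_id]
        masks = masks_from_label_image(
            label, cell_ids=[f"{block.patient_id}_c{i + 1:02d}"
                             for i in range(int(label.max()))])
        frames.append(extract_features(cal, masks, catalog=catalog).data)
    return FeatureTable(pd.concat(frames, ignore_index=True)), cohort


@pytest.fixture(scope="session")
def mini_cohort():
    return generate_cohort(small_two_group_config(seed=11))


@pytest.fixture(scope="session")
def mini_features():
    table, cohort = cohort_feature_table(small_two_group_config(seed=11))
    return table, cohort
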