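"""Validation benchmark scenarios with analytically known answers.

These configurations exercise the pipeline under controlled conditions:

* ``planted_effect_config`` - two groups identical except for a 2x abundance
  shift of a narrow-band marker fluorophore, chosen so that exactly three
  channels are informative at the default relative margin; feature selection
  should recover those channels' mean features.
* ``null_cohort_config`` - two groups with identical generative parameters;
  any classifier should score near chance.
* ``leakage_cohort_config`` - no group effect but strong per-patient spectral
  signatures; cell-level cross-validation with global feature selection
  inflates the AUC that patient-grouped cross-validation reports honestly.
* ``gaussian_shift_table`` - a one-feature class shift of delta between two
  unit-variance Gaussians, whose true AUC is Phi(delta / sqrt(2)) in closed
  form.

Cohort fields are 96x96 px with proportionally small cells so the scenarios
run quickly; spectral structure, noise model and channel count match the
full-scale generator.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import FeatureTable
from .synthetic import CohortConfig, Fluorophore

#: Baseline endogenous fluorophores shared by both benchmark groups.
_BASELINE = (
    Fluorophore("NADH-like", 350.0, 45.0, 460.0, 50.0),
    Fluorophore("FAD-like", 450.0, 45.0, 535.0, 50.0),
)

#: Three narrow-band markers, each concentrated in exactly one channel of a
#: different spectral region (Ex370Em480, Ex430Em560, Ex490Em630).  Widths
#: are chosen so excitation leakage into neighbouring excitation lines and
#: emission leakage into adjacent bands stay below the informativeness
#: margin, and each marker varies independently from cell to cell, so the
#: three informative channel means are not mutually redundant.
PLANTED_MARKERS = (
    Fluorophore("marker-blue", 370.0, 10.0, 480.0, 15.0),
    Fluorophore("marker-green", 430.0, 10.0, 560.0, 11.0),
    Fluorophore("marker-red", 490.0, 6.0, 645.0, 10.0),
)

_SMALL_FIELD = dict(field_shape=(96, 96), cell_radius_px=(8.0, 13.0))


def planted_effect_config(seed: int = 0) -> CohortConfig:
    """Two groups differing only by a 2x shift of three planted markers.

    With marker abundances 20 (group A) vs 40 (group B) over the shared
    baseline, exactly three channels exceed the 10% relative margin:
    Ex370Em480, Ex430Em560 and Ex490Em630.
    """
    base = {"NADH-like": 120.0, "FAD-like": 60.0}
    marker_a = {m.name: 20.0 for m in PLANTED_MARKERS}
    marker_b = {m.name: 40.0 for m in PLANTED_MARKERS}
    return CohortConfig(
        groups=("A", "B"),
        patients_per_group=3,
        cells_per_patient=(6, 6),
        fluorophores=_BASELINE + PLANTED_MARKERS,
        abundance_means={
            "A": {**base, **marker_a},
            "B": {**base, **marker_b},
        },
        abundance_cv=0.2,
        patient_effect_sd=0.05,
        seed=seed,
        **_SMALL_FIELD,
    )


def null_cohort_config(seed: int = 0, patients_per_group: int = 5,
                       cells_per_patient: Tuple[int, int] = (10, 10)) -> CohortConfig:
    """Two groups drawn from identical generative parameters, exchangeable
    cells (~50 + 50).

    The patient random effect is switched off here so the null isolates
    classifier calibration: with only a handful of patients per group, a
    realised patient effect creates genuine in-sample group differences,
    which is the separate phenomenon ``leakage_cohort_config`` demonstrates.
    """
    base = {"NADH-like": 110.0, "FAD-like": 70.0}
    return CohortConfig(
        groups=("A", "B"),
        patients_per_group=patients_per_group,
        cells_per_patient=cells_per_patient,
        fluorophores=_BASELINE,
        abundance_means={"A": dict(base), "B": dict(base)},
        patient_effect_sd=0.0,
        field_shape=(128, 128),
        cell_radius_px=(7.0, 11.0),
        seed=seed,
    )


def leakage_cohort_config(seed: int = 0) -> CohortConfig:
    """No group effect, strong patient random effects (log-normal sigma 0.4):
    cells within a patient share a spectral signature that a cell-level CV
    can memorise."""
    base = {"NADH-like": 110.0, "FAD-like": 70.0}
    return CohortConfig(
        groups=("A", "B"),
        patients_per_group=4,
        cells_per_patient=(6, 6),
        fluorophores=_BASELINE,
        abundance_means={"A": dict(base), "B": dict(base)},
        patient_effect_sd=0.4,
        abundance_cv=0.1,
        seed=seed,
        **_SMALL_FIELD,
    )


def gaussian_shift_table(delta: float = 2.0, n_per_class: int = 60,
                         seed: int = 0) -> FeatureTable:
    """One-feature benchmark: class A ~ N(0,1), class B ~ N(delta,1).

    The population AUC of the feature itself is ``Phi(delta / sqrt(2))``
    (probability one N(delta,1) draw exceeds an independent N(0,1) draw).
    """
    rng = np.random.default_rng(seed)
    x_a = rng.normal(0.0, 1.0, n_per_class)
    x_b = rng.normal(delta, 1.0, n_per_class)
    data = pd.DataFrame({
        "cell_id": [f"a{i:03d}" for i in range(n_per_class)]
                   + [f"b{i:03d}" for i in range(n_per_class)],
        "patient_id": [f"pa{i % 6}" for i in range(n_per_class)]
                      + [f"pb{i % 6}" for i in range(n_per_class)],
        "group_label": ["A"] * n_per_class + ["B"] * n_per_class,
        "shift_feature": np.concatenate([x_a, x_b]),
    })
    return FeatureTable(data)


def gaussian_shift_expected_auc(delta: float) -> float:
    return float(norm.cdf(delta / np.sqrt(2.0)))
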