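"""Synthetic multispectral cohort generator with known ground truth.

Emulates the acquisition upstream of the analysis: elliptical cells whose
autofluorescence is a mixture of Gaussian-profile fluorophores (NADH-like,
FAD-like by default), imaged through the 34-channel excitation/emission
grid with

* a radial-quadratic uneven illumination field shared by all channels,
* per-channel background fluorescence (also subject to the illumination),
* Poisson shot noise, dead pixels (shared across channels, as camera
  defects are) and saturated pixels (per channel),
* a per-patient log-normal abundance multiplier creating within-patient
  correlation, and per-cell log-normal abundance variation,
* mild smooth multiplicative intra-cell texture so SD/skewness features
  are non-degenerate.

Reference data (water frames, calibration-fluid frames and the
spectrofluorometer spectrum of the fluid) are generated consistently so
the full calibration chain is testable against ground truth.

All randomness flows from ``CohortConfig.seed``; identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm
from skimage.draw import ellipse as draw_ellipse

from .channels import ChannelSpec, ChannelTable, default_channel_table
from .errors import CrowdedFieldError, ValidationError
from .io import write_data_block, write_masks, write_reference_set
from .model import DataBlock, ReferenceSet


@dataclass(frozen=True)
class Fluorophore:
    """Gaussian excitation/emission profile of one native fluorophore."""

    name: str
    excitation_center_nm: float
    excitation_width_nm: float    # Gaussian sigma
    emission_center_nm: float
    emission_width_nm: float      # Gaussian sigma
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.excitation_width_nm <= 0 or self.emission_width_nm <= 0:
            raise ValidationError(f"fluorophore {self.name!r}: widths must be positive")
        if self.brightness < 0:
            raise ValidationError(f"fluorophore {self.name!r}: brightness must be nonnegative")


def channel_response(f: Fluorophore, c: ChannelSpec) -> float:
    """Deterministic response of fluorophore ``f`` in channel ``c``.

    Separable model: Gaussian excitation efficiency at the channel's
    excitation center times the mass of the (unit-normalised) Gaussian
    emission profile falling inside the emission bandpass, scaled by
    brightness.  Additive over any partition of the emission axis.
    """
    exc = math.exp(-0.5 * ((c.excitation_center_nm - f.excitation_center_nm)
                           / f.excitation_width_nm) ** 2)
    em = (norm.cdf(c.emission_high_nm, f.emission_center_nm, f.emission_width_nm)
          - norm.cdf(c.emission_low_nm, f.emission_center_nm, f.emission_width_nm))
    return float(f.brightness * exc * em)


def response_matrix(fluorophores: Sequence[Fluorophore],
                    table: ChannelTable) -> np.ndarray:
    """(n_fluorophores, n_channels) matrix of channel responses."""
    return np.array([[channel_response(f, c) for c in table] for f in fluorophores])


#: Default endogenous fluorophores (NADH: ex~350/em~460; FAD: ex~450/em~535).
DEFAULT_FLUOROPHORES = (
    Fluorophore("NADH-like", 350.0, 45.0, 460.0, 50.0),
    Fluorophore("FAD-like", 450.0, 45.0, 535.0, 50.0),
)

#: Weak broadband component of the calibration fluid (solvent/optics
#: baseline) keeping the reference spectrum positive on every channel.
CALIBRATION_BASELINE = Fluorophore("broadband-baseline", 425.0, 300.0, 535.0, 300.0)

#: Calibration-fluid composition in abundance units (30 NADH : 18 FAD,
#: mirroring the 30 uM / 18 uM mixture) plus the broadband baseline.
DEFAULT_CALIBRATION_ABUNDANCES = {"NADH-like": 30.0, "FAD-like": 18.0,
                                  "broadband-baseline": 5.0}

#: Group-mean fluorophore abundances.  The three groups differ in their
#: NADH/FAD balance (a redox-ratio-like shift): the acute-injury group is
#: most displaced from the rejection group, the chronic-scarring group sits
#: between them, so pairwise separability is graded.
DEFAULT_ABUNDANCE_MEANS = {
    "ATN": {"NADH-like": 130.0, "FAD-like": 55.0},
    "REJECTION": {"NADH-like": 95.0, "FAD-like": 80.0},
    "IFTA": {"NADH-like": 115.0, "FAD-like": 65.0},
}


@dataclass
class CohortConfig:
    """Study-scale synthetic cohort: 3 groups x 10 patients, ~5 cells each
    (~160 cells), 1024x1024 fields, 34 channels."""

    groups: Tuple[str, ...] = ("ATN", "REJECTION", "IFTA")
    patients_per_group: int = 10
    cells_per_patient: Tuple[int, int] = (3, 8)          # inclusive range
    fluorophores: Tuple[Fluorophore, ...] = DEFAULT_FLUOROPHORES
    abundance_means: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_ABUNDANCE_MEANS.items()})
    abundance_cv: float = 0.2
    patient_effect_sd: float = 0.15                      # log-normal sigma
    illumination_gradient: float = 0.3                   # relative corner falloff
    background_level: float = 20.0                       # counts per pixel
    dead_pixel_rate: float = 2e-4
    saturated_pixel_rate: float = 1e-4
    full_well: int = 65535
    field_shape: Tuple[int, int] = (1024, 1024)
    cell_radius_px: Tuple[float, float] = (40.0, 80.0)   # major semi-axis range
    texture_sd: float = 0.10
    texture_smooth_px: float = 6.0
    calibration_abundances: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_ABUNDANCES))
    calibration_gain: float = 60.0                       # counts per reference unit
    informative_margin: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.dead_pixel_rate, self.saturated_pixel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("pixel defect rates must lie in [0, 1]")
        if self.full_well <= self.background_level:
            raise ValidationError("full_well must exceed background_level")
        if self.cells_per_patient[0] > self.cells_per_patient[1]:
            raise ValidationError("cells_per_patient range is inverted")
        for g in self.groups:
            if g not in self.abundance_means:
                raise ValidationError(f"no abundance means for group {g!r}")

    def fluorophore_names(self) -> List[str]:
        return [f.name for f in self.fluorophores]

    def calibration_fluorophores(self) -> List[Fluorophore]:
        by_name = {f.name: f for f in self.fluorophores}
        by_name.setdefault(CALIBRATION_BASELINE.name, CALIBRATION_BASELINE)
        return [by_name[n] for n in self.calibration_abundances]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fluorophores"] = [dataclasses.asdict(f) for f in self.fluorophores]
        return d


@dataclass
class GroundTruth:
    """What the generator knows: per-cell abundances, the illumination
    field, and which channels are informative for each group pair."""

    cells: pd.DataFrame            # cell_id, patient_id, group_label, abundance_<f>
    illumination: np.ndarray
    informative_channels: Dict[str, List[str]]
    margin: float

    def to_json_dict(self) -> dict:
        return {
            "cells": self.cells.to_dict(orient="records"),
            "informative_channels": self.informative_channels,
            "margin": self.margin,
        }


@dataclass
class Cohort:
    config: CohortConfig
    channel_table: ChannelTable
    blocks: List[DataBlock]
    label_images: Dict[str, np.ndarray]          # keyed by sample_id
    reference: ReferenceSet
    ground_truth: GroundTruth
    labels: pd.DataFrame                          # cell_id, patient_id, group_label, sample_id

    @property
    def n_cells(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------

def illumination_field(shape: Tuple[int, int], gradient: float) -> np.ndarray:
    """Radial quadratic falloff: 1 at the field center, 1-gradient at the corner."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2max = cy ** 2 + cx ** 2
    return 1.0 - gradient * r2 / r2max


def expected_group_spectrum(cfg: CohortConfig, table: ChannelTable,
                            group: str) -> np.ndarray:
    """Expected background-free cell signal per channel for a group."""
    resp = response_matrix(cfg.fluorophores, table)
    means = np.array([cfg.abundance_means[group][f.name] for f in cfg.fluorophores])
    return means @ resp


def informative_channels(cfg: CohortConfig, table: ChannelTable,
                         group_a: str, group_b: str,
                         margin: Optional[float] = None) -> List[str]:
    """Channels whose expected cell signal differs between two groups by more
    than ``margin`` relative to the larger of the two expectations.
    Deterministic closed form from the config."""
    margin = cfg.informative_margin if margin is None else margin
    mu_a = expected_group_spectrum(cfg, table, group_a)
    mu_b = expected_group_spectrum(cfg, table, group_b)
    hi = np.maximum(mu_a, mu_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(hi > 0, np.abs(mu_a - mu_b) / hi, 0.0)
    return [cid for cid, r in zip(table.channel_ids, rel) if r > margin]


def _smooth_texture(shape: Tuple[int, int], sd: float, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative texture field with spatial scale ``scale`` px."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    s = noise.std()
    if s > 0:
        noise *= sd / s
    return np.clip(1.0 + noise, 0.05, None)


def _place_cells(shape: Tuple[int, int], n_cells: int,
                 radius_range: Tuple[float, float],
                 rng: np.random.Generator,
                 max_tries_per_cell: int = 200) -> np.ndarray:
    """Rejection-sampled non-overlapping elliptical cells; returns label image."""
    h, w = shape
    label = np.zeros(shape, dtype=np.uint16)
    lo, hi = radius_range
    placed = 0
    tries = 0
    budget = max_tries_per_cell * max(n_cells, 1)
    while placed < n_cells:
        if tries >= budget:
            raise CrowdedFieldError(
                f"field too crowded: placed {placed}/{n_cells} cells "
                f"after {tries} tries"
            )
        tries += 1
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.6, 1.0)
        cy = rng.uniform(a, h - 1 - a)
        cx = rng.uniform(a, w - 1 - a)
        angle = rng.uniform(0.0, np.pi)
        # check with a 2 px guard band so neighbouring cells stay disjoint
        gr, gc = draw_ellipse(cy, cx, a + 2, b + 2, shape=shape, rotation=angle)
        if label[gr, gc].any():
            continue
        rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=angle)
        if rr.size == 0:
            continue
        placed += 1
        label[rr, cc] = placed
    return label


def _cell_abundances(cfg: CohortConfig, group: str,
                     patient_mult: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-cell abundance vector: group mean x patient multiplier x cell-level
    log-normal variation at coefficient of variation ``abundance_cv``."""
    means = np.array([cfg.abundance_means[group][f.name] for f in cfg.fluorophores])
    cv = cfg.abundance_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        cell_mult = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                                  size=means.size)
    else:
        cell_mult = np.ones_like(means)
    return means * patient_mult * cell_mult


def render_block(cfg: CohortConfig, table: ChannelTable, patient_id: str,
                 group: str, n_cells: int, rng: np.random.Generator,
                 patient_mult: Optional[np.ndarray] = None,
                 sample_id: Optional[str] = None
                 ) -> Tuple[DataBlock, np.ndarray, pd.DataFrame]:
    """Render one data block.

    Expected pixel value in channel ``c`` inside cell ``k``::

        illum(x, y) * (background + texture(x, y) * sum_f a_kf * response(f, c))

    with Poisson shot noise, then dead pixels forced to 0 and saturated
    pixels to ``full_well``.  Outside cells only background remains.
    Returns the block, its label image, and a per-cell ground-truth frame
    (cell_id + true abundances).
    """
    if patient_mult is None:
        patient_mult = np.ones(len(cfg.fluorophores))
    sample_id = sample_id or f"{patient_id}_block0"
    shape = cfg.field_shape
    illum = illumination_field(shape, cfg.illumination_gradient)
    label = _place_cells(shape, n_cells, cfg.cell_radius_px, rng)
    texture = _smooth_texture(shape, cfg.texture_sd, cfg.texture_smooth_px, rng)

    resp = response_matrix(cfg.fluorophores, table)       # (F, C)
    cell_rows = []
    abund = np.zeros((n_cells, len(cfg.fluorophores)))
    for k in range(n_cells):
        abund[k] = _cell_abundances(cfg, group, patient_mult, rng)
        cell_rows.append({"cell_id": f"{patient_id}_c{k + 1:02d}",
                          "patient_id": patient_id, "group_label": group,
                          **{f"abundance_{f.name}": abund[k, i]
                             for i, f in enumerate(cfg.fluorophores)}})
    spectra = abund @ resp                                # (K, C)

    masks = [np.nonzero(label == k + 1) for k in range(n_cells)]
    dead = rng.random(shape) < cfg.dead_pixel_rate        # camera defects: shared
    images = {}
    for ci, cid in enumerate(table.channel_ids):
        signal = np.zeros(shape)
        for k, (rr, cc) in enumerate(masks):
            signal[rr, cc] = spectra[k, ci] * texture[rr, cc]
        expected = illum * (cfg.background_level + signal)
        observed = rng.poisson(expected).astype(np.int64)
        saturated = rng.random(shape) < cfg.saturated_pixel_rate
        observed[dead] = 0
        observed[saturated] = cfg.full_well
        np.minimum(observed, cfg.full_well, out=observed)
        images[cid] = observed.astype(np.uint16)

    # brightfield: bright background, cells slightly darker (morphology only)
    bf_expected = 1000.0 * illum * np.where(label > 0, 0.8, 1.0)
    brightfield = np.minimum(rng.poisson(bf_expected), cfg.full_well).astype(np.uint16)

    block = DataBlock(sample_id=sample_id, patient_id=patient_id,
                      group_label=group, channel_images=images,
                      brightfield=brightfield, channel_table=table)
    return block, label, pd.DataFrame(cell_rows)


def reference_spectrum(cfg: CohortConfig, table: ChannelTable) -> np.ndarray:
    """Spectrofluorometer spectrum R_c of the calibration fluid (exact)."""
    fluors = cfg.calibration_fluorophores()
    resp = response_matrix(fluors, table)
    ab = np.array([cfg.calibration_abundances[f.name] for f in fluors])
    return ab @ resp


def render_reference_set(cfg: CohortConfig, table: ChannelTable,
                         rng: np.random.Generator) -> ReferenceSet:
    """Water and calibration-fluid frames plus the exact reference spectrum.

    Water frames are ``Poisson(background * illum)``; calibration frames are
    ``Poisson((background + R_c * gain) * illum)``.
    """
    shape = cfg.field_shape
    illum = illumination_field(shape, cfg.illumination_gradient)
    r = reference_spectrum(cfg, table)
    background, calibration = {}, {}
    for ci, cid in enumerate(table.channel_ids):
        water = rng.poisson(cfg.background_level * illum)
        calib = rng.poisson((cfg.background_level + r[ci] * cfg.calibration_gain) * illum)
        background[cid] = np.minimum(water, cfg.full_well).astype(np.uint16)
        calibration[cid] = np.minimum(calib, cfg.full_well).astype(np.uint16)
    return ReferenceSet(
        background_images=background,
        calibration_images=calibration,
        reference_values={cid: float(r[ci]) for ci, cid in enumerate(table.channel_ids)},
        dark_offset={cid: 0.0 for cid in table.channel_ids},
    )


def generate_cohort(cfg: CohortConfig,
                    table: Optional[ChannelTable] = None) -> Cohort:
    """Generate the full synthetic cohort: one block per patient, shared
    reference set, ground truth and a labels frame.  Deterministic under
    ``cfg.seed``."""
    table = table or default_channel_table()
    rng = np.random.default_rng(cfg.seed)
    reference = render_reference_set(cfg, table, rng)

    sigma_p = cfg.patient_effect_sd
    blocks: List[DataBlock] = []
    label_images: Dict[str, np.ndarray] = {}
    cell_frames = []
    label_rows = []
    for group in cfg.groups:
        for p in range(cfg.patients_per_group):
            patient_id = f"{group}_p{p + 1:02d}"
            if sigma_p > 0:
                pm = rng.lognormal(mean=-0.5 * sigma_p ** 2, sigma=sigma_p,
                                   size=len(cfg.fluorophores))
            else:
                pm = np.ones(len(cfg.fluorophores))
            n_cells = int(rng.integers(cfg.cells_per_patient[0],
                                       cfg.cells_per_patient[1] + 1))
            block, label, cells = render_block(cfg, table, patient_id, group,
                                               n_cells, rng, patient_mult=pm)
            blocks.append(block)
            label_images[block.sample_id] = label
            cell_frames.append(cells)
            for cid in cells["cell_id"]:
                label_rows.append({"cell_id": cid, "patient_id": patient_id,
                                   "group_label": group,
                                   "sample_id": block.sample_id})

    cells_df = pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame()
    groups = list(cfg.groups)
    informative = {
        f"{a}|{b}": informative_channels(cfg, table, a, b)
        for i, a in enumerate(groups) for b in groups[i + 1:]
    }
    gt = GroundTruth(
        cells=cells_df,
        illumination=illumination_field(cfg.field_shape, cfg.illumination_gradient),
        informative_channels=informative,
        margin=cfg.informative_margin,
    )
    labels = pd.DataFrame(label_rows)
    return Cohort(config=cfg, channel_table=table, blocks=blocks,
                  label_images=label_images, reference=reference,
                  ground_truth=gt, labels=labels)


# -- cohort directory layout -------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> Path:
    """Write the cohort in the on-disk layout the CLI consumes::

        <dir>/blocks/<sample_id>/   (TIFFs + manifest)
        <dir>/masks/<sample_id>.tif
        <dir>/references/
        <dir>/ground_truth.json
        <dir>/labels.csv
        <dir>/channel_table.json
    """
    directory = Path(directory)
    (directory / "blocks").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(exist_ok=True)
    for block in cohort.blocks:
        write_data_block(block, directory / "blocks" / block.sample_id)
        write_masks(cohort.label_images[block.sample_id],
                    directory / "masks" / f"{block.sample_id}.tif")
    write_reference_set(cohort.reference, directory / "references")
    gt = cohort.ground_truth.to_json_dict()
    (directory / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))
    cohort.labels.to_csv(directory / "labels.csv", index=False)
    cohort.channel_table.save(directory / "channel_table.json")
    return directory
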