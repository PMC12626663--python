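"""Per-cell spectral feature extraction from calibrated blocks.

Four feature families over the C channels of the acquisition:

* ``mean``  - arithmetic mean intensity over the mask pixels (C features),
* ``sd``    - population (divisor-n) standard deviation (C features),
* ``skew``  - Fisher-Pearson g1 = m3 / m2^{3/2}, population moments,
  defined as 0 when the variance vanishes (C features),
* ``ratio`` - ordered channel-mean ratios (mean_i + eps)/(mean_j + eps)
  for every ordered pair i != j (C(C-1) features).

Total: 3C + C(C-1) features; 1224 for the default 34-channel table.  The
catalog is explicit and configurable, so subsets of families can be used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import CellMask, DataBlock, FeatureTable

ALL_FAMILIES = ("mean", "sd", "skew", "ratio")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered descriptors of the per-cell features to compute."""

    channel_ids: Tuple[str, ...]
    families: Tuple[str, ...] = ALL_FAMILIES

    def __post_init__(self) -> None:
        bad = [f for f in self.families if f not in ALL_FAMILIES]
        if bad:
            raise ValidationError(f"unknown feature families: {bad}")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("catalog channel ids must be unique")

    @property
    def total_count(self) -> int:
        c = len(self.channel_ids)
        n = 0
        for fam in self.families:
            n += c * (c - 1) if fam == "ratio" else c
        return n

    def column_names(self) -> List[str]:
        names: List[str] = []
        for fam in self.families:
            if fam == "ratio":
                names.extend(f"ratio_{i}_over_{j}"
                             for i in self.channel_ids
                             for j in self.channel_ids if j != i)
            else:
                names.extend(f"{fam}_{cid}" for cid in self.channel_ids)
        return names

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"channel_ids": list(self.channel_ids), "families": list(self.families)},
            indent=2))

    @classmethod
    def from_json(cls, path) -> "FeatureCatalog":
        d = json.loads(Path(path).read_text())
        return cls(channel_ids=tuple(d["channel_ids"]),
                   families=tuple(d["families"]))


def cell_channel_stats(image: np.ndarray, mask: CellMask) -> Tuple[float, float, float]:
    """(mean, population SD, Fisher-Pearson g1 skewness) over the mask pixels.

    Zero-variance pixel sets have skewness 0 by convention.
    """
    if not mask.in_bounds(image.shape):
        raise ValidationError(f"mask {mask.cell_id!r} outside image bounds")
    vals = np.asarray(image, dtype=float)[mask.rows, mask.cols]
    return _moments(vals)


def _moments(vals: np.ndarray) -> Tuple[float, float, float]:
    mean = vals.mean()
    centered = vals - mean
    m2 = (centered ** 2).mean()
    if m2 == 0.0:
        return float(mean), 0.0, 0.0
    m3 = (centered ** 3).mean()
    return float(mean), float(np.sqrt(m2)), float(m3 / m2 ** 1.5)


def channel_ratio(mean_i: float, mean_j: float, eps: float) -> float:
    """eps-regularised directional ratio of two calibrated channel means."""
    return (mean_i + eps) / (mean_j + eps)


def default_eps(block: DataBlock) -> float:
    """Default ratio regulariser: 1e-6 x global mean intensity of the block."""
    return 1e-6 * float(block.image_stack().mean())


def extract_features(block: DataBlock, masks: Sequence[CellMask],
                     catalog: Optional[FeatureCatalog] = None,
                     eps: Optional[float] = None,
                     require_calibrated: bool = True) -> FeatureTable:
    """One feature row per cell mask; columns follow the catalog order.

    Masks reaching outside the image are skipped with a warning and listed
    under ``metadata['rejects']``.  The regulariser ``eps`` used for ratios
    is recorded in the table metadata.
    """
    if require_calibrated and not block.calibrated:
        raise ValidationError(
            f"block {block.sample_id!r} is not calibrated; calibrate first or pass "
            "require_calibrated=False"
        )
    catalog = catalog or FeatureCatalog(channel_ids=block.channel_table.channel_ids)
    unknown = [c for c in catalog.channel_ids if c not in block.channel_table.channel_ids]
    if unknown:
        raise ValidationError(f"catalog channels absent from block: {unknown}")
    if eps is None:
        eps = default_eps(block)

    stack = np.stack([np.asarray(block.channel_images[cid], dtype=float)
                      for cid in catalog.channel_ids])     # (C, H, W)
    c = len(catalog.channel_ids)
    rows = []
    rejects = []
    for mask in masks:
        if not mask.in_bounds(block.pixel_shape):
            warnings.warn(f"mask {mask.cell_id!r} outside block bounds; cell skipped")
            rejects.append(mask.cell_id)
            continue
        pix = stack[:, mask.rows, mask.cols]               # (C, n)
        mean = pix.mean(axis=1)
        centered = pix - mean[:, None]
        m2 = (centered ** 2).mean(axis=1)
        sd = np.sqrt(m2)
        m3 = (centered ** 3).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        row: dict = {"cell_id": mask.cell_id, "patient_id": block.patient_id,
                     "group_label": block.group_label}
        values: List[float] = []
        for fam in catalog.families:
            if fam == "mean":
                values.extend(mean)
            elif fam == "sd":
                values.extend(sd)
            elif fam == "skew":
                values.extend(skew)
            else:  # ratio, ordered pairs in catalog order
                reg = mean + eps
                ratio = reg[:, None] / reg[None, :]        # (i, j) -> mean_i / mean_j
                values.extend(ratio[i, j] for i in range(c) for j in range(c) if j != i)
        rows.append((row, values))

    names = catalog.column_names()
    data = pd.DataFrame(
        [{**meta, **dict(zip(names, vals))} for meta, vals in rows],
        columns=list(FeatureTable.REQUIRED_COLUMNS) + names,
    )
    return FeatureTable(data, feature_names=names,
                        metadata={"eps": float(eps), "rejects": rejects,
                                  "families": list(catalog.families)})
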