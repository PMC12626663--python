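"""Core in-memory data model: data blocks, cell masks, references, feature tables.

A *data block* is the full set of per-channel fluorescence images plus one
brightfield image for a single sample area.  Cells are delineated by masks
drawn on the brightfield image and stored as a single label image per block
(0 = background, each positive integer = one cell), which guarantees
disjointness by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .channels import ChannelTable
from .errors import GeometryError, ValidationError

GROUP_LABELS = ("ATN", "REJECTION", "IFTA")


@dataclass
class DataBlock:
    """Per-sample stack of channel images + brightfield."""

    sample_id: str
    patient_id: str
    group_label: str
    channel_images: Dict[str, np.ndarray]
    brightfield: np.ndarray
    channel_table: ChannelTable
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        table_ids = set(self.channel_table.channel_ids)
        block_ids = set(self.channel_images)
        if table_ids != block_ids:
            missing = sorted(table_ids - block_ids)
            extra = sorted(block_ids - table_ids)
            raise ValidationError(
                f"block {self.sample_id!r}: channel set differs from channel table "
                f"(missing={missing}, unexpected={extra})"
            )
        shape = self.brightfield.shape
        if self.brightfield.ndim != 2:
            raise GeometryError(f"block {self.sample_id!r}: brightfield must be 2-D")
        for cid, img in self.channel_images.items():
            if img.shape != shape:
                raise GeometryError(
                    f"block {self.sample_id!r}: channel {cid!r} shape {img.shape} "
                    f"differs from brightfield shape {shape}"
                )

    @property
    def pixel_shape(self) -> Tuple[int, int]:
        return self.brightfield.shape  # type: ignore[return-value]

    def image_stack(self) -> np.ndarray:
        """Channel images stacked (C, H, W) in channel-table order."""
        return np.stack([self.channel_images[cid] for cid in self.channel_table.channel_ids])


@dataclass
class CellMask:
    """Pixel support of one segmented cell, referencing a block's geometry."""

    cell_id: str
    rows: np.ndarray
    cols: np.ndarray
    shape: Tuple[int, int]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.size == 0:
            raise ValidationError(f"mask {self.cell_id!r} is empty")
        if self.rows.size != self.cols.size:
            raise ValidationError(f"mask {self.cell_id!r}: row/col index length mismatch")

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    def in_bounds(self, shape: Tuple[int, int]) -> bool:
        return bool(
            (self.rows >= 0).all() and (self.rows < shape[0]).all()
            and (self.cols >= 0).all() and (self.cols < shape[1]).all()
        )


def masks_from_label_image(label_image: np.ndarray,
                           cell_ids: Optional[Sequence[str]] = None,
                           id_prefix: str = "cell") -> List[CellMask]:
    """One :class:`CellMask` per distinct positive label, in label order.

    An all-zero label image yields an empty list (not an error).
    """
    label_image = np.asarray(label_image)
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    if cell_ids is not None and len(cell_ids) != len(labels):
        raise ValidationError(
            f"{len(cell_ids)} cell ids supplied for {len(labels)} labels"
        )
    masks = []
    for i, lab in enumerate(labels):
        rows, cols = np.nonzero(label_image == lab)
        cid = cell_ids[i] if cell_ids is not None else f"{id_prefix}{int(lab):03d}"
        masks.append(CellMask(cell_id=cid, rows=rows, cols=cols,
                              shape=label_image.shape))
    return masks


def label_image_from_masks(masks: Sequence[CellMask],
                           shape: Tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        if not m.in_bounds(shape):
            raise ValidationError(f"mask {m.cell_id!r} outside image bounds")
        if (out[m.rows, m.cols] != 0).any():
            raise ValidationError(f"mask {m.cell_id!r} overlaps a previous mask")
        out[m.rows, m.cols] = i
    return out


@dataclass
class ReferenceSet:
    """Per-channel reference data: water background frames, calibration-fluid
    frames, and the spectrofluorometer reference spectrum of the fluid."""

    background_images: Dict[str, np.ndarray]
    calibration_images: Dict[str, np.ndarray]
    reference_values: Dict[str, float]
    dark_offset: Dict[str, float] = field(default_factory=dict)

    def validate(self, table: ChannelTable) -> None:
        ids = set(table.channel_ids)
        for name, d in (("background_images", self.background_images),
                        ("calibration_images", self.calibration_images),
                        ("reference_values", self.reference_values)):
            if set(d) != ids:
                raise ValidationError(f"reference set {name} does not cover the channel table")
        shapes = {img.shape for img in self.background_images.values()}
        shapes |= {img.shape for img in self.calibration_images.values()}
        if len(shapes) != 1:
            raise GeometryError("reference frames have inconsistent shapes")

    def offset(self, channel_id: str) -> float:
        return float(self.dark_offset.get(channel_id, 0.0))


class FeatureTable:
    """Cells x named spectral features, with cell/patient/group metadata.

    Thin wrapper over a :class:`pandas.DataFrame` whose first columns are
    ``cell_id, patient_id, group_label`` followed by real-valued feature
    columns.
    """

    REQUIRED_COLUMNS = ("cell_id", "patient_id", "group_label")

    def __init__(self, data: pd.DataFrame,
                 feature_names: Optional[Sequence[str]] = None,
                 metadata: Optional[dict] = None):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"feature table missing required columns: {missing}")
        if feature_names is None:
            feature_names = [c for c in data.columns if c not in self.REQUIRED_COLUMNS]
        feature_names = list(feature_names)
        if len(set(feature_names)) != len(feature_names):
            raise ValidationError("feature names must be unique")
        absent = [f for f in feature_names if f not in data.columns]
        if absent:
            raise ValidationError(f"feature columns absent from data: {absent[:5]}")
        vals = data[feature_names]
        if len(data) and not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValidationError("feature table contains NaN/Inf values")
        self.data = data.reset_index(drop=True)
        self.feature_names = feature_names
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def classes(self) -> List[str]:
        return sorted(self.data["group_label"].unique())

    def subset(self, groups: Sequence[str]) -> "FeatureTable":
        sel = self.data[self.data["group_label"].isin(list(groups))].reset_index(drop=True)
        return FeatureTable(sel, feature_names=self.feature_names, metadata=self.metadata)

    def matrix(self, features: Optional[Sequence[str]] = None) -> np.ndarray:
        features = list(features) if features is not None else self.feature_names
        return self.data[features].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["group_label"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.data["cell_id"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data["patient_id"].to_numpy()
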