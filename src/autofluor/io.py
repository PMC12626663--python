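"""Readers and writers for blocks, masks, references and feature tables.

On-disk layout of a block directory::

    <block>/
      manifest.json        # metadata + embedded channel table
      Ex340Em440.tif ...   # one grayscale TIFF per channel
      brightfield.tif

Raw synthetic/camera images are 16-bit unsigned TIFF; calibrated images are
32-bit float TIFF.  Masks are a single 16-bit label TIFF (0 = background).
Feature tables are CSV with header ``cell_id,patient_id,group_label,<features>``;
spreadsheet files (.xlsx) with the same column contract are also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd
import tifffile

from .channels import ChannelTable
from .errors import GeometryError, IncompleteBlockError, ValidationError
from .model import CellMask, DataBlock, FeatureTable, ReferenceSet, masks_from_label_image

MANIFEST_NAME = "manifest.json"
_FLOAT_FMT = "%.12g"  # 12 significant digits on CSV round-trips


def _image_path(directory: Path, channel_id: str) -> Path:
    return directory / f"{channel_id}.tif"


def write_data_block(block: DataBlock, directory) -> dict:
    """Write one TIFF per channel plus brightfield and a JSON manifest.

    Returns the manifest dictionary.  ``read_data_block`` on the directory
    reproduces the block bit-exactly (lossless TIFF encoding).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid in block.channel_table.channel_ids:
        tifffile.imwrite(_image_path(directory, cid), block.channel_images[cid])
    tifffile.imwrite(directory / "brightfield.tif", block.brightfield)
    manifest = {
        "sample_id": block.sample_id,
        "patient_id": block.patient_id,
        "group_label": block.group_label,
        "calibrated": block.calibrated,
        "pixel_shape": list(block.pixel_shape),
        "brightfield": "brightfield.tif",
        "channels": block.channel_table.to_records(),
        "images": {cid: f"{cid}.tif" for cid in block.channel_table.channel_ids},
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_data_block(directory, channel_table: Union[ChannelTable, None] = None) -> DataBlock:
    """Read a block directory written by :func:`write_data_block`.

    ``channel_table`` overrides the table embedded in the manifest.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise IncompleteBlockError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    table = channel_table or ChannelTable.from_records(manifest["channels"])
    images = {}
    for cid in table.channel_ids:
        path = _image_path(directory, cid)
        if not path.exists():
            raise IncompleteBlockError(
                f"incomplete block {manifest.get('sample_id')!r}: missing channel {cid!r}"
            )
        images[cid] = tifffile.imread(path)
    brightfield = tifffile.imread(directory / manifest.get("brightfield", "brightfield.tif"))
    shape = brightfield.shape
    for cid, img in images.items():
        if img.shape != shape:
            raise GeometryError(
                f"geometry error in block {manifest.get('sample_id')!r}: "
                f"channel {cid!r} shape {img.shape} != {shape}"
            )
    return DataBlock(
        sample_id=manifest["sample_id"],
        patient_id=manifest["patient_id"],
        group_label=manifest["group_label"],
        channel_images=images,
        brightfield=brightfield,
        channel_table=table,
        calibrated=bool(manifest.get("calibrated", False)),
    )


# -- masks -------------------------------------------------------------------

def write_masks(label_image: np.ndarray, path) -> None:
    """Write a label image (0 = background) as 16-bit TIFF."""
    label_image = np.asarray(label_image)
    if label_image.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValidationError("label image has more than 65535 cells")
    tifffile.imwrite(Path(path), label_image.astype(np.uint16))


def read_masks(path, cell_ids=None) -> List[CellMask]:
    """Read a 16-bit label TIFF into one :class:`CellMask` per positive label."""
    label_image = tifffile.imread(Path(path))
    return masks_from_label_image(label_image, cell_ids=cell_ids)


def read_label_image(path) -> np.ndarray:
    return tifffile.imread(Path(path))


# -- feature tables ----------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> Path:
    """CSV with header ``cell_id,patient_id,group_label,<features...>``."""
    path = Path(path)
    cols = list(FeatureTable.REQUIRED_COLUMNS) + list(table.feature_names)
    table.data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> FeatureTable:
    """Read a CSV (or .xlsx spreadsheet) feature table.

    Raises a parse error naming the offending row/column if a feature cell
    is not numeric, and a validation error if required metadata columns are
    absent.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in FeatureTable.REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table {path.name} missing columns: {missing}")
    feature_names = [c for c in df.columns if c not in FeatureTable.REQUIRED_COLUMNS]
    for col in feature_names:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValidationError(
                f"non-numeric feature value at row {row}, column {col!r} in {path.name}"
            ) from None
    for col in FeatureTable.REQUIRED_COLUMNS:
        df[col] = df[col].astype(str)
    return FeatureTable(df, feature_names=feature_names)


# -- reference sets ----------------------------------------------------------

def write_reference_set(refs: ReferenceSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, img in refs.background_images.items():
        tifffile.imwrite(directory / f"water_{cid}.tif", img)
    for cid, img in refs.calibration_images.items():
        tifffile.imwrite(directory / f"calib_{cid}.tif", img)
    meta = {
        "reference_values": {k: float(v) for k, v in refs.reference_values.items()},
        "dark_offset": {k: float(v) for k, v in refs.dark_offset.items()},
    }
    (directory / "reference_values.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_reference_set(directory, table: ChannelTable) -> ReferenceSet:
    directory = Path(directory)
    meta = json.loads((directory / "reference_values.json").read_text())
    background, calibration = {}, {}
    for cid in table.channel_ids:
        wpath = directory / f"water_{cid}.tif"
        cpath = directory / f"calib_{cid}.tif"
        if not wpath.exists() or not cpath.exists():
            raise IncompleteBlockError(f"reference set missing frames for channel {cid!r}")
        background[cid] = tifffile.imread(wpath)
        calibration[cid] = tifffile.imread(cpath)
    refs = ReferenceSet(
        background_images=background,
        calibration_images=calibration,
        reference_values={k: float(v) for k, v in meta["reference_values"].items()},
        dark_offset={k: float(v) for k, v in meta.get("dark_offset", {}).items()},
    )
    refs.validate(table)
    return refs
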