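"""Image preparation: despiking/smoothing, background subtraction, flat-field
correction, and alignment of channel intensities to spectrofluorometer
reference values.

Order of operations (configurable defaults): a 3x3 median filter removes
isolated dead/saturated pixels, Gaussian smoothing suppresses shot noise,
the per-pixel water frame is subtracted as background, the result is divided
by a unit-mean flat-field image, and finally scaled so that the calibration
fluid's spatial mean matches its spectrofluorometer reference value.  Sensor
defects are treated first and the scale factor is applied last.

Negative intensities after background subtraction are clamped to zero:
fluorescence is physically nonnegative.  The clamp sits at the noise floor
and is the only non-linear step in the chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import tifffile
from scipy import ndimage

from .channels import ChannelTable
from .errors import UncalibratableChannelError, ValidationError
from .model import DataBlock, ReferenceSet

#: Floor applied to the flat-field image so division is always defined.
FLAT_FIELD_FLOOR = 0.05


def despike_and_smooth(image: np.ndarray, sigma: float = 1.0,
                       median_size: int = 3) -> np.ndarray:
    """3x3 median filter (removes isolated dead/saturated pixels) followed by
    Gaussian smoothing.  Shape-preserving, nonnegative output."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("despike_and_smooth expects a 2-D image")
    out = ndimage.median_filter(img, size=median_size)
    if sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=sigma)
    return np.clip(out, 0.0, None)


@dataclass
class CalibrationModel:
    """Per-channel background image b_c, unit-mean flat field F_c, and scale k_c."""

    background: Dict[str, np.ndarray]
    flat_field: Dict[str, np.ndarray]
    scale: Dict[str, float]
    smooth_sigma: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def channel_ids(self):
        return tuple(self.scale)

    def validate(self) -> None:
        for cid, f in self.flat_field.items():
            if not (f > 0).all():
                raise ValidationError(f"flat field for channel {cid!r} not strictly positive")
        for cid, k in self.scale.items():
            if not (np.isfinite(k) and k > 0):
                raise ValidationError(f"scale factor for channel {cid!r} not finite/positive")

    # -- serialization (JSON + TIFF bundle) ----------------------------------
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for cid in self.scale:
            tifffile.imwrite(directory / f"background_{cid}.tif",
                             self.background[cid].astype(np.float32))
            tifffile.imwrite(directory / f"flatfield_{cid}.tif",
                             self.flat_field[cid].astype(np.float32))
        meta = {"scale": {k: float(v) for k, v in self.scale.items()},
                "smooth_sigma": self.smooth_sigma, "metadata": self.metadata}
        (directory / "calibration.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return directory

    @classmethod
    def load(cls, directory) -> "CalibrationModel":
        directory = Path(directory)
        meta = json.loads((directory / "calibration.json").read_text())
        scale = {k: float(v) for k, v in meta["scale"].items()}
        background = {cid: tifffile.imread(directory / f"background_{cid}.tif")
                      for cid in scale}
        flat = {cid: tifffile.imread(directory / f"flatfield_{cid}.tif")
                for cid in scale}
        return cls(background=background, flat_field=flat, scale=scale,
                   smooth_sigma=float(meta.get("smooth_sigma", 1.0)),
                   metadata=meta.get("metadata", {}))


def fit_calibration(refs: ReferenceSet, table: ChannelTable,
                    smooth_sigma: float = 1.0,
                    flat_field_sigma: float = 4.0) -> CalibrationModel:
    """Fit the calibration model from reference frames.

    Per channel: ``b_c`` is the despiked/smoothed water frame; the excess
    (calibration minus water, both smoothed) carries the illumination
    pattern, so ``F_c`` is the excess smoothed further (``flat_field_sigma``;
    flat fields are spatially smooth by nature) and divided by its own mean;
    ``k_c = reference_value / mean(excess)`` aligns intensities to the
    spectrofluorometer scale.
    """
    refs.validate(table)
    background, flat, scale = {}, {}, {}
    for cid in table.channel_ids:
        off = refs.offset(cid)
        water = despike_and_smooth(
            np.asarray(refs.background_images[cid], dtype=float) - off, smooth_sigma)
        calib = despike_and_smooth(
            np.asarray(refs.calibration_images[cid], dtype=float) - off, smooth_sigma)
        excess = calib - water
        mean_excess = float(excess.mean())
        if mean_excess <= 0:
            raise UncalibratableChannelError(
                f"uncalibratable channel {cid!r}: mean(calibration - water) = "
                f"{mean_excess:.4g} <= 0"
            )
        f = ndimage.gaussian_filter(excess, flat_field_sigma)
        f = f / f.mean()
        flat[cid] = np.clip(f, FLAT_FIELD_FLOOR, None)
        background[cid] = water
        ref_val = refs.reference_values[cid]
        if ref_val <= 0:
            raise UncalibratableChannelError(
                f"uncalibratable channel {cid!r}: nonpositive reference value"
            )
        scale[cid] = ref_val / mean_excess
    model = CalibrationModel(background=background, flat_field=flat, scale=scale,
                             smooth_sigma=smooth_sigma)
    model.validate()
    return model


def calibrate_block(block: DataBlock, model: CalibrationModel,
                    clamp: bool = True) -> DataBlock:
    """Apply the calibration chain to every channel of a block.

    Per pixel: ``out = max(0, smoothed(in) - b_c) / F_c * k_c``.  The output
    block is flagged calibrated; calibrating an already-calibrated block is
    an error (the chain is not idempotent).
    """
    if block.calibrated:
        raise ValidationError(f"block {block.sample_id!r} is already calibrated")
    missing = [cid for cid in block.channel_table.channel_ids if cid not in model.scale]
    if missing:
        raise ValidationError(f"calibration model lacks channels: {missing}")
    out_images = {}
    for cid in block.channel_table.channel_ids:
        smoothed = despike_and_smooth(block.channel_images[cid], model.smooth_sigma)
        sub = smoothed - model.background[cid]
        if clamp:
            sub = np.clip(sub, 0.0, None)
        out_images[cid] = (sub / model.flat_field[cid] * model.scale[cid]).astype(np.float32)
    return DataBlock(
        sample_id=block.sample_id,
        patient_id=block.patient_id,
        group_label=block.group_label,
        channel_images=out_images,
        brightfield=block.brightfield,
        channel_table=block.channel_table,
        calibrated=True,
    )
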