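"""Spectral channel definitions for multispectral autofluorescence acquisition.

A *channel* is one excitation-LED / emission-filter combination of the
microscope: a narrowband excitation centered at ``excitation_center_nm``
(halfwidth ``excitation_halfwidth_nm``) paired with an emission bandpass
``[emission_low_nm, emission_high_nm]``.  The default acquisition uses 34
such channels spanning excitation 340-510 nm and emission 420-650 nm.

The exact band list of the instrument is configurable; ``default_channel_table``
builds a documented stand-in grid honouring the spectral ranges and channel
count, with only physically valid pairs (emission band strictly above the
excitation center) retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Sequence, Union

import pandas as pd

from .errors import ValidationError

#: Spectral extent of the default acquisition (closed intervals, nm).
EXCITATION_RANGE_NM = (340.0, 510.0)
EMISSION_RANGE_NM = (420.0, 650.0)

_DEFAULT_EXCITATION_CENTERS = (340, 370, 400, 430, 460, 490, 510)
_DEFAULT_EMISSION_BANDS = (
    (420, 460),
    (460, 500),
    (500, 540),
    (540, 580),
    (580, 620),
    (610, 650),
)


def make_channel_id(excitation_center_nm: float, emission_low_nm: float,
                    emission_high_nm: float) -> str:
    """Self-describing channel name ``Ex{excitation}Em{emission midpoint}`` in nm."""
    mid = (emission_low_nm + emission_high_nm) / 2.0
    return f"Ex{int(round(excitation_center_nm))}Em{int(round(mid))}"


@dataclass(frozen=True)
class ChannelSpec:
    """One excitation/emission band of the acquisition."""

    channel_id: str
    excitation_center_nm: float
    excitation_halfwidth_nm: float
    emission_low_nm: float
    emission_high_nm: float
    index: int

    def __post_init__(self) -> None:
        if not self.emission_low_nm < self.emission_high_nm:
            raise ValidationError(
                f"channel {self.channel_id!r}: emission_low_nm must be < emission_high_nm"
            )
        if self.excitation_halfwidth_nm <= 0:
            raise ValidationError(
                f"channel {self.channel_id!r}: excitation_halfwidth_nm must be positive"
            )

    @property
    def emission_mid_nm(self) -> float:
        return 0.5 * (self.emission_low_nm + self.emission_high_nm)


class ChannelTable:
    """Ordered, uniquely named collection of :class:`ChannelSpec`."""

    def __init__(self, channels: Sequence[ChannelSpec]):
        channels = tuple(channels)
        if not channels:
            raise ValidationError("channel table must contain at least one channel")
        ids = [c.channel_id for c in channels]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise ValidationError(f"duplicate channel_id in table: {sorted(dups)}")
        if [c.index for c in channels] != list(range(len(channels))):
            raise ValidationError("channel indices must be contiguous 0..n-1 in order")
        self._channels = channels
        self._by_id = {c.channel_id: c for c in channels}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._channels)

    def __iter__(self) -> Iterator[ChannelSpec]:
        return iter(self._channels)

    def __getitem__(self, key: Union[int, str]) -> ChannelSpec:
        if isinstance(key, str):
            return self._by_id[key]
        return self._channels[key]

    def __contains__(self, channel_id: str) -> bool:
        return channel_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelTable):
            return NotImplemented
        return self._channels == other._channels

    @property
    def channel_ids(self) -> tuple:
        return tuple(c.channel_id for c in self._channels)

    # -- serialization -------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self._channels])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ChannelTable":
        required = {"channel_id", "excitation_center_nm", "excitation_halfwidth_nm",
                    "emission_low_nm", "emission_high_nm", "index"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"channel table file missing columns: {sorted(missing)}")
        rows = df.sort_values("index").to_dict("records")
        return cls([ChannelSpec(
            channel_id=str(r["channel_id"]),
            excitation_center_nm=float(r["excitation_center_nm"]),
            excitation_halfwidth_nm=float(r["excitation_halfwidth_nm"]),
            emission_low_nm=float(r["emission_low_nm"]),
            emission_high_nm=float(r["emission_high_nm"]),
            index=int(r["index"]),
        ) for r in rows])

    def to_records(self) -> list:
        return [asdict(c) for c in self._channels]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ChannelTable":
        return cls.from_dataframe(pd.DataFrame(list(records)))

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_records(), indent=2))
        else:
            self.to_dataframe().to_csv(path, index=False)


def read_channel_table(path) -> ChannelTable:
    """Read a channel table from a JSON or CSV sidecar file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return ChannelTable.from_records(json.loads(path.read_text()))
    return ChannelTable.from_dataframe(pd.read_csv(path))


def default_channel_table(excitation_halfwidth_nm: float = 5.0) -> ChannelTable:
    """Default 34-channel grid over excitation 340-510 nm x emission 420-650 nm.

    All combinations of the 7 excitation centers and 6 emission bands are
    formed and pairs whose emission band does not lie strictly above the
    excitation center are discarded, leaving exactly 34 channels.
    """
    specs = []
    idx = 0
    for exc in _DEFAULT_EXCITATION_CENTERS:
        for lo, hi in _DEFAULT_EMISSION_BANDS:
            if lo <= exc:  # emission band must sit strictly above the excitation line
                continue
            specs.append(ChannelSpec(
                channel_id=make_channel_id(exc, lo, hi),
                excitation_center_nm=float(exc),
                excitation_halfwidth_nm=float(excitation_halfwidth_nm),
                emission_low_nm=float(lo),
                emission_high_nm=float(hi),
                index=idx,
            ))
            idx += 1
    table = ChannelTable(specs)
    assert len(table) == 34
    return table
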