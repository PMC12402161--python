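"""Shared containers: image stacks, label masks and the constriction-device geometry.

Conventions used throughout the package:

* pixel indices are 0-based, ``(row, col)`` order, origin at the top-left;
* physical coordinates are ``index * pixel_size`` in micrometres;
* image stacks carry axes ``(time, channel, y, x)``; the flow axis of the
  constriction device is the image x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "LabelMask",
    "DeviceGeometry",
    "REGION_ORDER",
    "BASELINE",
    "UNASSIGNED",
]

#: Canonical device-region labels, upstream to downstream.  CC = constriction
#: channel, RC = the relaxation chamber immediately downstream of it.
REGION_ORDER = ("CC_30", "RC_30", "CC_20", "RC_20", "CC_10", "RC_10", "CC_5", "RC_5")
BASELINE = "BASELINE"
UNASSIGNED = "UNASSIGNED"


class InvalidGeometryError(ValueError):
    """Raised when device dimensions are physically impossible."""


@dataclass
class ImageStack:
    """An N-D fluorescence/brightfield stack with physical pixel size.

    ``data`` always has axes ``(time, channel, y, x)``; singleton axes are
    kept so every consumer can rely on the contract.
    """

    data: np.ndarray
    pixel_size: float  # µm per pixel
    channel_names: tuple[str, ...] = ("ch0",)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis, np.newaxis]
        elif self.data.ndim == 3:
            self.data = self.data[:, np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected <=4 axes (t, c, y, x), got {self.data.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def channel(self, name: str) -> np.ndarray:
        """All frames of one named channel, shape (time, y, x)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.data[:, idx]

    def save(self, path: str | Path) -> None:
        meta = dict(self.metadata)
        meta.update(
            axes="TCYX",
            pixel_size_um=self.pixel_size,
            channel_names=list(self.channel_names),
        )
        tifffile.imwrite(path, self.data, metadata={k: str(v) for k, v in meta.items()})

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if pixel_size is None:
            try:
                pixel_size = float(meta.get("pixel_size_um"))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: no pixel-size metadata; pass pixel_size explicitly"
                ) from None
        names = meta.get("channel_names")
        if isinstance(names, str):  # round-tripped through str()
            names = [n.strip(" '\"") for n in names.strip("[]").split(",")]
        if data.ndim == 2:
            data = data[None, None]
        elif data.ndim == 3:
            data = data[:, None]
        if names is None:
            names = [f"ch{i}" for i in range(data.shape[1])]
        return cls(data=data, pixel_size=pixel_size, channel_names=tuple(names))


@dataclass
class LabelMask:
    """Integer-labelled segmentation sharing geometry with its source image.

    Background is 0; object labels are consecutive positive integers.
    """

    data: np.ndarray
    pixel_size: float
    provenance: str = ""
    flags: dict = field(default_factory=dict)  # label -> QC note

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be >= 0 (0 = background)")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def area(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.data.astype(np.uint16))


@dataclass
class DeviceGeometry:
    """The microcapillary-mimicking device: sequential constriction channels
    of decreasing width, each followed by a relaxation chamber.

    The flow axis is x; ``region_intervals`` maps each region label to its
    half-open interval [x0, x1) in µm, with a baseline field of length
    ``spacing`` upstream of the first channel.
    """

    channel_widths: tuple[float, ...] = (30.0, 20.0, 10.0, 5.0)
    channel_length: float = 150.0  # µm
    channel_height: float = 15.0  # µm
    spacing: float = 150.0  # µm between regions (the relaxation chambers)
    pixel_size: float = 0.33  # µm/px, typical of 10x confocal sampling

    def __post_init__(self) -> None:
        self.channel_widths = tuple(float(w) for w in self.channel_widths)
        if any(w <= 0 for w in self.channel_widths):
            raise InvalidGeometryError("channel widths must be positive")
        if any(
            b >= a for a, b in zip(self.channel_widths, self.channel_widths[1:])
        ) and len(self.channel_widths) > 1:
            raise InvalidGeometryError("channel widths must be strictly decreasing")
        for name in ("channel_length", "channel_height", "spacing", "pixel_size"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")
        if min(self.channel_widths) < self.pixel_size:
            raise InvalidGeometryError(
                "narrowest channel is below one pixel; decrease pixel_size"
            )

    @property
    def region_labels(self) -> tuple[str, ...]:
        out = []
        for w in self.channel_widths:
            wtxt = f"{w:g}"
            out += [f"CC_{wtxt}", f"RC_{wtxt}"]
        return tuple(out)

    @property
    def region_intervals(self) -> dict[str, tuple[float, float]]:
        """Ordered {label: (x0, x1)} in µm, BASELINE first, contiguous."""
        intervals: dict[str, tuple[float, float]] = {}
        x = 0.0
        intervals[BASELINE] = (x, x + self.spacing)
        x += self.spacing
        for w in self.channel_widths:
            wtxt = f"{w:g}"
            intervals[f"CC_{wtxt}"] = (x, x + self.channel_length)
            x += self.channel_length
            intervals[f"RC_{wtxt}"] = (x, x + self.spacing)
            x += self.spacing
        return intervals

    @property
    def total_length(self) -> float:
        return self.spacing + len(self.channel_widths) * (
            self.channel_length + self.spacing
        )

    def width_of(self, region: str) -> float:
        """Constriction width governing a region (its own channel's width)."""
        if region == BASELINE:
            return float("inf")
        try:
            return float(region.split("_", 1)[1])
        except (IndexError, ValueError):
            raise KeyError(f"unknown region {region!r}") from None


def as_float(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64)


def physical_area(n_pixels: int | np.ndarray, pixel_size: float) -> float | np.ndarray:
    """Pixel count -> µm²."""
    return n_pixels * pixel_size**2


def check_sequence(name: str, values: Sequence[float], positive: bool = True) -> None:
    arr = np.asarray(values, dtype=float)
    if positive and np.any(arr <= 0):
        raise ValueError(f"{name} must be positive")
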