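"""Core image containers shared across the pipeline.

A :class:`ChannelImage` is a single 2-D intensity grid carrying its channel
name, acquisition cycle and physical pixel size; a :class:`CycleStack` is the
cycles x channels (x z) collection produced by iterative indirect
immunofluorescence (4i) acquisition; a :class:`LabelMap` is an integer object
map (0 = background) as produced by segmentation.

Images are stored row-major with 0-based, pixel-centered coordinates.  All
offsets in this package are expressed as integer ``(dy, dx)`` pairs: ``dy``
moves down (increasing row), ``dx`` moves right (increasing column).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger("apicoloc")

#: Fill value used when translating images (border pixels with no source data).
BORDER_FILL = 0.0

#: Default nuclear channel name; every 4i cycle must contain it.
DAPI = "DAPI"


class ApicolocError(ValueError):
    """Base class for contract violations raised by this package."""


class DegenerateInputError(ApicolocError):
    """Raised when an operation receives input it is mathematically unable to
    process (e.g. thresholding a constant image)."""


class InfeasibleSpecError(ApicolocError):
    """Raised when a synthetic-data specification cannot be realized."""


class InconsistentStackError(ApicolocError):
    """Raised when images that must share a frame do not."""


@dataclass
class ChannelImage:
    """One 2-D grayscale image with physical metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite intensities.
    channel : str
        Marker / stain name (e.g. ``"DAPI"``, ``"UMOD"``).
    cycle : int
        4i acquisition cycle index (1-based); 0 for single-round images.
    pixel_size_um : float
        Physical size of one pixel in micrometres; must be positive.
    """

    pixels: np.ndarray
    channel: str = ""
    cycle: int = 0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ApicolocError("ChannelImage requires a 2-D grid of size >= 1x1")
        if not np.all(np.isfinite(self.pixels)):
            raise ApicolocError("ChannelImage pixels must be finite")
        if self.pixel_size_um <= 0:
            raise ApicolocError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return dataclasses.replace(self, pixels=np.asarray(pixels, dtype=np.float64))

    def um_to_px(self, distance_um: float) -> float:
        return distance_um / self.pixel_size_um


@dataclass
class CycleStack:
    """Ordered cycles of channel images sharing one frame.

    ``cycles[i]`` is the ordered channel list of cycle ``i+1``.  Before
    maximum-intensity projection each entry may carry a z-dimension in
    ``zstacks``; after projection only the 2-D images remain.
    """

    cycles: list[list[ChannelImage]]
    zstacks: dict[tuple[int, str], list[ChannelImage]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {im.shape for cyc in self.cycles for im in cyc}
        if len(shapes) > 1:
            raise InconsistentStackError(f"images do not share a frame: {shapes}")
        for i, cyc in enumerate(self.cycles, start=1):
            if not any(im.channel == DAPI for im in cyc):
                raise InconsistentStackError(f"cycle {i} lacks a {DAPI} channel")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cycles[0][0].shape

    def get(self, cycle: int, channel: str) -> ChannelImage:
        for im in self.cycles[cycle - 1]:
            if im.channel == channel:
                return im
        raise KeyError(f"cycle {cycle} has no channel {channel!r}")

    def iter_images(self) -> Iterator[ChannelImage]:
        for cyc in self.cycles:
            yield from cyc


@dataclass
class LabelMap:
    """Integer-labelled object map over one frame (0 = background).

    Labels of primary objects are contiguous from 1 and 8-connected.
    ``provenance`` records which channel/threshold produced the map.
    """

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ApicolocError("LabelMap requires a 2-D grid")
        if np.issubdtype(self.labels.dtype, np.floating):
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ApicolocError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def ids(self) -> np.ndarray:
        out = np.unique(self.labels)
        return out[out > 0]


@dataclass
class BinaryMask:
    """Boolean foreground mask with provenance (method and threshold used)."""

    mask: np.ndarray
    provenance: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ApicolocError("BinaryMask requires a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


def translate(pixels: np.ndarray, dy: int, dx: int, fill: float = BORDER_FILL) -> np.ndarray:
    """Translate an image by an integer offset, filling exposed borders.

    Output pixel ``(y, x)`` takes the value of input pixel ``(y - dy, x - dx)``
    where that source exists, otherwise ``fill``.
    """
    out = np.full_like(np.asarray(pixels, dtype=np.float64), fill)
    h, w = pixels.shape
    ys0, ys1 = max(0, dy), min(h, h + dy)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = pixels[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def write_channels_tiff(path, images: Sequence[ChannelImage] | Mapping[str, ChannelImage]) -> None:
    """Write a set of channel images as a multi-page 32-bit float TIFF.

    Pages are written in iteration order; channel names and the pixel size go
    into the ImageDescription metadata so the file round-trips.
    """
    if isinstance(images, Mapping):
        images = list(images.values())
    arr = np.stack([im.pixels.astype(np.float32) for im in images])
    meta = {
        "axes": "CYX",
        "channels": [im.channel for im in images],
        "cycles": [im.cycle for im in images],
        "pixel_size_um": images[0].pixel_size_um,
    }
    # shaped TIFF with JSON metadata (channel map + pixel size) regardless of
    # the file suffix
    tifffile.imwrite(path, arr, metadata=meta, ome=False,
                     photometric="minisblack")


def read_channels_tiff(path, channels: Sequence[str] | None = None,
                       pixel_size_um: float | None = None) -> dict[str, ChannelImage]:
    """Read a multi-page TIFF into named :class:`ChannelImage` objects.

    Channel names are taken from the file's metadata when present; an explicit
    ``channels`` list (the config's channel map) overrides it.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    names = list(channels) if channels is not None else list(meta.get("channels", []))
    if len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    cycles = list(meta.get("cycles", [0] * arr.shape[0]))
    psz = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    return {
        name: ChannelImage(arr[i].astype(np.float64), channel=name,
                           cycle=int(cycles[i]), pixel_size_um=psz)
        for i, name in enumerate(names)
    }


def read_stack_tiff(path, pixel_size_um: float | None = None) -> "CycleStack":
    """Read a multi-cycle TIFF (channel names may repeat across cycles)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    names = list(meta.get("channels", [f"ch{i}" for i in range(arr.shape[0])]))
    cycles = [int(c) for c in meta.get("cycles", [1] * arr.shape[0])]
    psz = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    by_cycle: dict[int, list[ChannelImage]] = {}
    for i, (name, cyc) in enumerate(zip(names, cycles)):
        cyc = max(cyc, 1)
        by_cycle.setdefault(cyc, []).append(
            ChannelImage(arr[i].astype(np.float64), channel=name, cycle=cyc,
                         pixel_size_um=psz))
    return CycleStack(cycles=[by_cycle[c] for c in sorted(by_cycle)])
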