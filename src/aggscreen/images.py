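"""Image containers, TIFF/PNG I/O and the blur-rejection quality filter.

Intensities are stored internally as floating point values in ``[0, 1]``
regardless of the bit depth on disk; 8- and 16-bit integer images are divided
by their dtype maximum on read and re-quantised to 16 bit on write.
Coordinates are ``(row, col)``, 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import filters

from .errors import ImageReadError

__all__ = [
    "ChannelImage",
    "MultiChannelImage",
    "FocusReport",
    "read_field",
    "write_field",
    "focus_metric",
    "qc_filter",
]


@dataclass
class ChannelImage:
    """A single 2-D fluorescence channel.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with finite values in ``[0, 1]``.
    name : str
        Channel label, e.g. ``"nuclei"`` or ``"gfp"``.
    pixel_size : float, optional
        Physical pixel size in µm/px, if known.
    """

    pixels: np.ndarray
    name: str = ""
    pixel_size: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ChannelImage requires a 2-D array with height, width >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ChannelImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MultiChannelImage:
    """Named 2-D intensity planes sharing one pixel grid."""

    channels: dict[str, ChannelImage]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched dimensions: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> ChannelImage:
        return self.channels[name]


@dataclass
class FocusReport:
    """Outcome of the blur-rejection filter for one field.

    ``accepted`` is true exactly when ``metric >= threshold``.
    """

    metric: float
    threshold: float
    accepted: bool

    @classmethod
    def evaluate(cls, metric: float, threshold: float) -> "FocusReport":
        return cls(metric=float(metric), threshold=float(threshold), accepted=metric >= threshold)


def _normalise(arr: np.ndarray) -> np.ndarray:
    """Map an integer or float raster to float64 in [0, 1]."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    out = arr.astype(float)
    if out.size and (out.min() < 0 or out.max() > 1):
        raise ImageReadError("float image intensities outside [0, 1]")
    return out


def _read_raster(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            return tifffile.imread(path)
        return np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - distinct, descriptive error
        raise ImageReadError(f"unreadable image file {path!r}: {exc}") from exc


def read_field(path: str, channel_map: Mapping[str, int | str]) -> MultiChannelImage:
    """Read a multi-channel field from disk.

    ``channel_map`` maps channel names either to page indices of a multi-page
    TIFF at ``path`` (int values) or to file paths (str values, absolute or
    relative to the directory of ``path``), one single-channel raster each.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pages: np.ndarray | None = None
    if any(isinstance(v, int) for v in channel_map.values()):
        arr = _read_raster(path)
        if arr.ndim == 2:
            pages = arr[None]
        elif arr.ndim == 3:
            # tifffile returns (pages, H, W) for multi-page files
            pages = arr
        else:
            raise ImageReadError(f"unsupported raster rank {arr.ndim} in {path!r}")

    channels: dict[str, ChannelImage] = {}
    for name, ref in channel_map.items():
        if isinstance(ref, int):
            assert pages is not None
            if ref >= pages.shape[0]:
                raise ImageReadError(
                    f"channel {name!r} requests page {ref} but {path!r} has "
                    f"{pages.shape[0]} page(s)"
                )
            plane = pages[ref]
        else:
            ref_path = ref if os.path.isabs(ref) else os.path.join(os.path.dirname(path), ref)
            if not os.path.exists(ref_path):
                raise FileNotFoundError(ref_path)
            plane = _read_raster(ref_path)
            if plane.ndim == 3:  # RGB(A) PNG: accept grey written as identical planes
                plane = plane[..., 0]
        channels[name] = ChannelImage(_normalise(plane), name=name)
    out = MultiChannelImage(channels, provenance={"path": os.path.abspath(path)})
    return out


def write_field(field: MultiChannelImage, path: str) -> list[str]:
    """Write a field as a 16-bit multi-page TIFF, one page per channel.

    Channel order is the container's insertion order; returns the channel
    names in page order so a matching ``channel_map`` can be rebuilt.
    """
    stack = np.stack(
        [np.round(np.clip(ch.pixels, 0, 1) * 65535).astype(np.uint16) for ch in field.channels.values()]
    )
    tifffile.imwrite(
        path, stack, photometric="minisblack", metadata={"channel_names": list(field.channels)}
    )
    return list(field.channels)


def focus_metric(image: ChannelImage) -> float:
    """Sharpness score used for blur rejection.

    Mean Sobel gradient magnitude over the image (reflect boundary handling),
    so the score is invariant to image size and to constant intensity
    offsets, and scales linearly with contrast. A constant image scores 0.
    """
    return float(np.mean(filters.sobel(image.pixels)))


def qc_filter(
    fields: Sequence[MultiChannelImage],
    channel: str,
    threshold: float,
) -> tuple[list[MultiChannelImage], list[FocusReport]]:
    """Partition fields into accepted/rejected by the focus metric.

    Returns the accepted fields and one :class:`FocusReport` per input field
    in input order. A field is accepted when its metric on ``channel`` is at
    least ``threshold``.
    """
    if threshold < 0:
        raise ValueError("qc threshold must be >= 0")
    accepted: list[MultiChannelImage] = []
    reports: list[FocusReport] = []
    for f in fields:
        if channel not in f.channels:
            raise KeyError(f"channel {channel!r} absent from field (has {f.channel_names})")
        rep = FocusReport.evaluate(focus_metric(f[channel]), threshold)
        reports.append(rep)
        if rep.accepted:
            accepted.append(f)
    return accepted, reports
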