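"""Windowed access to pyramidal and plain TIFF whole-slide images.

A whole-slide image (WSI) stores one tissue scan as a pyramid of
progressively downsampled copies ("series"), each internally chunked into
small storage tiles so that any rectangle can be decoded without loading
the full gigapixel image.  This module opens tiled-pyramidal and plain
TIFF files, enumerates their series in file order, and reads arbitrary
rectangular regions of one series with memory proportional to the region,
not the slide.

Coordinates are 0-based, half-open, origin top-left, ``x`` = column,
``y`` = row, always in the pixel grid of the requested series.  Series
indices are 1-based at every public surface (series 1 is the highest
resolution in a well-formed pyramid).

Proprietary scanner formats (SVS, NDPI, SCN, ...) are not parsed here;
an optional adapter can be installed with :func:`register_reader`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import tifffile
import zarr

from .errors import RegionBoundsError, SeriesIndexError, UnsupportedFormatError

__all__ = [
    "SeriesInfo",
    "SlidePyramid",
    "open_slide",
    "read_region",
    "register_reader",
]


@dataclass(frozen=True)
class SeriesInfo:
    """One resolution series of a slide file.

    Attributes
    ----------
    index : int
        1-based position of the series in the file.
    width_px, height_px : int
        Series dimensions in pixels.
    downsample : float
        Linear downsampling factor relative to series 1 (series 1 -> 1.0).
    internal_tile_w, internal_tile_h : int
        Storage-tile dimensions, 0 if the series is stripped rather than
        tiled.
    """

    index: int
    width_px: int
    height_px: int
    downsample: float
    internal_tile_w: int = 0
    internal_tile_h: int = 0


@dataclass
class SlidePyramid:
    """Handle on an open slide file: ordered series plus lazy pixel access.

    Pixel data is only decoded on :meth:`read_region` calls; opening a
    slide touches metadata alone.  The handle keeps the underlying TIFF
    open; use as a context manager or call :meth:`close`.
    """

    path: Path
    series: list[SeriesInfo]
    _tiff: Optional[tifffile.TiffFile] = field(default=None, repr=False)
    _pages: list = field(default_factory=list, repr=False)
    _zarrs: dict = field(default_factory=dict, repr=False)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def series_info(self, series: int) -> SeriesInfo:
        """Return :class:`SeriesInfo` for a 1-based series index."""
        if not 1 <= series <= len(self.series):
            raise SeriesIndexError(
                f"series {series} out of range 1..{len(self.series)} in {self.path.name}"
            )
        return self.series[series - 1]

    def read_region(self, series: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        """Read the rectangle [x, x+w) x [y, y+h) of one series.

        Returns an ``(h, w, 3)`` uint8 RGB array holding exactly the
        requested pixels.  The region must lie fully inside the series
        bounds; callers (the tiler) pre-clip.  Repeated identical calls
        return identical arrays.
        """
        info = self.series_info(series)
        if w < 1 or h < 1:
            raise RegionBoundsError(f"empty region {w}x{h} requested")
        if x < 0 or y < 0 or x + w > info.width_px or y + h > info.height_px:
            raise RegionBoundsError(
                f"region x={x} y={y} w={w} h={h} exceeds series {series} "
                f"bounds {info.width_px}x{info.height_px} in {self.path.name}"
            )
        z = self._zarr(series)
        region = np.asarray(z[y : y + h, x : x + w])
        if region.ndim == 2:  # grayscale page: broadcast to RGB
            region = np.repeat(region[:, :, None], 3, axis=2)
        return np.ascontiguousarray(region[:, :, :3], dtype=np.uint8)

    def _zarr(self, series: int):
        if series not in self._zarrs:
            page = self._pages[series - 1]
            store = page.aszarr()
            self._zarrs[series] = zarr.open(store, mode="r")
        return self._zarrs[series]

    def close(self) -> None:
        self._zarrs.clear()
        if self._tiff is not None:
            self._tiff.close()
            self._tiff = None

    def __enter__(self) -> "SlidePyramid":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# Registered adapters for formats the core does not parse.  Each adapter is
# a callable (path) -> SlidePyramid | None; None means "not mine".
_READERS: list[Callable[[Path], Optional[SlidePyramid]]] = []


def register_reader(reader: Callable[[Path], Optional[SlidePyramid]]) -> None:
    """Install an adapter that can open additional slide formats.

    Adapters are consulted, in registration order, before the built-in
    TIFF reader.  An adapter returns a :class:`SlidePyramid` or ``None``
    to decline the file.  The core never imports adapter modules.
    """
    _READERS.append(reader)


def open_slide(path: os.PathLike | str) -> SlidePyramid:
    """Open a slide file and enumerate its resolution series.

    Both pyramid dialects are accepted — successive reduced-resolution
    main IFDs, and SubIFD-attached levels — and are flattened into one
    1-based series list in file order.  A plain single-resolution TIFF
    yields exactly one series with downsample 1.0.  Non-image companion
    series (thumbnails, labels) are listed in file order as-is; the
    caller selects the series to process.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedFormatError
        If the file is not a readable TIFF and no registered adapter
        accepts it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide file not found: {path}")
    for reader in _READERS:
        slide = reader(path)
        if slide is not None:
            return slide
    try:
        tf = tifffile.TiffFile(str(path))
    except Exception as exc:
        raise UnsupportedFormatError(f"cannot open {path} as TIFF: {exc}") from exc

    # Flatten: every tifffile series contributes its pyramid levels in order.
    pages = []
    for s in tf.series:
        for level in s.levels:
            pages.append(level)
    if not pages:
        tf.close()
        raise UnsupportedFormatError(f"no image series found in {path}")

    infos: list[SeriesInfo] = []
    base_w = base_h = None
    for i, level in enumerate(pages):
        keyframe = level.keyframe
        w, h = keyframe.imagewidth, keyframe.imagelength
        if base_w is None:
            base_w, base_h = w, h
        down = ((base_w / w) + (base_h / h)) / 2.0
        tile_w = keyframe.tilewidth if keyframe.is_tiled else 0
        tile_h = keyframe.tilelength if keyframe.is_tiled else 0
        infos.append(
            SeriesInfo(
                index=i + 1,
                width_px=int(w),
                height_px=int(h),
                downsample=float(down),
                internal_tile_w=int(tile_w),
                internal_tile_h=int(tile_h),
            )
        )
    return SlidePyramid(path=path, series=infos, _tiff=tf, _pages=pages)


def read_region(
    slide: SlidePyramid, series: int, x: int, y: int, w: int, h: int
) -> np.ndarray:
    """Functional alias for :meth:`SlidePyramid.read_region`."""
    return slide.read_region(series, x, y, w, h)
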