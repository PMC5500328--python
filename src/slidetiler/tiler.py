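"""Tile-grid computation and the tile file-name template.

A run extracts square tiles of side ``tile_size`` with a configurable
``overlap`` (identical in X and Y).  Tile origins along each axis step by
``stride = tile_size - overlap``; origin generation stops at the first
tile that reaches the edge, and edge tiles are clipped — never shifted
inward — so that at overlap 0 the tiles partition the image exactly and
area aggregation never double counts.

Extracted tiles are named after their position on the slide:

    <OriginalFileName.ext>__<series>_<x_origin>_<y_origin>.tif

(double underscore after the original file name, single underscores
between the three decimal integers).  Parsing proceeds from the right so
underscores — including doubled ones — inside the slide file name never
break the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GridParameterError, TileNameError

__all__ = ["TileSpec", "TileGrid", "compute_grid", "tile_name", "parse_tile_name"]


@dataclass(frozen=True)
class TileSpec:
    """One tile: origin and (edge-clipped) extent in series pixel coordinates."""

    series: int
    x_origin: int
    y_origin: int
    width: int
    height: int


@dataclass(frozen=True)
class TileGrid:
    """The ordered tile set for one series under (tile_size, overlap).

    Tiles are row-major: y outer, x inner — a deterministic, documented
    order so per-tile results tables are reproducible.
    """

    tile_size: int
    overlap: int
    n_cols: int
    n_rows: int
    tiles: tuple[TileSpec, ...]

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


def _axis_origins(length: int, tile_size: int, stride: int) -> list[int]:
    """Origins k*stride for k = 0, 1, ..., stopping at the first tile that
    reaches the edge (k*stride + tile_size >= length)."""
    origins = []
    k = 0
    while True:
        origin = k * stride
        origins.append(origin)
        if origin + tile_size >= length:
            return origins
        k += 1


def compute_grid(
    width: int, height: int, tile_size: int, overlap: int = 0, series: int = 1
) -> TileGrid:
    """Compute the tile grid covering a ``width`` x ``height`` series.

    Every pixel is covered by at least one tile; with ``overlap == 0``
    the tiles partition the image (each pixel in exactly one tile).

    Raises :class:`GridParameterError` on non-positive dimensions or
    tile size, negative overlap, or ``overlap >= tile_size``.
    """
    if width < 1 or height < 1:
        raise GridParameterError(f"non-positive image dimensions {width}x{height}")
    if tile_size < 1:
        raise GridParameterError(f"tile_size must be >= 1, got {tile_size}")
    if overlap < 0 or overlap >= tile_size:
        raise GridParameterError(
            f"overlap must satisfy 0 <= overlap < tile_size, got "
            f"overlap={overlap}, tile_size={tile_size}"
        )
    stride = tile_size - overlap
    xs = _axis_origins(width, tile_size, stride)
    ys = _axis_origins(height, tile_size, stride)
    tiles = tuple(
        TileSpec(
            series=series,
            x_origin=x,
            y_origin=y,
            width=min(tile_size, width - x),
            height=min(tile_size, height - y),
        )
        for y in ys
        for x in xs
    )
    return TileGrid(
        tile_size=tile_size,
        overlap=overlap,
        n_cols=len(xs),
        n_rows=len(ys),
        tiles=tiles,
    )


def tile_name(slide_filename: str, series: int, x_origin: int, y_origin: int) -> str:
    """Build the tile file name encoding slide, series and origin."""
    if not slide_filename:
        raise TileNameError("slide filename must be non-empty")
    if series < 1 or x_origin < 0 or y_origin < 0:
        raise TileNameError(
            f"invalid tile identity series={series} x={x_origin} y={y_origin}"
        )
    return f"{slide_filename}__{series}_{x_origin}_{y_origin}.tif"


def parse_tile_name(name: str) -> tuple[str, int, int, int]:
    """Invert :func:`tile_name`: ``(slide_filename, series, x_origin, y_origin)``.

    Parsing is right-to-left: strip the ``.tif`` suffix, take the last two
    underscore-delimited tokens as y then x, split the remainder at its
    final double underscore into slide filename and series.
    """
    err = TileNameError(f"not a tile name: {name!r}")
    if not name.endswith(".tif"):
        raise err
    stem = name[: -len(".tif")]
    parts = stem.rsplit("_", 2)
    if len(parts) != 3:
        raise err
    head, x_str, y_str = parts
    if "__" not in head:
        raise err
    slide_filename, series_str = head.rsplit("__", 1)
    if not slide_filename:
        raise err
    if not (series_str.isdigit() and x_str.isdigit() and y_str.isdigit()):
        raise err
    series, x, y = int(series_str), int(x_str), int(y_str)
    if series < 1:
        raise err
    return slide_filename, series, x, y
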