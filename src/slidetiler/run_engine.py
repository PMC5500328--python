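"""The tile-iteration workflow: the engine every analysis plugs into.

No specific analysis lives here — only the iterative loading of tiles.
For each slide in a folder (lexicographic order), the engine computes
the tile grid for the selected series, and for each tile in row-major
order: reads the tile, writes it as a TIFF under the position-encoding
file name into ``<output>/tiles/``, invokes the user's processor with
the tile pixels, a :class:`TileContext`, and the shared
:class:`~slidetiler.results_store.ResultsStore`, then deletes the tile
file unless the run keeps tiles.  Tiles are always materialized on disk
before the processor runs so follow-up passes can re-open them; the
keep/delete flag only controls post-hoc deletion.

A processor is any callable ``(tile_pixels, context, store) -> None``
that does not retain the pixel array beyond the call.  Processor
exceptions are isolated per tile and collected into the run summary —
long unsupervised batches must not die mid-run.  Memory stays bounded
by one tile, never the slide.
"""

from __future__ import annotations

import importlib.util
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import tifffile

from .errors import ConfigurationError, ProcessorLoadError, SlideTilerError
from .pyramid_io import SlidePyramid, open_slide
from .results_store import ResultsStore
from .tiler import compute_grid, tile_name

__all__ = [
    "RunConfig",
    "TileContext",
    "RunSummary",
    "TileProcessor",
    "run_slide",
    "run_folder",
    "load_processor",
    "void_processor",
    "BUILTIN_PROCESSORS",
    "PROCESSOR_ENTRY_POINT",
]

logger = logging.getLogger("slidetiler.engine")

TILES_SUBDIR = "tiles"
PROCESSOR_ENTRY_POINT = "process_tile"

SLIDE_EXTENSIONS = {".tif", ".tiff"}

TileProcessor = Callable[..., None]


@dataclass
class RunConfig:
    """Everything a run needs: paths, processor, grid parameters, keep flag."""

    input_path: Union[str, Path]
    output_path: Union[str, Path]
    processor_ref: str = "void"
    series: int = 1
    tile_size: int = 2048
    overlap: int = 0
    keep_tiles: bool = False

    def __post_init__(self):
        self.input_path = Path(self.input_path)
        self.output_path = Path(self.output_path)
        if self.tile_size < 1:
            raise ConfigurationError(f"tile_size must be >= 1, got {self.tile_size}")
        if not 0 <= self.overlap < self.tile_size:
            raise ConfigurationError(
                f"overlap must satisfy 0 <= overlap < tile_size, got "
                f"overlap={self.overlap}, tile_size={self.tile_size}"
            )
        if self.series < 1:
            raise ConfigurationError(f"series must be >= 1, got {self.series}")


@dataclass(frozen=True)
class TileContext:
    """What a processor may need to know about the tile it was handed."""

    slide_filename: str
    series: int
    x_origin: int
    y_origin: int
    tile_width: int
    tile_height: int
    tile_path: Path
    tile_index: int  # 1-based position in the run over this slide
    n_tiles: int
    overlap: int = 0

    @property
    def tile_name(self) -> str:
        return tile_name(self.slide_filename, self.series, self.x_origin, self.y_origin)


@dataclass
class RunSummary:
    """Aggregate outcome of a run; failures carry (slide, tile, message)."""

    slides_processed: int = 0
    tiles_processed: int = 0
    tiles_retained: int = 0
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def merge(self, other: "RunSummary") -> None:
        self.slides_processed += other.slides_processed
        self.tiles_processed += other.tiles_processed
        self.tiles_retained += other.tiles_retained
        self.failures.extend(other.failures)


def void_processor(tile, context, store) -> None:
    """Do nothing: with tiles kept, the run becomes a pure tile export."""


def _tiles_dir(config: RunConfig) -> Path:
    return config.output_path / TILES_SUBDIR


def _prepare_output(config: RunConfig) -> Path:
    """Create the output and tile folders; fatal if not writable."""
    tiles_dir = _tiles_dir(config)
    try:
        tiles_dir.mkdir(parents=True, exist_ok=True)
        probe = tiles_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ConfigurationError(
            f"output folder not writable: {config.output_path} ({exc})"
        ) from exc
    return tiles_dir


def run_slide(
    slide: SlidePyramid,
    config: RunConfig,
    processor: TileProcessor,
    store: ResultsStore,
) -> RunSummary:
    """Process every grid tile of one open slide.

    Raises :class:`ConfigurationError` before reading any tile if the
    selected series does not exist or the output folder is unwritable;
    per-tile processor errors are collected, not raised.  The store is
    saved once at the end of the slide.
    """
    tiles_dir = _prepare_output(config)
    info = slide.series_info(config.series)
    grid = compute_grid(
        info.width_px, info.height_px, config.tile_size, config.overlap, config.series
    )
    slide_filename = slide.path.name
    summary = RunSummary()
    n = len(grid)
    t0 = time.monotonic()
    for i, spec in enumerate(grid, start=1):
        pixels = slide.read_region(
            config.series, spec.x_origin, spec.y_origin, spec.width, spec.height
        )
        name = tile_name(slide_filename, config.series, spec.x_origin, spec.y_origin)
        tile_path = tiles_dir / name
        tifffile.imwrite(str(tile_path), pixels, photometric="rgb")
        context = TileContext(
            slide_filename=slide_filename,
            series=config.series,
            x_origin=spec.x_origin,
            y_origin=spec.y_origin,
            tile_width=spec.width,
            tile_height=spec.height,
            tile_path=tile_path,
            tile_index=i,
            n_tiles=n,
            overlap=config.overlap,
        )
        try:
            processor(pixels, context, store)
        except Exception as exc:  # isolate: unsupervised batches continue
            logger.error("processor failed on %s: %s", name, exc)
            summary.failures.append((slide_filename, name, str(exc)))
        summary.tiles_processed += 1
        if config.keep_tiles:
            summary.tiles_retained += 1
        else:
            tile_path.unlink(missing_ok=True)
        del pixels
        logger.info(
            "%s: tile %d/%d (%.1fs elapsed)", slide_filename, i, n, time.monotonic() - t0
        )
    summary.slides_processed = 1
    store.save()
    return summary


def find_slides(input_path: Path) -> list[Path]:
    """Slide files for a run: a single file, or folder contents sorted
    lexicographically for deterministic batch order."""
    if input_path.is_file():
        return [input_path]
    if not input_path.is_dir():
        raise ConfigurationError(f"input path does not exist: {input_path}")
    return sorted(
        p
        for p in input_path.iterdir()
        if p.is_file() and p.suffix.lower() in SLIDE_EXTENSIONS
    )


def run_folder(config: RunConfig, processor: TileProcessor) -> RunSummary:
    """Process every slide under the input path against one shared store.

    A slide failing to open is recorded as a failure and the batch
    continues.  The shared store lives at the run's output folder.
    """
    _prepare_output(config)
    slides = find_slides(config.input_path)
    store = ResultsStore(config.output_path)
    summary = RunSummary()
    for path in slides:
        try:
            slide = open_slide(path)
        except (SlideTilerError, OSError) as exc:
            logger.error("cannot open %s: %s", path.name, exc)
            summary.failures.append((path.name, "", str(exc)))
            continue
        try:
            summary.merge(run_slide(slide, config, processor, store))
        finally:
            slide.close()
    store.save()
    return summary


BUILTIN_PROCESSORS: dict[str, TileProcessor] = {}


def _register_builtins() -> None:
    # Imported lazily to avoid a circular import at module load.
    from .hdab import hdab_slide_processor, hdab_tile_processor

    BUILTIN_PROCESSORS.update(
        {
            "void": void_processor,
            "hdab_tile": hdab_tile_processor,
            "hdab_slide": hdab_slide_processor,
        }
    )


def load_processor(processor_ref: Union[str, Path]) -> TileProcessor:
    """Resolve a processor reference to a callable, before any slide opens.

    ``processor_ref`` is a built-in name (``void``, ``hdab_tile``,
    ``hdab_slide``) or the path of a Python script defining a function
    ``process_tile(tile, context, store)``.
    """
    if not BUILTIN_PROCESSORS:
        _register_builtins()
    ref = str(processor_ref)
    if ref in BUILTIN_PROCESSORS:
        return BUILTIN_PROCESSORS[ref]
    path = Path(ref)
    if not path.exists():
        raise ProcessorLoadError(
            f"unknown processor {ref!r}: not a built-in "
            f"({', '.join(sorted(BUILTIN_PROCESSORS))}) and no such file"
        )
    spec = importlib.util.spec_from_file_location(f"slidetiler_user_{path.stem}", path)
    if spec is None or spec.loader is None:
        raise ProcessorLoadError(f"cannot import processor script {path}")
    module = importlib.util.module_from_spec(spec)
    try:
        spec.loader.exec_module(module)
    except Exception as exc:
        raise ProcessorLoadError(f"error importing {path}: {exc}") from exc
    fn = getattr(module, PROCESSOR_ENTRY_POINT, None)
    if not callable(fn):
        raise ProcessorLoadError(
            f"{path} does not define a callable {PROCESSOR_ENTRY_POINT}(tile, context, store)"
        )
    return fn
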