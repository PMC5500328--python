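"""Exception hierarchy for slidetiler.

Every error raised by the library derives from :class:`SlideTilerError` so
batch drivers can catch one type and keep an unsupervised run alive.
"""


class SlideTilerError(Exception):
    """Base class for all slidetiler errors."""


class UnsupportedFormatError(SlideTilerError):
    """The file exists but is not a readable TIFF slide."""


class SeriesIndexError(SlideTilerError):
    """A 1-based series index outside the slide's series list."""


class RegionBoundsError(SlideTilerError):
    """A requested region extends outside the series bounds."""


class GridParameterError(SlideTilerError):
    """Invalid tile-grid parameters (overlap >= tile size, non-positive dims)."""


class TileNameError(SlideTilerError):
    """A string does not match the tile file-name template."""


class ProcessorLoadError(SlideTilerError):
    """A processor reference could not be resolved to a callable."""


class ConfigurationError(SlideTilerError):
    """A run configuration is invalid (fatal, raised before any tile is read)."""


class MissingVariableError(SlideTilerError, KeyError):
    """get_var on a name never set."""


class StainBasisError(SlideTilerError):
    """A stain matrix that cannot be inverted."""


class NoDataError(SlideTilerError):
    """A query on an empty results table."""


class PlacementError(SlideTilerError):
    """Synthetic object placement failed after bounded retries."""
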