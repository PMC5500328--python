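"""Colour-deconvolution H/DAB positivity: the built-in reference analyses.

Brightfield immunohistochemistry slides stained with hematoxylin (blue
nuclear counterstain) and diaminobenzidine (DAB, brown peroxidase
product) are quantified by separating each RGB pixel into per-stain
"concentrations".  Absorbance is additive in optical density (OD)
space — ``OD = -log10(I / 255)`` per channel — so a pixel's OD vector is
a linear mix of the stains' unit absorbance vectors and the per-stain
concentrations solve a 3x3 linear system (colour deconvolution).

A pixel is DAB-positive (brown) when its DAB concentration reaches the
DAB threshold; otherwise it is hematoxylin (blue) when its hematoxylin
concentration reaches the H threshold; otherwise background.  Brown
takes precedence over blue so a DAB-positive nucleus counts as positive
regardless of counterstain.  Positivity is the nuclear-fraction score

    positivity_pct = 100 * brown_area / (blue_area + brown_area)

with the 0/0 blank-tile convention of 0.  Both raw areas are always
reported so any other denominator can be recomputed.

The default stain vectors are the Ruifrok–Johnston H-DAB set; the
default thresholds (0.15 OD) are validated only against the synthetic
slide generator and are NOT clinical-grade: no nuclei segmentation, no
stromal or in-situ discrimination is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NoDataError, StainBasisError
from .tiler import tile_name

__all__ = [
    "StainBasis",
    "PositivityResult",
    "RUIFROK_HDAB",
    "DEFAULT_TAU_H",
    "DEFAULT_TAU_D",
    "rgb_to_od",
    "deconvolve",
    "classify_hdab",
    "positivity",
    "analyze_image",
    "hdab_tile_processor",
    "hdab_slide_processor",
    "max_positivity_tile",
]

logger = logging.getLogger("slidetiler.hdab")

DEFAULT_TAU_H = 0.15  # OD threshold on hematoxylin concentration
DEFAULT_TAU_D = 0.15  # OD threshold on DAB concentration

TILES_TABLE = "tiles"
SLIDES_TABLE = "slides"


@dataclass(frozen=True)
class StainBasis:
    """Three unit absorbance vectors (R, G, B optical densities).

    Columns of the stain matrix M: hematoxylin, DAB, and a residual
    third stain completing the basis (by default the normalized cross
    product of the first two).  Vectors are re-normalized to unit
    Euclidean length on construction.
    """

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    residual: tuple[float, float, float] | None = None

    def matrix(self) -> np.ndarray:
        """The 3x3 stain matrix with unit stain vectors as columns."""
        h = np.asarray(self.hematoxylin, dtype=float)
        d = np.asarray(self.dab, dtype=float)
        if self.residual is None:
            r = np.cross(h, d)
        else:
            r = np.asarray(self.residual, dtype=float)
        m = np.stack([h, d, r], axis=1)
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms == 0):
            raise StainBasisError("stain vector with zero norm")
        m = m / norms
        if abs(np.linalg.det(m)) < 1e-12:
            raise StainBasisError("stain vectors are linearly dependent")
        return m


# Ruifrok & Johnston H-DAB absorbance vectors, the de-facto standard basis
# for hematoxylin/DAB separation; residual = normalized H x DAB.
RUIFROK_HDAB = StainBasis(
    hematoxylin=(0.650, 0.704, 0.286),
    dab=(0.268, 0.570, 0.776),
)


@dataclass(frozen=True)
class PositivityResult:
    """Pixel areas per stain class and the derived positivity percentage."""

    blue_area: int
    brown_area: int

    @property
    def positivity_pct(self) -> float:
        total = self.blue_area + self.brown_area
        if total == 0:
            return 0.0
        return 100.0 * self.brown_area / total


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density per channel.

    ``OD = -log10(max(I, 1) / 255)``: white (255) maps to exactly 0,
    black is clamped at intensity 1 (OD ~ 2.4065) so the transform stays
    finite.  Output is float64, same leading shape, 3 channels, >= 0.
    """
    image = np.asarray(image)
    if image.shape[-1] != 3:
        raise ValueError(f"expected RGB input with 3 channels, got shape {image.shape}")
    intensity = np.maximum(image.astype(np.float64), 1.0)
    od = -np.log10(intensity / 255.0)
    return np.maximum(od, 0.0)


def deconvolve(od: np.ndarray, basis: StainBasis = RUIFROK_HDAB) -> np.ndarray:
    """Solve M c = od per pixel: per-stain concentration maps.

    ``od`` is (..., 3); returns (..., 3) concentrations ordered
    (hematoxylin, DAB, residual).  Concentrations may be slightly
    negative where noise falls outside the stain cone; callers threshold.
    """
    m = basis.matrix()
    m_inv = np.linalg.inv(m)
    od = np.asarray(od, dtype=np.float64)
    return od @ m_inv.T


def classify_hdab(
    conc_h: np.ndarray,
    conc_d: np.ndarray,
    tau_h: float = DEFAULT_TAU_H,
    tau_d: float = DEFAULT_TAU_D,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold concentration maps into disjoint (blue, brown) masks.

    brown: conc_d >= tau_d.  blue: conc_h >= tau_h and not brown.
    Background pixels belong to neither mask.
    """
    if tau_h <= 0 or tau_d <= 0:
        raise ValueError("thresholds must be > 0")
    brown = conc_d >= tau_d
    blue = (conc_h >= tau_h) & ~brown
    return blue, brown


def positivity(blue_area: int, brown_area: int) -> PositivityResult:
    """Wrap pixel counts as a :class:`PositivityResult` (0-100 scale)."""
    if blue_area < 0 or brown_area < 0:
        raise ValueError("areas must be non-negative")
    return PositivityResult(blue_area=int(blue_area), brown_area=int(brown_area))


def analyze_image(
    image: np.ndarray,
    basis: StainBasis = RUIFROK_HDAB,
    tau_h: float = DEFAULT_TAU_H,
    tau_d: float = DEFAULT_TAU_D,
) -> PositivityResult:
    """Full per-image pipeline: OD -> deconvolution -> masks -> areas."""
    conc = deconvolve(rgb_to_od(image), basis)
    blue, brown = classify_hdab(conc[..., 0], conc[..., 1], tau_h, tau_d)
    return positivity(int(blue.sum()), int(brown.sum()))


# -- built-in tile processors ------------------------------------------


def make_tile_processor(
    basis: StainBasis = RUIFROK_HDAB,
    tau_h: float = DEFAULT_TAU_H,
    tau_d: float = DEFAULT_TAU_D,
):
    """A per-tile positivity processor with a custom basis/thresholds."""

    def process_tile(tile, context, store) -> None:
        _tile_step(tile, context, store, basis, tau_h, tau_d)

    return process_tile


def make_slide_processor(
    basis: StainBasis = RUIFROK_HDAB,
    tau_h: float = DEFAULT_TAU_H,
    tau_d: float = DEFAULT_TAU_D,
):
    """A whole-slide positivity processor with a custom basis/thresholds."""

    def process_tile(tile, context, store) -> None:
        _slide_step(tile, context, store, basis, tau_h, tau_d)

    return process_tile


def hdab_tile_processor(tile, context, store) -> None:
    """Per-tile positivity: one "tiles" table row per processed tile."""
    _tile_step(tile, context, store, RUIFROK_HDAB, DEFAULT_TAU_H, DEFAULT_TAU_D)


def _tile_step(tile, context, store, basis, tau_h, tau_d) -> None:
    result = analyze_image(tile, basis, tau_h, tau_d)
    store.append_row(
        TILES_TABLE,
        {
            "slide": context.slide_filename,
            "series": context.series,
            "x": context.x_origin,
            "y": context.y_origin,
            "blue_area": result.blue_area,
            "brown_area": result.brown_area,
            "positivity_pct": result.positivity_pct,
        },
    )


def hdab_slide_processor(tile, context, store) -> None:
    """Whole-slide positivity: accumulate per tile, one "slides" row per slide.

    Running blue/brown totals live in the variable store keyed by slide,
    so independent tile steps (and interrupted, resumed runs) share
    state.  With overlap > 0 overlapped pixels are counted once per
    covering tile; area fractions are only exact at overlap 0, so a
    warning is emitted.
    """
    _slide_step(tile, context, store, RUIFROK_HDAB, DEFAULT_TAU_H, DEFAULT_TAU_D)


def _slide_step(tile, context, store, basis, tau_h, tau_d) -> None:
    if context.tile_index == 1 and getattr(context, "overlap", 0) > 0:
        logger.warning(
            "overlap=%d > 0: slide-level areas double-count overlapped pixels; "
            "use overlap 0 for quantification",
            context.overlap,
        )
    result = analyze_image(tile, basis, tau_h, tau_d)
    blue_key = f"_hdab_blue::{context.slide_filename}"
    brown_key = f"_hdab_brown::{context.slide_filename}"
    blue = (store.get_var(blue_key) if store.has_var(blue_key) else 0) + result.blue_area
    brown = (
        store.get_var(brown_key) if store.has_var(brown_key) else 0
    ) + result.brown_area
    store.set_var(blue_key, blue)
    store.set_var(brown_key, brown)
    if context.tile_index == context.n_tiles:
        total = positivity(blue, brown)
        store.append_row(
            SLIDES_TABLE,
            {
                "slide": context.slide_filename,
                "blue_area": total.blue_area,
                "brown_area": total.brown_area,
                "positivity_pct": total.positivity_pct,
            },
        )


def max_positivity_tile(store) -> str:
    """Tile file name of the "tiles" row with maximal positivity.

    Ties resolve to the first-appended row.  With tiles retained on
    disk, the returned name identifies a file that can be re-opened for
    follow-up processing.
    """
    rows = store.rows(TILES_TABLE)
    if not rows:
        raise NoDataError(f"no rows in table {TILES_TABLE!r}")
    best = rows[0]
    for row in rows[1:]:
        if row["positivity_pct"] > best["positivity_pct"]:
            best = row
    return tile_name(best["slide"], int(best["series"]), int(best["x"]), int(best["y"]))
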