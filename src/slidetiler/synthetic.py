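"""Synthetic whole-slide fixtures with exact stain-area ground truth.

Generates pyramidal tiled TIFF "slides" that emulate H/DAB-stained
brightfield tissue at the level the engine and the positivity analyses
need: a white background (255,255,255) carrying hard-edged circular
"nuclei" painted at the exact 8-bit transmittance of a chosen optical
density along the hematoxylin or DAB absorbance vector.  Because edges
are hard (no anti-aliasing) and colors exact, the generator knows the
painted pixel count per stain to the pixel, so positivity recovery is
an exact integer test rather than a tolerance test.

What this does NOT emulate: scanner noise, stain intensity variation,
chromatin texture, overlapping nuclei, stromal tissue, compression
artifacts.  An optional Gaussian noise floor is available for eyeballing
robustness but breaks the exact-count guarantee.

Pyramid levels follow the halving rule ``dims(L) = ceil(dims(1)/2**(L-1))``
and are produced by 2x2 block averaging (edge-replicated padding for odd
dimensions) rounded half-up to 8 bits, so downsampled reads are
reproducible.  The same spec and seed always produce a byte-identical
file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import PlacementError
from .hdab import RUIFROK_HDAB, StainBasis

__all__ = ["SyntheticSlideSpec", "GroundTruth", "stain_rgb", "generate_slide"]


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``stain_od`` is the optical-density amplitude of painted objects
    (1.0 gives strongly stained, clearly supra-threshold nuclei);
    ``internal_tile`` is the storage-tile side (0 writes a stripped,
    non-tiled file); ``n_levels`` is the pyramid depth (1 = plain
    single-resolution image).
    """

    width: int
    height: int
    n_blue: int = 0
    n_brown: int = 0
    object_radius: int = 20
    stain_od: float = 1.0
    seed: int = 0
    internal_tile: int = 256
    n_levels: int = 3
    noise_sigma: float = 0.0
    basis: StainBasis = RUIFROK_HDAB


@dataclass
class GroundTruth:
    """Exact level-1 painted-pixel counts and object geometry."""

    blue_px: int
    brown_px: int
    blue_centers: list[tuple[int, int]] = field(default_factory=list)
    brown_centers: list[tuple[int, int]] = field(default_factory=list)
    radius: int = 0

    @property
    def expected_positivity_pct(self) -> float:
        total = self.blue_px + self.brown_px
        return 100.0 * self.brown_px / total if total else 0.0

    def to_json(self) -> str:
        payload = asdict(self)
        payload["expected_positivity_pct"] = self.expected_positivity_pct
        return json.dumps(payload, indent=1)


def stain_rgb(basis: StainBasis, stain: str, od: float) -> np.ndarray:
    """Exact 8-bit RGB of a pure stain at optical density ``od``.

    Transmittance per channel: ``I = round(255 * 10**(-od * v))`` with
    ``v`` the unit absorbance vector of the stain ('hematoxylin' or
    'dab').
    """
    m = basis.matrix()
    column = {"hematoxylin": 0, "dab": 1, "residual": 2}[stain]
    v = m[:, column]
    intensity = np.rint(255.0 * np.power(10.0, -od * v))
    return np.clip(intensity, 0, 255).astype(np.uint8)


def _disc_mask(radius: int) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(span, span, indexing="ij")
    return (xx * xx + yy * yy) <= radius * radius


def _place_objects(
    rng: np.random.Generator,
    width: int,
    height: int,
    n_objects: int,
    radius: int,
    taken: list[tuple[int, int]],
    max_attempts_per_object: int = 2000,
) -> list[tuple[int, int]]:
    """Rejection-sample integer centers fully inside bounds, pairwise
    non-overlapping with each other and with ``taken``."""
    if n_objects == 0:
        return []
    if width < 2 * radius + 1 or height < 2 * radius + 1:
        raise PlacementError(
            f"radius {radius} does not fit a {width}x{height} slide"
        )
    centers: list[tuple[int, int]] = []
    min_sq = (2 * radius + 1) ** 2  # strict separation: discs never touch
    for _ in range(n_objects):
        for _attempt in range(max_attempts_per_object):
            cx = int(rng.integers(radius, width - radius))
            cy = int(rng.integers(radius, height - radius))
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 >= min_sq
                for ox, oy in centers + taken
            ):
                centers.append((cx, cy))
                break
        else:
            raise PlacementError(
                f"could not place object {len(centers) + 1}/{n_objects} after "
                f"{max_attempts_per_object} attempts; use fewer or smaller objects"
            )
    return centers


def _paint(
    canvas: np.ndarray, centers: list[tuple[int, int]], mask: np.ndarray, color: np.ndarray
) -> int:
    """Paint discs onto the canvas; returns exact painted pixel count."""
    radius = mask.shape[0] // 2
    painted = 0
    for cx, cy in centers:
        canvas[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1][mask] = color
        painted += int(mask.sum())
    return painted


def _halve(level: np.ndarray) -> np.ndarray:
    """2x2 block mean with edge-replicated padding, rounded half-up to 8 bits.

    Integer arithmetic throughout (the 4-pixel sum fits uint16), so
    downsampling a large level needs at most ~2/3 of its own size in
    scratch memory and is bit-reproducible.
    """
    h, w = level.shape[:2]
    if h % 2:
        level = np.concatenate([level, level[-1:]], axis=0)
    if w % 2:
        level = np.concatenate([level, level[:, -1:]], axis=1)
    acc = level[0::2, 0::2].astype(np.uint16)
    acc += level[0::2, 1::2]
    acc += level[1::2, 0::2]
    acc += level[1::2, 1::2]
    return ((acc + 2) // 4).astype(np.uint8)


def generate_slide(
    spec: SyntheticSlideSpec,
    out_path: Union[str, Path],
    sidecar: bool = True,
) -> GroundTruth:
    """Write a synthetic slide and return its exact ground truth.

    The file is a tiled pyramidal TIFF (successive reduced-resolution
    IFDs, Deflate compression) unless ``spec.internal_tile == 0``, which
    writes a stripped file, or ``spec.n_levels == 1``, which writes a
    single-resolution image.  A ``<file>.groundtruth.json`` sidecar
    records the counts unless ``sidecar`` is false.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.height, spec.width, 3), 255, dtype=np.uint8)
    mask = _disc_mask(spec.object_radius)
    blue_color = stain_rgb(spec.basis, "hematoxylin", spec.stain_od)
    brown_color = stain_rgb(spec.basis, "dab", spec.stain_od)

    blue_centers = _place_objects(
        rng, spec.width, spec.height, spec.n_blue, spec.object_radius, taken=[]
    )
    brown_centers = _place_objects(
        rng, spec.width, spec.height, spec.n_brown, spec.object_radius, taken=blue_centers
    )
    blue_px = _paint(canvas, blue_centers, mask, blue_color)
    brown_px = _paint(canvas, brown_centers, mask, brown_color)

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, canvas.shape)
        canvas = np.clip(canvas.astype(np.float64) + noise, 0, 255).astype(np.uint8)

    tile_kw: dict = {}
    if spec.internal_tile > 0:
        tile_kw["tile"] = (spec.internal_tile, spec.internal_tile)
    n_levels = max(1, spec.n_levels)
    with tifffile.TiffWriter(str(out_path)) as writer:
        level = canvas
        for level_index in range(n_levels):
            writer.write(
                level, photometric="rgb", compression="deflate", **tile_kw
            )
            if level_index < n_levels - 1:
                level = _halve(level)

    truth = GroundTruth(
        blue_px=blue_px,
        brown_px=brown_px,
        blue_centers=blue_centers,
        brown_centers=brown_centers,
        radius=spec.object_radius,
    )
    if sidecar:
        sidecar_path = out_path.with_name(out_path.name + ".groundtruth.json")
        sidecar_path.write_text(truth.to_json() + "\n", encoding="utf-8")
    return truth
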