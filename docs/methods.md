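# Methods

## The processing model

`slidetiler` implements one abstraction: iterate a per-tile analysis
over a whole-slide image too large to hold in memory. A run is defined
by an input folder (or single slide), an output folder, a processor, a
1-based resolution series index, a tile side `T` (px), an overlap `V`
(px, identical in X and Y, `0 ≤ V < T`), and a keep/delete flag. The
engine makes no assumptions about the analysis; everything the workflow
needs beyond tile iteration — state between tiles, state between runs —
goes through the results store.

### Tile grid

Per axis of length `L`, tile origins are `k·(T − V)` for `k = 0, 1, …`,
stopping at the first tile that reaches the edge (`k·(T−V) + T ≥ L`).
Two deliberate choices:

- **Edge tiles are clipped, never shifted inward.** Shifting the last
  origin to `L − T` (as some tilers do) silently changes the local
  overlap and double-counts area in any aggregation. Clipping keeps the
  exact-partition property at `V = 0`: every pixel in exactly one tile,
  which is what makes tiled and whole-image pixel counting an *integer
  identity* rather than an approximation.
- **Origin generation stops at the first edge-reaching tile**, so no
  tile is wholly contained in its predecessor even at large `V`.

Tiles are ordered row-major (y outer, x inner) and slides are processed
in lexicographic filename order, so results tables are byte-reproducible
across runs.

### Coordinates and naming

Coordinates are 0-based, half-open, origin top-left, `x` = column — the
TIFF storage order — and always in the pixel grid of the *selected*
series, so a tile name identifies the exact `read_region` call that
re-extracts it. The name template is
`<OriginalFileName.ext>__<series>_<x>_<y>.tif`; parsing proceeds from
the right (last two `_`-tokens are y, x; the remainder splits at its
final `__`) so underscores, including doubled ones, inside slide file
names can never break the round trip.

### Slide access

TIFF reading is delegated to `tifffile`; windowed region reads go
through its zarr interface so only the storage tiles intersecting the
request are decoded — peak memory is a small constant times the region
size. Both pyramid dialects (successive reduced-resolution main IFDs,
and SubIFD-attached levels) are normalized into one flat 1-based series
list in file order. Companion series a file may carry (thumbnail,
label) cannot be reliably distinguished from pyramid levels without
format-specific heuristics, so they are listed as-is and series choice
is left to the user. Downsample factors are reported relative to series
1 as the mean of the width and height ratios.

### Failure semantics

Unsupervised overnight batches must not die mid-run: a processor
exception on one tile, or a slide that fails to open, is logged,
recorded in the run summary's failure list, and skipped. Only
configuration errors (invalid grid parameters, unwritable output,
unknown processor) are fatal, and they are raised before any tile is
read.

## Results store

Tables are append-only lists of rows (mappings of column name to number
or string); each table persists as `<name>.csv` (RFC 4180, UTF-8, `.`
decimal separator, quoting only when needed), with the header being the
first-seen-order union of row keys and missing cells left empty. Table
names are escaped to file-safe form by percent-encoding any character
outside `[A-Za-z0-9_-]`, which is invertible. Variables (scalars or
lists) live in one JSON sidecar, `_variables.json`. Numbers round-trip
losslessly (integers as integers, floats at full `repr` precision); one
documented CSV limitation: a *string* cell that parses as a number
(e.g. `"42"`) reloads as that number, since unambiguous typing of such
cells is not representable in plain CSV.

## H/DAB positivity

The per-pixel model is standard colour deconvolution. Transmitted
intensity `I ∈ {0..255}` converts to optical density per channel as
`OD = −log10(max(I,1)/255)` — white maps to exactly 0, and the clamp at
intensity 1 keeps black finite (OD ≈ 2.4065). A pixel's OD vector is
modeled as `M·c` with `M` the 3×3 matrix whose columns are unit
absorbance vectors for hematoxylin, DAB and a residual axis;
concentrations are `c = M⁻¹·OD`, computed by one precomputed inverse
applied per pixel.

Parameters, defaults, and why:

- **Stain vectors** — Ruifrok–Johnston H-DAB values, H =
  (0.650, 0.704, 0.286), DAB = (0.268, 0.570, 0.776) (RGB OD,
  normalized to unit length), residual = normalized H × DAB. These are
  the de-facto standard for H/DAB brightfield separation; real scanners
  and stain batches deviate, so the vectors are overridable via the run
  config file.
- **Thresholds** `τ_H = τ_D = 0.15` OD — low enough to catch moderate
  staining, high enough that 8-bit quantization noise around white
  (OD ≲ 0.002 per grey level) never classifies background. Validated
  only against the synthetic generator; not clinical.
- **Brown precedence**: masks are disjoint, brown = `c_DAB ≥ τ_D`,
  blue = `c_H ≥ τ_H ∧ ¬brown`. A DAB-positive nucleus counts as
  positive regardless of counterstain, which is what makes
  `100·brown/(blue+brown)` a nuclear-fraction score.
- **Denominator**: blue+brown (not total tissue). Both raw areas are
  always stored so any other score can be recomputed from the tables.
- **Blank convention**: positivity of (0, 0) is 0, keeping slide
  aggregation well-defined on empty tiles.
- **Overlap warning**: slide-level aggregation with `V > 0` counts
  overlapped pixels once per covering tile; `hdab_slide` logs a warning
  and `V = 0` is the documented quantification setting. Overlap is for
  boundary objects (e.g. mitosis screening), not area fractions.

`hdab_slide` keeps its running blue/brown totals in the variable store
keyed by slide filename and emits its row when `tile_index == n_tiles`;
`max_positivity_tile` breaks ties toward the first-appended row.

## Synthetic slides

The generator emulates exactly the features the engine and the
positivity analyses depend on: a white (255,255,255) background with
hard-edged discs painted at the exact 8-bit transmittance
`round(255·10^(−od·v))` of a pure stain at amplitude `od` (default 1.0)
along the hematoxylin or DAB vector. Discs have integer centers, a
common radius, are rejection-sampled to lie fully inside the slide and
pairwise non-touching, and so have identical pixel counts — painted
areas are known *exactly*, no anti-aliasing, making ground-truth
recovery an integer test. Pyramid level `L` has dimensions
`ceil(dims/2^(L−1))`, produced by 2×2 block mean (edge-replicated
padding for odd sizes) rounded half-up, in integer arithmetic, so files
are byte-identical for identical spec+seed. Slides are written as tiled
(default 256 px storage tiles, Deflate) or stripped TIFF.

What the generator does **not** emulate — and hence what passing tests
do not show about real slides: stain intensity variation, co-localized
(double-stained) pixels, chromatin texture, nuclear overlap, stromal
and in-situ tissue, scanner noise, stitching seams, JPEG color drift.
An optional Gaussian noise floor exists for eyeballing robustness but
voids the exact-count guarantee and is excluded from all quantitative
tests. Real-slide validity of the default thresholds is explicitly out
of scope.

## Numerical notes

- Deconvolution accuracy is limited by 8-bit quantization: synthesizing
  an H/DAB mix, quantizing to RGB, and deconvolving recovers
  concentrations to ~2×10⁻² at ODs up to ≈1.3 (the error scales with
  `1/(I·ln10)` through the inverse stain matrix); the linear solve
  itself matches an explicit adjugate/determinant inverse to 10⁻⁹.
  Only physical mixes are synthesizable: the residual axis has a
  negative green component, so exciting it alone would require
  transmittance above white.
- Concentrations may be slightly negative for pixels outside the stain
  cone; thresholds are positive, so classification is unaffected.
- The stain matrix must be nonsingular; a near-zero determinant raises
  a basis error at construction, not midway through a slide.
- Region reads are pure (bit-identical on repeat) because storage-tile
  decoding is deterministic; engine re-runs therefore produce
  byte-identical results CSVs.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen so the
full suite completes in well under a minute while still exercising every
contract at non-trivial size: quantification slides of 2048×1536 px
(tile sizes 256/512/1000, the last a deliberate non-divisor), randomized
grid domains up to 64×64 px with tile sizes up to 16, and one
16384×8192 px (134 Mpixel) streaming run at T = 512 verifying that
traced peak memory stays under a quarter of the decoded slide size.
Throughput on real hardware depends on the analysis and I/O; as a rule
of thumb larger tiles amortize per-tile open/save overhead, and tile
sides of a few thousand pixels are a sensible default (the CLI default
is 2048).

## Known limitations

- Only RGB 8-bit, single focal plane, single time point; no
  fluorescence or 16-bit support.
- No parallelism: cross-tile persistence through a shared store is
  order-sensitive, and the documented row order is part of the
  contract. Any future concurrency must preserve it.
- The CSV string-vs-number typing caveat above.
- The H/DAB demo analyses are illustrative, not validated for clinical
  use.
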