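# slidetiler

Tile-wise batch processing of whole-slide images (WSI), with built-in
H/DAB immunohistochemistry positivity analyses.

A digitized glass slide is a gigapixel RGB image stored as a pyramid of
progressively downsampled resolution series, each internally chunked
into small storage tiles. Image-analysis routines developed on single
microscopic fields cannot load such an image whole; the practical
workflow is always the same — extract a tile, run the routine on it,
iterate over the slide. `slidetiler` implements exactly that workflow
layer, and nothing else: it walks the tile grid of every slide in a
folder, hands each tile to a user-supplied per-tile processor, and
persists tiles and cross-tile results, with memory bounded by one tile
rather than the slide. It is aimed at researchers prototyping
quantitative pathology analyses (biomarker quantification, tissue
fractions, rare-event screening) who need their single-field code to
run unattended over full slides.

## What it does

- **Reads** pyramidal tiled TIFF and plain TIFF slides (both pyramid
  dialects: successive reduced-resolution IFDs and SubIFD levels),
  enumerating resolution series in file order, 1-based. Proprietary
  scanner formats can be supplied by an optional reader adapter
  (`register_reader`); they are not parsed by the core.
- **Tiles** the selected series with configurable tile size `T` and
  overlap `V` (identical in X and Y): origins step by `T − V` per axis,
  edge tiles are clipped, so at `V = 0` the tiles partition the image
  exactly. Overlap exists so objects straddling tile boundaries are not
  missed.
- **Names** every extracted tile after its position, so any tile is
  identifiable and re-extractable later:
  `<OriginalFileName.ext>__<series>_<x_origin>_<y_origin>.tif`
- **Runs** a processor — a built-in name or a Python script defining
  `process_tile(tile, context, store)` — on each tile, isolating
  per-tile failures so overnight batches never die mid-run. Tiles are
  materialized on disk before processing; `--keep-tiles` retains them,
  `--delete-tiles` (default) removes each after its processor returns.
- **Persists** cross-tile state in named append-only CSV tables plus a
  key/value variable store, the mechanism by which otherwise independent
  tile steps accumulate slide-level results.

## The built-in analysis: H/DAB positivity by colour deconvolution

Brightfield slides stained with hematoxylin (blue nuclear counterstain)
and diaminobenzidine (DAB, brown immunoperoxidase product) are
quantified per pixel. Absorbance is additive in optical-density space,

    OD_c = −log10(I_c / 255),   c ∈ {R, G, B},

so each pixel's OD vector decomposes over the stains' unit absorbance
vectors (Ruifrok–Johnston H-DAB set by default; overridable): solving
`M·c = OD` with the 3×3 stain matrix `M` yields per-stain concentrations
`c = (c_H, c_DAB, c_res)`. Thresholding gives disjoint masks — brown
where `c_DAB ≥ τ_D`, blue where `c_H ≥ τ_H` and not brown (brown takes
precedence: a DAB-positive nucleus is positive regardless of
counterstain) — and the slide score is the nuclear-fraction positivity

    positivity % = 100 · brown_area / (blue_area + brown_area),

defined as 0 on blank tissue. Defaults `τ_H = τ_D = 0.15` OD are
validated against the synthetic generator only; this is a demonstration
analysis, **not** clinical-grade scoring (no nuclei segmentation, no
stromal/in-situ discrimination).

Three built-in processors mirror the standard use cases: `hdab_tile`
(one results row per tile), `hdab_slide` (running totals per slide, one
row per slide), and the follow-up query `hdab-max` (the retained tile
with maximum positivity, re-openable for further processing). `void`
with `--keep-tiles` turns the tool into a pure tile exporter.

## Worked example

No downloads needed — the package generates its own slides with exact
ground truth (hard-edged discs painted at exact stain transmittances on
a white background):

```sh
$ slidetiler synth --width 1024 --height 768 --blue 7 --brown 3 \
      --radius 20 --seed 5 --out demo/slides/example.tif
wrote demo/slides/example.tif: blue_px=8799 brown_px=3771 expected_positivity_pct=30.0

$ slidetiler run --input demo/slides --output demo/results \
      --processor hdab_tile --tile-size 512 --keep-tiles
slides processed: 1
tiles processed: 4
tiles retained: 4
failures: 0

$ cat demo/results/tiles.csv
slide,series,x,y,blue_area,brown_area,positivity_pct
example.tif,1,0,0,2514,2514,50.0
example.tif,1,512,0,3771,0,0.0
example.tif,1,0,512,1257,1257,50.0
example.tif,1,512,512,1257,0,0.0

$ slidetiler hdab-max --results demo/results
example.tif__1_0_0.tif
```

Reading the numbers: each 20-px-radius disc covers exactly 1257 pixels,
so 7 blue + 3 brown discs give 8799 blue and 3771 brown pixels and an
expected slide positivity of `100·3771/(8799+3771) = 30.0%`. The
1024×768 slide splits into four 512-px tiles; the per-tile rows recover
the painted areas exactly (e.g. the top-right tile holds three whole
blue discs: 3·1257 = 3771 blue pixels, 0% positive). The most positive
tile, `example.tif__1_0_0.tif` (50%), was retained by `--keep-tiles`
and can be re-opened by name. Running `--processor hdab_slide` instead
yields one row with the slide totals and `positivity_pct` exactly 30.0,
identical for every tile size — per-pixel classification is local, so
at zero overlap tiled and whole-image quantification agree as an
integer identity.

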