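# histoquant

Atlas-based quantification of labelled objects in serial brain-section
images. Given colour-coded segmentation images (one exact RGB colour per
object class), section-matched atlas label maps, and an anchoring file
placing each section plane in 3D atlas space, histoquant:

- extracts individual objects by 4- or 8-connected flood fill and computes
  their statistics (position, bounding box, centroid, pixel and physical
  area);
- assigns each object to the atlas region under its top-left member pixel
  and tallies labelled area per region, with two attribution rules
  (whole-object by anchor, or pixel-by-pixel) exposed side by side;
- reports per-region and whole-section/series counts, areas and *load*
  (labelled area divided by region area), with custom region merges and
  exclusions;
- exports the 3D atlas-space coordinates of every segmented pixel (or
  object centroid) as TSV/JSON point clouds for external atlas viewers;
- renders overlay images of the objects colour-coded by region on the
  atlas map;
- provides image-series pre-processing (resize, quarter-turn rotation,
  mirroring, renaming) and a point-grid (stereological) area-fraction
  estimator for validation;
- generates fully synthetic input trees with exactly known ground truth
  (`histoquant fixtures`), so every stage is testable offline.

## CLI

```sh
# generate a synthetic ready-to-run input tree with ground truth
histoquant fixtures --seed 1 --out demo --sections 3

# run the full quantification pipeline from its config
histoquant quantify --config demo/config.toml

# or with explicit flags
histoquant quantify --segmentation-dir demo/segmentations \
    --atlas-dir demo/atlas --anchoring demo/anchoring.xml \
    --label-table demo/label_table.csv --pixel-size 0.284 \
    --resize-factor 0.05 --min-px 8 --max-px 1000000 --out demo/output

# point cloud only
histoquant points --config demo/config.toml --format tsv --out demo/points.tsv

# series pre-processing
histoquant transform --input-dir raw --output-dir prepped \
    --resize 0.05 --rename-template 'img_s{N:03}.png' --start 1 --step 4
```

Exit codes: 0 success, 1 partial failure (failed sections are recorded in
`manifest.json` and the remaining sections still complete), 2 config error.

## File dialects

- **Label table** (CSV): `id,name,acronym,red,green,blue,parent_id`;
  ids and colours must be unique, parent links acyclic. A background row
  (id 0) is auto-added if absent.
- **Atlas maps**: 24-bit colour PNG decoded exactly against the label-table
  palette (off-palette pixels are an error, never snapped), or a raw
  `QMAP` matrix (magic `QMAP`, little-endian uint32 width, height, then
  row-major uint32 region ids).
- **Anchoring**: XML
  `<series><slice filename=".." width=".." height=".." ox=".." ... vz=".."/></series>`
  or the equivalent JSON list. Each slice gives the plane origin `o` and
  in-plane vectors `u`, `v` in atlas voxel units; a pixel maps to
  `o + u*(x+0.5)/width + v*(y+0.5)/height` (pixel-centre convention;
  a corner convention is selectable).
- **Custom regions** (CSV): `group_name,member_ids` with ids separated by
  `;`; a token `<id>+` includes all hierarchy descendants; the pseudo-group
  `EXCLUDE` removes regions from reports and summaries.
- **Run config**: TOML (see `demo/config.toml` after running `fixtures`),
  or a CSV `key,value` template rendering of the same schema.

Sections are joined across files by the section number embedded in
filenames (default pattern `_s(\d+)`, configurable).

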