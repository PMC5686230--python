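# wsicyto

Whole-slide tissue cytometry for multiplexed immunohistochemistry (mIHC)
that combines fluorescence and chromogenic staining of the same FFPE
section. The package re-implements, as a reusable and testable Python
pipeline, the image-analysis platform of that assay family:

* **registration** of the brightfield and fluorescence whole-slide
  images using nuclei visible in both (haematoxylin as the reference,
  DAPI/Hoechst as the moving image), with SURF-family determinant-of-
  Hessian keypoints, ratio-test matching and RANSAC affine estimation;
* **colour de-convolution** of the RGB brightfield image into
  per-chromogen concentration maps via the Beer–Lambert model
  (`OD = -log10(I/255)`, concentrations `c = OD · M⁻¹` for a unit-norm
  stain matrix `M`);
* **tile–pad–stitch** processing: the registered slide is tiled into
  2048 × 2048 px cores, each padded to a larger context window so whole
  epithelial glands are visible to the per-tile analysis; stitched
  results keep a cell iff its centroid lies in its tile's half-open
  core, so nothing is lost or duplicated;
* **segmentation** of epithelial glands (global or adaptive Otsu +
  lumen filling + watershed at distance-transform maxima) and of cell
  nuclei (adaptive Otsu + watershed at intensity maxima, objects kept
  if their equivalent-circle diameter is 20–80 px at 0.64 µm/px);
* **single-cell cytometry**: mean marker intensity per nucleus
  (0–255, normalized to 0–1), positivity at `mean + k·SD` over all
  cells (k = 1; k = 3 for Ki67), compartment assignment by gland
  membership, and the two hierarchical classification schemes —
  immune (CD45 mask → epithelial/stromal leukocytes → T regulatory
  CD4⁺FoxP3⁺CD8⁻ / T helper CD4⁺FoxP3⁻CD8⁻ / T effector CD8⁺CD4⁻FoxP3⁻)
  and epithelial (a gland is malignant iff it contains no basal cell,
  i.e. no nucleus with ≥ 10 % area overlap with the CK5+p63 mask;
  its nuclei are then cancer / basal / benign-luminal / stromal);
* **statistics and QC**: Fisher's exact test (two-tailed, exact
  probability-mass method), two-sample Kolmogorov–Smirnov, Pearson's r,
  signal-to-background ratio `S/B = (mean(signal) − B)/B`, and the
  object-wise intensity-retention metric used in fluorochrome
  heat-stability tests.

Because real mIHC whole-slide images of this kind are not publicly
deposited, the package ships a first-class **synthetic slide
generator** (`wsicyto.synthetic`) that emulates glandular prostate
tissue — elliptical glands with lumina and epithelial rings, stromal
and immune cells, per-class marker profiles, autofluorescence, and a
brightfield image rendered through the Beer–Lambert forward model
under a planted similarity transform at a different pixel size. Every
planted quantity is returned, so each pipeline stage has a
parameter-recovery oracle.

## Worked example

```python
from wsicyto import PanelConfig, RunConfig, run_panel
from wsicyto.pipeline import immune_proportion_recovery, validate_against_truth
from wsicyto.synthetic import immune_config, generate_slide

cfg = immune_config(image_height_px=2048, image_width_px=2048, rng_seed=5)
fl, bf, truth = generate_slide(cfg)          # fluorescence, brightfield, truth

result = run_panel(fl, bf, cfg.bf_resolution,
                   PanelConfig(scheme="immune"),
                   RunConfig(core_size=1024, context_size=2048, seed=0))
val = validate_against_truth(result.cells, truth)
print(len(result.cells), "cells; recall %.3f" % val.recall)
print(immune_proportion_recovery(result.cells, truth).round(2).to_string())
```

Output from this exact run:

```
1351 cells; recall 0.988
                  quantity  recovered  planted  abs_error_pp
0   leukocyte_pct_of_cells      39.38    38.00          1.38
1  epithelial_pct_of_cells      38.19    40.00          1.81
2     stromal_pct_of_cells      22.43    22.00          0.43
3   treg_pct_of_leukocytes       6.95     4.74          2.22
4     th_pct_of_leukocytes      18.05    18.95          0.90
5     te_pct_of_leukocytes       9.02     8.95          0.08
```

1,351 of the 1,367 planted cells are detected (recall 0.988); the
recovered population shares — 39.3 % leukocytes, 38.2 % epithelial,
22.4 % stromal cells, and the T-subset shares among leukocytes — sit
within ~2 percentage points of the planted mixture (the remaining gap
at this slide size is dominated by the multinomial sampling noise of
the draw itself, e.g. the planted slide actually contains 7.1 % Treg
among leukocytes).

The same flow is available from the shell:

```bash
wsicyto simulate --scheme immune --size 2048 --seed 5 --out slide/
wsicyto run --channels slide/ --brightfield slide/brightfield.tif \
    --scheme immune --tile-size 1024 --context-size 2048 --out run/
wsicyto validate --cells run/cells.csv --truth slide/
```

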