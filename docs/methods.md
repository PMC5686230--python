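# Methods

## Scope and model

`wsicyto` analyses one tissue section imaged twice: a multi-channel
fluorescence whole-slide image (nuclear counterstain plus up to five
marker channels) and an RGB brightfield image of the same section after
chromogenic staining (haematoxylin plus two chromogens). The analysis
chain is: register the modalities onto a common grid, unmix the
chromogens, segment glands and nuclei tile by tile, measure markers per
cell, classify cells by fixed rules, stitch, and summarize.

All rasters are 8-bit; physical pixel size is carried in µm/px.
Coordinates are 0-based (row, col); pixel intervals are half-open;
transforms act on (x, y) = (col, row) with homogeneous 3×3 matrices.
A pixel index `i` corresponds to physical position `i · resolution` µm.

## Registration

The haematoxylin concentration map (from de-convolution) is the
reference; the fluorescence nuclear channel is the moving image. Both
are downscaled to working resolutions — 1.76 µm/px (haematoxylin) and
2.56 µm/px (nuclear) by default — where nuclei become blobs a few
pixels across.

*Detector.* Scale-normalized determinant of Hessian,
`σ⁴(I_xx I_yy − I_xy²)`, over a fixed ladder of six scales
(σ = 1.6 … 9.05 px, geometric), 3×3×3 local maxima above an absolute
threshold (5·10⁻⁴ on intensities scaled to [0, 1]), quadratic sub-pixel
refinement, strongest 2000 kept. *Descriptor.* A 12×12 patch sampled
over ±6σ around the keypoint, mean-subtracted and L2-normalized.
Because the window scales with the detected σ, descriptors are
comparable across images with different pixel sizes. Patches are
upright (no orientation assignment): re-mounted slide pairs rotate by
at most ~10–15°, within the tolerance of an upright patch; this keeps
the descriptor deterministic and simple. *Matching.* Mutual nearest
neighbours with a 0.75 distance-ratio test. *Estimation.* RANSAC
(3-point samples, 2 px inlier threshold at working resolution, 2000
trials, fixed seed) followed by a closed-form least-squares refit on the
inlier set.

One numerical subtlety matters at sub-pixel accuracy: `skimage`'s
`rescale` aligns pixel centres and uses the realized integer-size
ratio, so the native→working coordinate map is
`x_w = (x + 0.5)·f′ − 0.5` with `f′ = out_size/in_size` per axis. The
module composes the estimated working-grid transform with these exact
maps; ignoring the half-pixel convention left a systematic ~0.45 px
translation bias.

Registered channels are resampled onto the reference frame at
0.64 µm/px with bilinear interpolation and re-quantized to 8 bits. On
synthetic pairs with planted similarity transforms (rotation ≤ 10°,
noise sd 4), recovered translations are within ~0.1 px and rotations
within ~0.015° at working resolution.

## Colour de-convolution

Beer–Lambert in optical density: `OD_k = −log10(max(I_k, 1)/255)` (the
clamp keeps OD finite at full absorption) and `c = OD · M⁻¹` for a
stain matrix `M` of unit-norm rows. Whole-slide inputs are area-average
downscaled (default 1:4) *before* OD conversion, mimicking optical
blur. Negative concentrations are clipped to zero and the clipped
fraction is logged rather than raised — brightfield noise routinely
produces small negatives on near-white pixels. The published
haematoxylin/eosin/DAB vectors serve as development defaults; real
VinaGreen and Liquid Permanent Red vectors are configuration inputs
because no published values exist. Recovery of planted concentrations
is quantization-limited: the error stays within the per-pixel
concentration change that one 8-bit gray step induces through `M⁻¹`,
provided pixels are not fully absorbed (the log clamp destroys
information there).

## Segmentation

`otsu_level` maximizes between-class variance over all 256 candidate
levels in exact integer arithmetic (the variance ratio is compared by
cross-multiplication of Python integers), so it equals a brute-force
search exactly; ties break toward the lower level, and foreground is
`pixel > level`. `adaptive_otsu` computes per-block levels on a grid of
~200 px blocks and interpolates bilinearly between block centres.
Blocks with no real split — single-valued, or with class means closer
than 16 gray levels — fall back to the global level; without this
guard, background-only blocks Otsu-split their own noise, which on
synthetic slides manufactured dozens of false glands. Beyond the outer
block centres the map is clamped, so strong background gradients in the
outermost half-block are a known limitation.

Glands: threshold (global for the immune panel, adaptive for the
epithelial panel), morphological closing (disk r = 3), lumen filling
(so luminal cells count as "inside"), small-object removal
(< 500 px²), watershed seeded at distance-transform maxima (minimum
seed separation 60 px). Nuclei: adaptive Otsu on the smoothed (σ = 2 px)
nuclear channel, watershed seeded at smoothed intensity maxima, objects
kept when the equivalent-circle diameter 2√(A/π) is within 20–80 px.
Seed suppression uses *half* the minimum diameter (10 px): the peak
finder suppresses within a Chebyshev (square) radius, and a full
20 px radius removed genuine neighbours ~22 px apart on the diagonal,
costing ~20 % of densely packed cells.

## Cytometry and classification

Marker intensity is the mean over the nucleus object; normalization is
a fixed global rescale raw/255 (not per-marker min–max), so expression
levels are comparable across classes and slides. Positivity is strictly
greater than `mean + k·SD` (population SD) over all cells; k = 1 except
Ki67, where k = 3 because the marker is rare and a 1-SD cut sits inside
the negative mode. Leukocyte status uses overlap of the nucleus with
the CD45 Otsu mask (≥ 10 % of nucleus area, the same fraction the
CK5+p63 basal rule uses) rather than intensity thresholding. Compartment
is decided by the centroid pixel: inside a hole-filled gland object →
epithelial. Gland malignancy is the complete absence of basal cells.
Label sets are closed partitions (10 immune labels, 4 epithelial
labels); exhaustive rule truth tables are enforced in the test suite.

## Tiling and stitching

Cores (2048 px) partition the slide exactly; context windows (default
10240 px, reduced for small slides) are centred on cores and zero-filled
beyond the slide edge. Segmentation and measurement run per context;
stitching keeps a record iff its centroid falls in its own tile's
half-open core, which makes the output independent of how many context
windows saw the object. Gland-level attributes (basal count, malignancy)
are computed per tile; since every context fully contains the glands
relevant to its core, the same gland gets identical attributes in every
tile that sees it, and stitched gland identities are resolved by
centroid coincidence (tolerance 25 px). The context margin must exceed
the largest gland radius for this to hold — with the synthetic
generator's glands (semi-axes ≤ 230 px) a 3072 px context over 2048 px
cores suffices.

## Synthetic slides

The generator emulates: elliptical glands (semi-axes 110–230 px at
0.64 µm/px, i.e. ~70–150 µm) placed on a jittered grid so glands never
touch, covering ~26 % of the section; an epithelial ring with an empty
lumen (lumen at 35 % of the axes in benign, 25 % in cancer glands);
basal cells only on the outer ring of benign glands; stromal cells
outside glands; immune cells anywhere. Nuclei are placed with a hard-core
minimum spacing of 22 px (≈ 14 µm) as in packed tissue and drawn as
isotropic Gaussians (σ = radius/2, radius 18 ± 1.5 px) on the nuclear
channel; marker channels reuse the footprint with class-specific
amplitudes (expressed ≈ 200 ± 12, background ≈ 4). The pan-epithelium
channel adds a constant ring field (120) so glands are contiguous.
Background is autofluorescence (8) plus Gaussian noise (sd 2; no
published noise model exists for this imagery, so this is a convention). Cell counts
follow a density of 800 /mm² (immune) or 550 /mm² (epithelial panel,
whose single-file basal rings need placement head-room); class labels
are multinomial draws from the planted mixture — 38 % leukocytes / 40 %
epithelial / 22 % stromal for the immune panel, 20 % cancer / 11 %
benign luminal / 15 % basal / 54 % stromal for the epithelial panel.

The brightfield image lives on its own grid (0.80 µm/px) under a
planted similarity transform (rotation, uniform scale, translation in
µm); haematoxylin concentration is stamped at every nucleus, the
gland chromogen on epithelial rings, and an accent chromogen on
Ki67⁺ (immune) or AMACR⁺ (epithelial) cells; the RGB image is the
Beer–Lambert rendering plus noise, quantized to 8 bits. AR amplitude is
shifted down in AMACR⁺ cells so the AR–AMACR association is negative,
as in the tissue the panel was designed for.

What the generator does **not** emulate: real chromatin texture,
out-of-focus blur, uneven illumination, section folds, overlapping
nuclei in z, or spectral crosstalk between fluorescence channels.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated geometric and photometric model, not
performance on real scanner data.

## Problem sizes and determinism

The acceptance suite runs the immune panel end-to-end on an
8192 × 8192 px slide (~27.5 mm², ~22,000 cells) with 2048 px cores and
3072 px contexts, the epithelial panel on 4096 × 4096 px, 50
registration pairs at 1024 × 1024 px, and the exhaustive statistics
sweeps (all 2×2 tables with N ≤ 40). `scripts/acceptance.py` uses
4096 px slides and 10 registration pairs, sizes chosen so a single-CPU
run finishes in a few minutes. All randomness flows from explicit
seeds; identical configuration and seed reproduce outputs bit for bit,
including CSVs.

## Known limitations

* Upright descriptors limit registration to small rotations (~±15°).
* Single working scale; no multi-resolution refinement.
* Adaptive thresholds are clamped beyond the outer block centres.
* The KS p-value is asymptotic (effective n = nm/(n+m)); exact
  small-sample p-values are out of scope because cell-population
  comparisons in this domain involve thousands of cells.
* The "background noise thresholding" S/B variant is an interpretation
  (signal pixels at or below the background Otsu level are excluded);
  it is off by default and clearly flagged.
* The class-overlay visualization paints cells at centroids rather than
  repainting full label masks at slide scale.
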