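# Methods

This note documents the models and procedures implemented in `apicoloc`, the
parameters that matter, what the synthetic generators do and do not emulate,
and the design choices made where the underlying protocols leave the
algorithm open.

## 1. 4i preprocessing

**Projection.** Confocal z-stacks are reduced by maximum-intensity projection
(per-pixel max over z). Projection is idempotent and preserves channel
metadata.

**Cross-cycle registration.** Staining/elution cycles re-image the same field
with a small, essentially translational stage error. The offset of each
cycle's DAPI image against cycle 1 is the integer `(dy, dx)` maximizing the
zero-normalized cross-correlation (NCC) over the geometric overlap, searched
exhaustively in a ±`max_shift_px` window (default 32 px). Ties (to 12
decimals) break toward the smallest `|dy|+|dx|`, then lexicographic
`(dy, dx)` — the zero shift wins over equally good alternatives. The search
is accelerated with an FFT cross-correlation for the product sums and
integral images for the per-window moment sums; this reproduces the
exhaustive argmax exactly (a direct per-offset implementation is kept as a
reference and the test suite confirms the equivalence).

Registration is **integer-pixel only**: no interpolation, so pixel
intensities are never resampled and downstream Pearson statistics are
unaffected by alignment. Each cycle's non-nuclear channels are shifted by
their cycle's DAPI offset; all images are then cropped to the intersection of
the shifted frames. Border fill for synthetic translations is a constant
(the background level in the generators; 0 by default in `translate`) and
fill never enters the overlap statistics because the overlap is defined
geometrically.

**Flat-field correction.** The illumination surface is the per-pixel median
across images of a channel, blurred with a Gaussian of sigma = 10 % of the
image width and normalized to mean 1; images are divided by it. The median
image is padded by odd reflection before blurring so linear intensity ramps
(the leading term of vignetting) are estimated without border bias; a known
linear gradient is inverted to a flat image to well under 1 %.

## 2. Thresholds

Two histogram thresholds drive all mask creation, both computed exhaustively
over a 256-bin histogram of the image's intensity range:

* **Otsu (2-class)** maximizes the between-class variance
  `w0·w1·(μ0−μ1)²`.
* **Minimum cross-entropy (Li)** minimizes `−(S0·log μ0 + S1·log μ1)` where
  `S` and `μ` are the class intensity sum and mean. The criterion requires
  positive class means (it is not shift-invariant), so it is defined for
  nonnegative data and cuts that isolate only zero-valued pixels are skipped.

Class statistics are computed from exact per-bin intensity sums (not bin
centers), so for integer 8-bit data — where every value occupies its own
bin — the selected cut agrees exactly with a brute-force search over all 255
integer cut points. The returned scalar threshold is the largest float below
the first foreground bin edge, making `pixels > threshold` reproduce the
histogram partition bit-exactly. Constant images raise a degenerate-input
error. These implementations exist because the contract demands exhaustive
grid semantics with an exact tie-break; `skimage.filters.threshold_otsu` /
`threshold_li` (an iterative root-finder) serve as independent cross-checks
in the tests.

## 3. Three-tier segmentation

* **Nuclei** (primary): Otsu foreground of DAPI → fill holes →
  distance-transform watershed to split touching nuclei (peak seeds at least
  one typical nucleus radius apart) → area filter (defaults 50–5000 px,
  config-overridable) → contiguous relabeling. An empty foreground yields an
  empty map with a warning, not an error.
* **Cells** (secondary): foreground = ER (calnexin) channel above its
  minimum-cross-entropy threshold, unioned with the nuclei; each foreground
  pixel is assigned to the **geodesically nearest** seed nucleus by a
  multi-source BFS implemented as iterated masked 8-connected dilation (one
  pixel step per sweep, so claims happen in order of within-foreground
  chessboard distance; equidistant ties go deterministically to the larger
  label). No installed library exposes multi-source geodesic label
  propagation directly (watershed on a constant image is not
  distance-ordered), hence the in-package implementation, verified against a
  brute-force BFS oracle.
* **Cytoplasm** (tertiary): per-label set difference cell − nucleus; a
  nucleus pixel outside its own cell is an inconsistency error; empty
  cytoplasm is allowed.
* **Border filtering:** any label owning a pixel in the first/last row or
  column is removed entirely, and survivors are renumbered.

8-connectivity is used for all connected components.

## 4. Per-cell colocalization

For each cell label, the sample Pearson coefficient between two aligned
marker images is computed over that cell's pixels from exact labelled moment
sums. A marker with zero variance inside a cell makes r undefined: the value
propagates as NaN, is excluded from well means, and the exclusion count is
logged. Correlations are computed over whole-cell pixels by default (the
label map passed in decides; pass the cytoplasm map to restrict).

Compartment overlap is `|cargo ∩ compartment ∩ cell| / |cargo ∩ cell|` on
binary masks; cells without cargo pixels are undefined/NaN. Over any
partition of the cell the fractions sum to 1 exactly.

Treatment effects: cells are averaged per well; each treated well's mean
minus the mean of control wells (`design="pooled"`, default) or its matched
control well (`design="paired"`) gives per-replicate deltas tested with the
closed-form two-tailed one-sample t against 0. Identical deltas (zero
variance) are reported as a degenerate-variance signal rather than an
invented p-value.

## 5. Apicality scoring

Chain and defaults (all quantile parameters are relative to the distribution
within the stated region, making the procedure invariant to intensity
scale):

1. **Tissue**: Gaussian-blurred DAPI (sigma 5 µm), Otsu, hole fill, erosion
   by a 2 µm margin to drop the peripheral edge.
2. **Cortex**: texture energy = local standard deviation of LTL in a 16 µm
   window; Otsu over the whole energy image (textured cortex versus quiet
   background) intersected with tissue. The threshold is deliberately taken
   over the full image: within tissue alone the energy has almost no
   contrast and Otsu would split noise.
3. **Papilla exclusion**: the papilla is strongly MUC1-positive but is not
   cortex. Connected regions of MUC1 above the 0.98 tissue quantile that are
   at least 200 µm² (anatomy, not noise speckle or apical-band fragments)
   are dilated by 2 µm — covering the texture-energy spillover at their
   boundary — and subtracted from the cortex.
4. **Apical area**: MUC1 ≥ its 0.95 quantile within cortex, intersected with
   cortex, despeckled (≥ 9 px). The generator's default geometry keeps the
   apical band at ~6 % of the cortex so this quantile falls inside the
   apical intensity class.
5. **Tubular area**: Euclidean-distance expansion of the apical area by 8 µm
   (distance transform, physical units), restricted to the low-MUC1 region
   (MUC1 ≥ its 0.50 quantile within cortex). Cellular tissue is weakly
   MUC1-positive while the intratubular space is not, so the restriction
   excludes the lumen. **Intracellular area** = tubular − apical, exactly.
6. **Score**: tubule instances are 8-connected components of the tubular
   area. Per tubule, the mean cargo over the whole tubular component decides
   positivity; the cutoff is Otsu over the per-tubule means, applied only
   when those means carry at least twofold contrast (below that, all tubules
   are cargo-positive and Otsu would split noise); a fixed cutoff can be
   supplied instead. Per positive tubule, ratio = A/B of mean cargo in the
   apical versus intracellular area; a tubule with empty intracellular area
   or B = 0 is excluded and logged. The section score is the unweighted mean
   ratio over scored tubules.

The score is invariant to any positive gain on the cargo channel (a ratio of
means) and equals 1 for spatially uniform cargo.

## 6. Histomorphometry

* **Positive-cell fraction** (TUNEL-, CD45-like): a cell is positive when at
  least `min_overlap_frac` (default 0.5) of its nucleus pixels lie in the
  marker mask. For membranous markers the nucleus can be ring-dilated
  (`dilate_um`, suggested 2 µm for CD45) before the test.
* **Positive-area fraction** (α-SMA-like): thresholded-pixel fraction within
  a region, threshold by Otsu, minimum cross-entropy, or a fixed value.
* **Trichrome blue/red percent**: RGB pixels classified by channel dominance
  (blue if B > 1.2·R, red if R > 1.2·B, each above a saturation floor of 50
  on the 8-bit scale); the fibrosis index is 100·|blue|/|red|; zero red
  pixels is an undefined-ratio error. Channel-dominance classification was
  chosen over stain deconvolution because only the area ratio is required.

## 7. Statistics

One-sample t (`t = (x̄−μ0)/(s/√n)`, df = n−1) and Welch's two-sample t with
Satterthwaite df are computed from the closed-form expressions; only the
Student-t tail probability comes from scipy. Welch's unequal-variance form is
the default for unpaired comparisons as the safer choice when variance
equality is unknown. ANOVA and post-hoc families are out of scope; where a
report needs them they should be delegated to statsmodels/scipy.
`aggregate` reduces observation tables to one mean per replicate unit per
metric with missing-value exclusion counts and flags units with no usable
observations.

## 8. Synthetic data: what it emulates, and what it does not

**Tissue sections** (`TissueSpec`, defaults): 512×512 px at 0.5 µm/px; one
tissue disk (radius 46 % of the frame); 18 tubules of outer radius 14 µm with
6 µm lumen and 3 µm apical band, centers placed on a jittered grid with
spacing ≥ 2.6× the outer radius (satisfying the ≥ 2× contract and keeping
8 µm expansions of neighboring tubules disconnected); background 20,
signal 2000, Gaussian noise sd 10, PSF blur sigma 0.5 µm; LTL carries a
sinusoidal texture of 8 µm period over the cortex; MUC1 is high in the
apical bands, at 15 % of signal in cellular tissue, at background in lumens,
and at 2× signal in the optional papilla (12 % of the tissue radius, < 2 %
of tissue area so the 0.98 papilla quantile separates it from apical bands).
Per positive tubule the cargo budget is `signal_level × (apical band pixel
count)`, split `apical_fraction : 1−apical_fraction` between the apical band
and the intracellular annulus (uniformly within each); total cargo intensity
is therefore conserved across the split, and with all cargo apical the
tubule ratio is (background+signal)/background ≈ signal/background to ~1 %.
Pixel pitch (0.5 µm tissue / 0.2 µm cells) was chosen so the 8 µm expansion
is a nontrivial integer pixel radius.

**4i stacks** (`FourISpec`, defaults): 512×512 px at 0.2 µm/px; cells as
disks (radius 4 µm, nucleus 2 µm) on a jittered grid; per-cycle channel
plans with DAPI always present; each cycle is the cycle-1 scene translated
by that cycle's integer shift (declared maximum, default 32 px) with fresh
additive Gaussian noise. Compartments are angular sectors of the cytoplasm;
cargo mask pixels are sampled per compartment at the specified ground-truth
fractions. Correlated marker pairs are rendered from jointly Gaussian
latents built by factoring the requested correlation matrix (Cholesky with
an eigenvalue fallback; an indefinite matrix is an invalid-spec error). For
a single pair this is the classic mixing construction
`B = ρ·Z + √(1−ρ²)·W`, which attains any ρ ∈ [−1, 1] exactly in
expectation. Optional z-stacks multiply the scene by a per-plane profile
with maximum 1, so the per-pixel max over z reconstructs the 2-D scene.

**Not emulated** (by design): photorealistic optics, spectral bleed-through,
Poisson shot noise (additive Gaussian only — the simplest model that
exercises thresholds and correlations), antibody-elution chemistry across
cycles, rotation or affine stage errors, irregular cell/tubule shapes, and
inner/outer medulla sub-regions. Passing tests therefore demonstrate the
correctness of the measurement chain on images whose geometry and noise obey
these simplifications — not robustness to the full variability of real
acquisitions.

## 9. Numerical choices and degenerate inputs

* 256-bin histograms, 8-connectivity, exact labelled moment sums throughout.
* NCC tie-break and the zero-variance guard (`var ≤ 1e-12 × Σx²`) are
  scale-aware; an all-constant overlap at every offset is an unalignable-pair
  error.
* Undefined statistics (zero-variance Pearson, cargo-free overlap, B = 0
  ratios) propagate as NaN and never enter aggregates.
* Generator placement uses jittered grids rather than rejection sampling:
  minimum spacing holds by construction, feasibility is decided exactly
  (fewer admissible slots than requested objects is an infeasible-spec
  error), and dense packings do not hang.
* Problem sizes used by the test suite and the acceptance script: 100
  registration trials at 192² px, 50 threshold fixtures at 64² px, tissue
  sections at 512² px, and the treatment-direction experiment at 3 wells ×
  2 conditions × 400 cells on 960² px fields — together about two minutes on
  one CPU.

## 10. Known limitations

* Integer-pixel registration cannot represent sub-pixel drift; on real data
  this leaves up to half a pixel of residual misalignment per cycle.
* Quantile-based MUC1 thresholds assume the apical band occupies less than
  `1 − high_quantile`… of the cortex only in the noiseless limit; with noise
  the apical mask recall degrades gracefully (the quantile keeps the
  brightest fixed fraction of pixels).
* Tubule instances are connected components of the tubular mask; tubules
  whose expansions touch would merge (the generator's default spacing avoids
  this, real sections may not).
* The Otsu positivity cutoff for tubules assumes a bimodal separation of
  per-tubule means; the twofold-contrast guard handles the all-positive
  case but intermediate mixtures may misclassify borderline tubules.
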