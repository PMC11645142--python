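# apicoloc

Quantitative image analysis for protein-trafficking studies in kidney
epithelia: multi-cycle immunofluorescence (4i) single-cell colocalization,
tissue-level **apicality** scoring of apical-membrane protein localization,
and per-field histomorphometry — together with synthetic-microscopy
generators that provide full ground truth for every stage.

## Who this is for

Misfolding mutations in secretory proteins such as uromodulin (UMOD, the most
abundant protein in human urine) trap the protein inside tubular epithelial
cells instead of letting it reach the apical plasma membrane. Assessing
whether an intervention restores apical trafficking requires two kinds of
image-derived readouts:

* **In cultured cells**, iterative indirect immunofluorescence (4i) images
  the same cells over many stain/elute cycles. Quantifying where a cargo
  protein sits requires registering the cycles (the stage never repositions
  perfectly), segmenting nuclei → cells → cytoplasm, and measuring per-cell
  colocalization of the cargo with compartment markers (COPII/COPI, Golgi,
  endosomes, lysosomes).

* **In tissue sections**, polarity is scored per tubule: how much cargo is on
  the apical membrane versus inside the cells.

No public imaging data accompanies studies like these, so the package ships
generators for both image types with known ground truth (masks, shifts,
compartment splits, correlations), making the whole pipeline testable on a
laptop.

## The statistics at the core

**Apicality ratio.** In a section stained for DAPI / UMOD / MUC1 / LTL, the
cortex is found from LTL texture, the apical membrane band from a high MUC1
quantile, and each tubule is the apical band expanded by 8 µm within the
low-MUC1 region (excluding the lumen). For each UMOD-positive tubule with
mean apical cargo *A* and mean intracellular cargo *B*,

```
apicality = A / B,     section score = mean over UMOD-positive tubules
```

A score ≫ 1 means apically polarized cargo; ≈ 1 means the cargo is as common
inside the cells as on the membrane.

**Single-cell colocalization.** After NCC registration of cycles on DAPI and
three-tier segmentation, each cell *c* gets the sample Pearson coefficient
r(X, Y) between marker pixels, and the overlap fraction

```
f(c, k) = |cargo ∩ compartment_k ∩ c| / |cargo ∩ c|
```

Well means of these metrics are compared as treated-minus-control deltas with
a two-tailed one-sample t-test against 0 (Welch's t for unpaired group
comparisons).

## Worked example

```python
import apicoloc as ap

# a synthetic kidney section: 18 tubules, 30% of cargo in the apical band
spec = ap.TissueSpec(seed=7, apical_fraction=0.3)
channels, truth = ap.generate_tissue(spec)
result, regions = ap.score_section(channels)
print(f"section score: {result.score:.3f} over {result.n_tubules} UMOD-positive tubules")

# a 'treated' section with restored apical trafficking (80% apical cargo)
treated, _ = ap.generate_tissue(ap.TissueSpec(seed=7, apical_fraction=0.8))
print(f"treated section score: {ap.score_section(treated)[0].score:.3f}")
```

prints

```
section score: 1.558 over 18 UMOD-positive tubules
treated section score: 5.861
```

The per-tubule table (`result.tubules`) carries A, B, the ratio, areas and
the positivity flag for every tubule; the first rows of the run above:

```
 tubule  apical_mean_A  intracellular_mean_B  ratio
      1         600.74                383.22   1.57
      2         601.16                391.20   1.54
      3         602.49                376.77   1.60
```

Raising the generator's apical fraction from 0.3 to 0.8 raises the score from
1.56 to 5.86 — the score tracks how much cargo actually reaches the apical
membrane.

The 4i side works the same way from a `FourISpec` through
`generate_4i_stack`, `align_and_crop`, `segment_nuclei` / `segment_cells`,
and `pearson_per_cell` / `overlap_fraction`; `analyze_4i_well` runs the whole
chain on one well. A thin CLI exposes each stage
(`apicoloc simulate|align|segment|coloc|apicality|histo|report`).

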