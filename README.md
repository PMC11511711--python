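# shgmorph

Label-free collagen morphometry for second-harmonic-generation (SHG)
microscopy. The package quantifies how interstitial collagen remodels
during disease progression (its reference application is the endometrial
stroma across normal tissue, hyperplasia, atypical hyperplasia and
carcinoma) from nothing but a grayscale SHG image and its pixel size.

## What it computes

For each 150 × 150 μm interstitial region the pipeline runs

1. **Segmentation** — a two-component Gaussian mixture is fitted to the
   pooled pixel intensities by EM (deterministic Otsu-split
   initialisation); a pixel is collagen when the posterior of the
   brighter component is ≥ ½.
2. **Fiber-network extraction** — the collagen mask is skeletonized to a
   1-px, 8-connected medial skeleton; the skeleton decomposes into
   branches between endpoints and junctions; at each junction, branch
   pairs whose tangents continue within a turn limit (default 60°) are
   greedily re-joined so a fiber tracks straight through a crossing. Each
   fiber is an ordered vertex list; a vertex shared by ≥ 2 fibers is a
   cross-link point.
3. **Eight morphological features** —

   | feature | definition |
   |---|---|
   | proportionate area (%) | collagen pixels / all pixels × 100 |
   | fiber number (1/μm²) | extracted fibers per region area |
   | fiber length (μm) | Σ distances between adjacent vertices |
   | fiber width (μm) | mean vertex → nearest-background distance (exact EDT) |
   | straightness | chord(first, last) / length, in (0, 1] |
   | cross-link density (1/μm) | cross-link points / Σ fiber lengths |
   | cross-link space (μm) | mean along-fiber distance between adjacent cross-links |
   | orientation index | 1 − short/long axis of the FFT power-spectrum ellipse |

4. **Group statistics** — per-group mean ± SD, one-way ANOVA (two-sided,
   α = 0.05) and Tukey-HSD pairwise comparisons with significance stars.

Because clinical SHG images are rarely shareable, the package ships a
synthetic fiber-field generator (`shgmorph.synthetic`) that emulates an
interstitial region — truncated-normal fiber lengths, von Mises axial
orientations, sinusoidal waviness solved to an exact chord/arc ratio,
integer-width ribbons, Poisson + Gaussian noise — with exact per-fiber
ground truth, so the whole chain is verifiable end to end.

## Worked example

```python
import shgmorph as sm

spec = sm.FieldSpec(n_fibers=40, crossing_rate=0.0, seed=3)
truth = sm.sample_fibers(spec)
image, clean = sm.render_field(truth, spec)

mask = sm.segment(image)                      # GMM binarization
network = sm.extract_fibers(sm.skeletonize(mask))
feats = sm.compute_feature_set(image, network, mask)
oracle = sm.analytic_features(truth, spec)    # ground-truth geometry

print(f"{'feature':<22}{'pipeline':>10}{'truth':>10}")
for name in sm.FEATURE_NAMES:
    print(f"{name:<22}{getattr(feats, name):>10.4f}{getattr(oracle, name):>10.4f}")
```

prints

```
feature                 pipeline     truth
area_pct                  9.3218    9.3218
number_per_um2            0.0018    0.0018
length_um                15.2499   15.5048
width_um                  1.5109    1.5316
straightness              0.8984    0.8970
xlink_density_per_um      0.0000    0.0000
xlink_space_um               nan       nan
orientation_index         0.2645    0.8179
```

The pipeline recovers count, area, length, width and straightness to
within a few percent of the generator's analytic truth on this separated,
crossing-free field; cross-link features are zero/undefined because no
fibers cross. The two orientation numbers measure anisotropy on different
objects (the FFT spectral index of the rendered mask vs. the
length-weighted orientation tensor of the ideal centerlines) and agree
only in their limits (0 isotropic, 1 aligned).

Real images go through the same functions (`sm.read_image`,
`sm.sample_regions`, `sm.run_pipeline`) or the CLI:

```bash
shgmorph simulate --out sim --seed 4
shgmorph features sim/image.tif --out feat
shgmorph run --config pipeline.yaml --seed 1
```

`run` writes `features.csv` (one row per specimen/ROI/region),
`group_summary.csv` (mean ± SD, ANOVA, Tukey stars), per-region mask
TIFFs and network JSONs, and a reproducibility manifest.

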