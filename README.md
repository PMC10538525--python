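# rootpouch

Phenotyping toolkit for 2D growth-pouch root images: background-cleaning
segmentation, extraction of 12 root morphological/architectural traits, the
supporting validation and genetics statistics, and a synthetic image
generator with analytic ground truth for end-to-end benchmarking.

## What it does

- **`rootpouch.synthgen`** — parametric root systems (tap root + non-crossing
  laterals), their analytic trait values, and pouch-style renders with
  configurable debris particles (false-tip emulation) and meniscus halos
  (in-air imaging emulation).
- **`rootpouch.cleaning`** — segmentation pipeline: LAB lightness channel →
  percentile stretch → global threshold (Otsu or fixed) → connected-component
  labeling → area + center-distance filtering → mask multiplication.
- **`rootpouch.traits`** — skeleton-based traits from a cleaned mask:
  TRL, TSA, DIM, TRV, TRT, TSA1, TSA3 (morphology via medial axis + distance
  transform radii) and TRW, TCA, SOL, COPM, RDI (architecture via convex
  hull, centroid and depth profile).
- **`rootpouch.stats`** — tip-count validation R², paired t-tests,
  broad-sense heritability H² = Vg/(Vg + Ve/r) from one-way variance
  components, greedy linkage-block counting and the block-wise Bonferroni
  −log10(p) threshold.
- **`rootpouch.cli`** — batch commands binding it all together.

## CLI

```sh
# synthetic benchmark images + ground-truth manifest
rootpouch synth --n 16 --seed 7 --debris 30 --out-dir out/imgs

# clean one image / run the whole directory
rootpouch clean --in img.png --out cleaned.png --mask mask.png
rootpouch pipeline --in-dir out/imgs --out traits.csv --masks-dir out/masks

# measure a cleaned image or directory (12-trait CSV)
rootpouch measure --in cleaned.png --scale 100 --out traits.csv

# self-contained tip-count validation (generate -> clean -> count -> R^2)
rootpouch validate-tips --n 16 --seed 1 --floor 0.95 --out validation.json

# heritability per trait from replicated phenotypes
rootpouch herit --phenotypes phenotypes.csv --trait TRL

# genome-wide significance threshold (-log10 scale)
rootpouch gwas-threshold --alpha 0.05 --blocks 212612   # -> 6.6
```

Phenotype CSVs have columns `genotype, replicate, <trait...>`. Pixel scale
(`--scale`, pixels per cm) comes from imaging-session calibration and is
supplied by the user; config files are TOML (see `rootpouch.cli.RunConfig`).

## Notes

- Lengths are cm, widths/diameters mm, areas cm², volumes cm³; the mm→cm
  factor is applied once at the render/measure boundary.
- The linkage-block scan is a greedy seed-based approximation of Plink
  clumping; block counts on real data will differ from published values.
- Disconnected fragments in a cleaned mask are measured as-is; removing
  non-root objects is the cleaning stage's job.
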