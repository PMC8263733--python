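# ftirdry

FTIR analysis pipeline for dry-preservation quality control of nucleic
acids and sperm chromatin, plus a synthetic-spectrum generator that stands
in for the instrument so every stage is testable offline.

## What it does

- **`ftirdry.spectral_core`** — spectrum data model, two-column CSV and
  JCAMP-DX (AFFN subset) readers, linear resampling onto a uniform
  1 cm⁻¹ grid, region extraction. Wavenumbers are always ascending.
- **`ftirdry.synthetic`** — composite gaussian/lorentzian band spectra from
  named component presets (A/B-form dsDNA, ssDNA, RNA, dried trehalose and
  sucrose, albumin, several OH-stretch matrices). Hydration morphs the DNA
  marker bands between B-form (970/1052/1089/1225 cm⁻¹) and A-form
  (965/1050/1089/1235 cm⁻¹) endpoints; temperature moves the νOH band at
  the preset's wavenumber temperature coefficient; a degradation model
  emulates storage drift. Noise is seeded, never implicit.
- **`ftirdry.preprocess`** — vector normalization over a spectral region
  and the 21-point Savitzky–Golay second derivative (per-cm² units, edge
  half-windows invalidated).
- **`ftirdry.band_markers`** — prominence-filtered detection of
  second-derivative band minima, extraction of the four B/A marker bands
  from fixed search windows, the asymmetric/symmetric phosphate intensity
  ratio, and a majority-vote B / A-like conformational call.
- **`ftirdry.hydrogen_bonding`** — νOH band position by the 80 %-height
  rule over 3000–3700 cm⁻¹ and OLS fitting of the wavenumber temperature
  coefficient (WTC) over 25–50 °C; liquids show large WTC, glasses small.
- **`ftirdry.pca_monitor`** — covariance PCA of vector-normalized
  fingerprint-region (1500–900 cm⁻¹) spectra with a standardized
  centroid-distance drift report for storage monitoring.
- **`ftirdry.dry_assays`** — gravimetric water content, drying-endpoint
  detection, % w/v → molarity conversion, and formazan grey-value image
  quantification with matching synthetic generators.

## CLI

One entry point with subcommands; logging goes to stderr, tables to files.
Exit codes: 0 success, 1 usage/config error, 2 partial data failure.

```sh
# generate 5 noisy dried-DNA spectra plus a manifest
ftirdry simulate --components dsDNA_B:1,albumin:0.5 --hydration 0 \
    --noise-sd 0.01 --seed 7 --n 5 --out-dir out/sim

# marker bands, phosphate ratio and conformational call per spectrum
ftirdry markers --manifest out/sim/manifest.csv --state dried --out markers.csv

# WTC per sample label from a temperature-series manifest
ftirdry wtc --manifest series.csv --out wtc.csv

# fingerprint-region PCA with a drift report between two groups
ftirdry pca --manifest manifest.csv --group-a baseline --group-b stored \
    --out-dir out/pca

# small assays
ftirdry assay molarity --percent 1.71 --molar-mass 342.30
ftirdry assay water --after-drying 1.05 --after-bake 1.0 --slide 0
```

A YAML config file (see `ftirdry.config.PipelineConfig` for keys and
defaults) can be passed to any pipeline subcommand with `--config`.

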