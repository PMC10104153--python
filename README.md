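# incisure

Stoichiometric modelling and image morphometry of rod photoreceptor disc
incisures.

## The problem

Rod outer segment discs are flattened membrane sacs whose lamellae are
packed with rhodopsin and whose high-curvature rim is built from the
tetraspanins peripherin-2 (PRPH2) and ROM1. Most discs also carry an
*incisure* — a deep, longitudinally aligned indentation of the rim (one per
disc in mouse, up to ~20 in frog). This package implements a quantitative
account of what sets incisure size: the disc's relative contents of
rhodopsin and tetraspanin.

The model treats the disc as two molecular budgets:

- rhodopsin count fixes disc surface area `A = 2·π·(d/2)²` (both lamellae)
  at constant areal packing density;
- tetraspanin count fixes total rim length, at a rim linear density
  `λ` (molecules/µm) calibrated on the wild type.

Because an incisure is lined by **two** apposed rim edges,

```
L_rim = π·d + 2·L_inc
```

Calibrating `λ` on the wild-type mouse (75,000 rhodopsins/disc,
rhodopsin:tetraspanin = 12.7, total rim 6.21 µm → λ ≈ 950 µm⁻¹) and
applying it to the rhodopsin hemizygote (smaller disc, ratio 6.0) predicts
a ~1.66 µm incisure — ~155% of the disc diameter, explaining the long,
bifurcated and twisted incisures seen in that genotype. A tetraspanin
budget *below* `λ·π·d` predicts failed disc enclosure and absent incisures
(the PRPH2-deficient phenotype). Uncertainty in the measured molar ratios
(mean ± s.d., n = 3 preparations) is propagated by Monte Carlo.

Alongside the model, the package ships a synthetic tangential-section image
generator with exact ground truth (straight, bifurcated, twisted and
multi-incisure disc morphologies), a morphometry stage (segmentation,
rim-concavity detection, skeleton-geodesic incisure lengths, area-equivalent
diameters) and cohort statistics (per-animal means, unpaired t-test, exact
binomial presence CIs), so every stage is testable without any micrograph
downloads.

It is aimed at photoreceptor cell biologists and image-analysis developers
who want a reproducible baseline linking disc protein stoichiometry to disc
morphology.

## Worked example

```sh
incisure predict --seed 1
```

prints (abridged):

```
genotype  surface_area_um2  rhodopsin_per_disc  tetraspanin_per_disc  rim_density_per_um  total_rim_length_um  incisure_length_um  incisure_fraction
      WT          3.534292             75000.0           5905.511811           950.60239             6.212389            0.750000           0.500000
  Rho+/-          1.796796             38129.2           6354.864638           950.60239             6.685092            1.662546           1.554477
```

Reading the `Rho+/-` row: a hemizygote disc (circumference 3.36 µm) holds
~38,100 rhodopsins, hence ~6,350 tetraspanins at ratio 6.0; at the
wild-type rim density of ~950 molecules/µm that material builds 6.69 µm of
rim, leaving `(6.69 − 3.36)/2 ≈ 1.66 µm` for the incisure — 155% of the
disc diameter.

The full pipeline (predictions + synthetic cohort + measurement + group
statistics) runs from a config:

```sh
incisure run --seed 1 --outdir out/        # uses the built-in default config
incisure generate --seed 1 --outdir imgs/  # synthetic TIFFs + ground truth
incisure measure imgs/WT --pixel-size 3 --out measured.csv
incisure stats --cohort out/cohort.csv --out stats.json
```

Library use mirrors the CLI: see `incisure.stoichiometry` (model),
`incisure.synthetic` (generator), `incisure.morphometry` (measurement),
`incisure.cohort` / `incisure.pipeline` (aggregation and orchestration).

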