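# Methods

## The rim-allocation model

A disc is modelled as a circle of diameter `d` (µm) carrying zero or more
incisures. Its two molecular budgets are linked to geometry by three
assumptions:

1. **Rhodopsin sets area.** Rhodopsin packs the lamellae at a constant
   areal density, independent of expression level; a disc's rhodopsin count
   is therefore proportional to `A = 2·π·(d/2)²` (both lamellar faces).
   The reference count comes from a whole-rod census: rhodopsins per rod ÷
   discs per rod (defaults 6×10⁷ and 800 → 75,000 per disc).
2. **Tetraspanin sets rim.** All peripherin-2 + ROM1 of a fully enclosed
   disc sits in the rim, at a linear density `λ` (molecules/µm) that does
   not differ between genotypes. `λ` is calibrated on the wild type from
   its tetraspanin budget and measured total rim length.
3. **An incisure is two rim edges.** The rim comprises the circumference
   plus both apposed edges of each incisure: `L_rim = π·d + 2·L_inc`. This
   factor of two is forced by the numbers the model must join up
   (6.21 = π·1.5 + 2·0.75; 1.66 = (6.69 − 3.36)/2) even though it is easy
   to miss when reading lengths off an image.

Tetraspanin budgets derive from molar ratios: with `R` rhodopsins and
ratios `a = R:PRPH2` and `b = R:ROM1`, the combined ratio is harmonic,
`R:(P+R₁) = 1/(1/a + 1/b)`, and the tetraspanin count is `R` divided by it.

Prediction for a genotype with circumference `C`: `L_rim = T/λ`; if
`L_rim ≥ C` the surplus is allocated to the incisure at half its length
(`L_inc = (L_rim − C)/2`); otherwise the disc cannot complete its rim —
the prediction reports a zero incisure, an **enclosure deficit** flag and
the missing length `C − L_rim`, rather than a negative incisure. This
mirrors the peripherin-2-deficient phenotypes, where incisures are almost
entirely absent and enclosure sometimes fails.

Geometry convention: when a genotype is specified by measured circumference
(the hemizygote's 3.36 µm), circumference is primary and `d = C/π`
(≈ 1.07 µm). Using the rounded printed diameter (~1.1 µm) instead would
shift the predicted incisure fraction from ~155% to ~151%; the
circumference-primary convention is the one under which the whole chain is
internally consistent, so the package adopts it. Molecule counts are
carried as reals and rounded (nearest 10) only for display.

## Uncertainty propagation

The tabulated ratios are means ± s.d. over n = 3 preparations with unknown
covariances. Each genotype's rhodopsin:tetraspanin ratio is drawn
independently from a normal truncated at zero (ratios are positive); the
full calibration + prediction chain is re-run per draw, vectorized over
draws. The point estimate is the chain at the means; intervals are
percentile CIs (default 95%, 10,000 draws, seed mandatory). With all s.d.
zero the interval collapses to the point estimate, and two seeds agree to
within Monte-Carlo error — both are tested.

## Synthetic sections

The generator emulates tangentially sectioned discs as seen by EM: a
bright disc on dark background, incisures carved as dark slits from the rim
toward the center, then Gaussian blur and additive Gaussian noise, 8-bit
output. Defaults: 3 nm/pixel (matching tomographic sampling of this
preparation), canvas with a 10% margin, foreground 200 / background 40,
blur σ 6 nm, noise σ 8 (5% of the 160-unit dynamic range). The slit width
default (30 nm) is a free parameter — no measured incisure width is
available for mouse — and is therefore exposed in every spec.

Shapes: **straight** (radial chord; the mouse WT archetype, fraction 0.5),
**twisted** (sinusoidal perturbation of the chord, solved so the rendered
arc length matches the requested fraction, allowing fractions > 1 as in
the rhodopsin hemizygote), **bifurcated** (a stem forking once, by default
at its midpoint). Multi-incisure amphibian discs place straight incisures
at distinct angles on a larger (6 µm) disc. Two carving constraints keep
the 2-D section usable: a straight slit near fraction 1 stops just short
of the opposite rim (a section of a full-diameter incisure would otherwise
fall into two pieces), and twisted paths are bounded away from the rim by
an envelope so the carved channel never breaches it. The recorded ground
truth is always the *rendered* path length, which the generator guarantees
to track the requested `f·d` within 2 pixels whenever the shape can
geometrically achieve it.

What the generator does **not** emulate: tomographic projection, section
compression, staining texture and gradients, membrane substructure,
neighbouring cell material. Recovery results on synthetic data therefore
validate the measurement geometry (segmentation, concavity detection,
length and diameter estimation) — not robustness to real EM contrast.

## Morphometry

- **Segmentation**: Otsu (or fixed) threshold, largest connected component
  (ties broken by centroid position), interior holes filled while slits
  that open at the rim are preserved.
- **Diameter**: area-equivalent diameter `2·√(A/π)` of the incisure-closed
  mask (morphological closing + hole filling), i.e. the diameter of the
  disc, not of disc-minus-slit. Rotation-invariant and exact for circles.
- **Incisure detection**: closing difference (closed minus original mask)
  split into connected components; components must touch the rim and pass
  a minimum area (default 20 px). The closing radius (default 15 px)
  bounds the detectable slit width at twice the radius; a radius smaller
  than half the slit width yields no detections, by design not an error.
  A practical setting is ~1.5× the expected slit width in pixels.
- **Length**: skeletonize the component; length is the geodesic from the
  rim entry (skeleton pixel nearest the closed-disc exterior) to the
  farthest skeleton point. The digital path is subsampled every 4 px
  before summing segment lengths — raw 8-connected step sums overestimate
  oblique curves by up to ~8%. The straight-line chord is reported
  alongside. For branched skeletons, each extra endpoint contributes a
  side branch measured from where its geodesic leaves the main path;
  sub-branches shorter than 5% of the main path are discarded as
  skeletonization spurs. Degenerate one-pixel components measure one
  pixel.
- **Presence**: a disc "has an incisure" when any measured fraction
  reaches `min_incisure_length_fraction` (default 0.03; "discernible" has
  no published operational definition, so the threshold is explicit and
  configurable).

Validated by parameter recovery: over fractions 0.2–1.0, diameters
1.07/1.5 µm, widths 21–45 nm and noise to 10% of dynamic range, mean
absolute error is < 0.05 on the fraction and < 0.02 µm on the diameter;
counts of 0–20 well-separated incisures are recovered exactly in ≥ 95% of
seeded replicates (k ≥ 5 at the amphibian scale, where that many incisures
are geometrically separable).

## Cohort statistics

The animal, not the disc, is the statistical unit: per-disc measurements
are averaged per (genotype, animal) before comparison. The group test is a
two-sided unpaired t-test on per-animal means — pooled-variance Student by
default, which is the conventional reading of "unpaired t-test" at n = 3
per group; Welch is available via flag. Degenerate inputs are defined
explicitly: identical groups give t = 0, p = 1; distinct means with zero
variance give the smallest representable p. Incisure presence per genotype
is a Clopper–Pearson exact binomial CI (95%). A single comparison is
performed, so no multiple-testing correction is applied; the report states
this. The published p-value for the diameter comparison (p = 0.0075) is
not a reproducible target because the underlying per-animal means are not
published; the pipeline instead verifies its test against a closed-form
oracle and demonstrates significance on synthetic cohorts with the same
design (3 animals per genotype).

## Pipeline scale and determinism

The default pipeline cohort is 3 animals × 8 discs per genotype, a size
chosen so a full run completes in well under a minute while the per-animal
design (3 per genotype) matches the study layout; the cohort size is a
config knob (`discs_per_animal: 25` reproduces the published imaging
design). All randomness flows from the single config seed through
`numpy.random.SeedSequence` spawns, making every output a pure function of
config + seed; determinism is tested end-to-end.

## Known limitations

- The model is planimetric: it ignores rim thickness, incisure width and
  any rim material in structures other than circumference and incisure
  (e.g. the tubular profiles seen alongside overgrown incisures), and it
  does not exclude rim-occupied membrane from the rhodopsin-bearing area —
  consistent with the calculation chain it implements.
- Incisure *number* is not modelled (one incisure per mouse disc is
  assumed by the geometry; what sets the count in amphibians is open).
- Ratio draws are independent; replicate-level covariances between ratios
  are unknown and ignored.
- The morphometry is validated on synthetic renders only; applying it to
  real micrographs requires at minimum a contrast-appropriate threshold
  strategy and a pixel size from the microscope metadata.
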