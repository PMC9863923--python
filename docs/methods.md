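# Methods

`specdx` implements a leaf-clip hyperspectral analysis pipeline for
discriminating macronutrient deficiencies (−N, −P, −K, −Mg, −S vs a
full-nutrition control) in flue-cured tobacco, together with a synthetic
reflectance generator that supplies data with the statistical structure
the analysis assumes. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic results do and do
not show about real data.

## Data model

A `SpectraSet` is a samples × bands matrix of percent reflectance (0–100)
on a strictly increasing wavelength grid — nominally integers
350–2500 nm, 2151 bands at 1-nm spacing — with one metadata record per
spectrum: treatment, maturity stage, a 4-level symptom-severity rating
(1 none … 4 high), leaf index, replicate, and trial. Maturity is a step
function of expanded-leaf count: ≤6 young, 7–12 intermediate, >12
mature. Reflectance outside [0, 100], non-finite values, or
metadata/spectra misalignment are construction-time errors naming the
offending cell; missing bands are never imputed, because silent
imputation would corrupt the derivative filters. The canonical on-disk
form is a wide CSV (metadata columns, then one column per wavelength);
a long triple layout with a metadata sidecar round-trips to the same
object.

## Preprocessing

The SWIR water-absorption windows 1355–1450 nm and 1800–1950 nm
(endpoints inclusive — "1355 to 1450" reads naturally as a closed
range, and the choice is encoded in exactly one place) are excluded
before analysis: on the full 1-nm grid this removes 96 + 151 = 247
bands, leaving 1904. Masking splits the grid into contiguous uniform
blocks; the derivative filters operate within blocks and mark the
positions they cannot reach as invalid. Row subsetting (by maturity,
treatment set, or minimum severity) and column masking commute, and
masking is idempotent.

## Band selection

Two families of per-band scores:

- **Information scores.** Shannon entropy of a band's values
  discretised into `n_bins` equal-width bins over the band's own
  [min, max] (class-free), or information gain
  IG = H(labels) − Σ_b p(b) H(labels | b) (class-aware). The
  discretisation default is 10 bins; both scorers are exposed because
  "information entropy" is used in both senses in the hyperspectral
  band-selection literature. The pipeline default is information gain:
  on data in which broad spectral regions carry only noise, class-free
  entropy with per-band min–max binning scores a pure-noise band nearly
  as high as a signal band (noise spread over a band's own range is
  close to uniform across bins), so its rankings are not
  class-informative. This is a property of the score, reproduced and
  documented by the tests, not a defect of the implementation.
- **Derivative scores.** Gap-segment (Norris) derivatives of the
  class-mean spectra: means over segments of `segment` bands separated
  by `gap` bands from the evaluation point, then finite differences —
  first order (right − left)/(centre distance), second order
  (left + right − 2·centre)/(distance²) — with defaults segment 3,
  gap 2 (filter length 2·3 + 2·2 + 1 = 11 for both orders). The filter
  is exact on linear (order 1) and quadratic (order 2) input, and
  positions within half the filter length of a block edge are NaN.
  The default band score is the absolute derivative of the balanced
  pooled class-mean spectrum, whose peaks sit where reflectance changes
  fastest — the red-edge maximum and the green-peak flanks, the
  locations one reads off plotted derivative curves. A cross-class
  standard-deviation contrast is available as an option
  (`contrast="std"`); it emphasises the *flanks* of the red-edge window
  instead, because every class's derivative is simultaneously large
  mid-edge, and was therefore not made the default.

Entropy/IG profiles are smoothed with a Savitzky–Golay filter before
peak search: local least-squares polynomial of order 3 evaluated at the
window centre, window 11. An even window cannot be symmetric, so a
requested window of 10 is promoted to 11 with a logged notice. Edges
are handled by fitting the same polynomial on the truncated one-sided
window, so output length equals input length and polynomials up to the
fit order are reproduced exactly (machine precision at interior points).

Peak extraction: a band is a peak when its score (absolute score for
derivative profiles) is the maximum within ±`span` bands (default 10)
and a strictly smaller score exists on each side within the span — a
monotone profile therefore has no peaks. Runs of consecutive equal-score
candidates (plateaus) are aggregated and reported at their central
wavelength, taking the lower median for even-length runs. The top k
(default 5) peaks are re-ranked by score, ties broken toward the lower
wavelength. The whole selection is deterministic.

## Classification

PCA is an SVD of the mean-centred data matrix; bands share units
(percent reflectance), so there is no per-band standardisation (a
switch exists). Components are ordered by explained variance (sample
covariance, divisor n−1) with the sign convention that each component's
largest-magnitude loading is positive. Ten components are retained by
default; reducing 2250 bands to 10 components is a
100·(1 − 10/2250) = 99.56% dimensionality reduction.

LDA fits class means, empirical priors, and a pooled within-class
covariance (divisor n − K, optional ridge regularization·I; a
rank-deficient covariance with zero regularization is an error that
says so). Discriminant scores are
δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k; posteriors are the softmax
of δ (the shared quadratic term cancels), and argmax ties break by
class declaration order (alphabetical by label).

Cross-validation is stratified five-fold: within each class, samples
are shuffled by the seeded generator and dealt round-robin, so per-class
fold sizes differ by at most one and no fold can lose a class.
Stratification is a deliberate strengthening of a plain random 80/20
split, which can otherwise drop a rare class from training. Two scopes:
`fold_safe` (default) refits PCA inside every training fold;
`paper_mimic` fits PCA once on all data before splitting, reproducing
the common fit-then-validate sequence at the cost of mild information
leakage (the leakage direction is asserted in the tests: fold-safe must
not systematically beat paper-mimic). Models are never tuned on test
folds. Per-class accuracy is recall (row-normalised confusion-matrix
diagonal); overall accuracy is 100·trace/total.

## Synthetic data generator

The generator is first-class, tested code. Each leaf has a latent
chlorosis level c ∈ [0, 1] that drives a closed-form reflectance curve:

- visible floor (6%) plus a green Gaussian at 550 nm (width 45 nm)
  whose amplitude interpolates linearly in c between values **solved
  exactly** so that R(550) = 12.6% at c = 0 and 41.1% at c = 1;
- a red-reflectance lift (Gaussian at 645 nm) and a small broad visible
  lift growing with c, so chlorotic leaves reflect proportionally more
  red;
- a logistic red edge (width 14 nm) rising to the NIR plateau (47%,
  plus a small NIR lift with c), centred at 712 − 18c nm — severe
  chlorosis shifts the edge 18 nm toward shorter wavelengths;
- a SWIR decline to 22% with Gaussian water-absorption dips at 1450 and
  1940 nm.

With these defaults a severely chlorotic leaf reflects strictly more
than a healthy one at every integer wavelength in 350–1000 nm (verified
exhaustively). A transparent closed form was chosen over a physical
radiative-transfer model (e.g. PROSPECT) because the available anchors
are reflectance values, not pigment concentrations; every anchor is
directly testable. `red_edge_position` returns the wavelength of the
maximum gap-segment first derivative in 660–760 nm and flags a flat
derivative (no edge) as undefined.

Treatments map onto the model through per-class effects — a chlorosis
distribution, a red-edge-shift scale, a maturity-dependent asymptomatic
fraction (leaves that look control-like despite the treatment), and a
within-leaf noise multiplier for nonuniform symptoms:

| class | c mean ± sd | edge scale | asympt. (y/i/m) | noise × |
|---|---|---|---|---|
| control | 0.02 ± 0.02 | 1.0 | 0/0/0 | 1.0 |
| −N | 0.80 ± 0.06 | 1.0 | 0/0.05/0.05 | 1.0 |
| −S | 0.60 ± 0.05 | 0.35 | 0/0.05/0.10 | 1.0 |
| −Mg | 0.50 ± 0.12 | 0.9 | 0.05/0.10/0.15 | 2.0 |
| −P | 0.40 ± 0.05 | 1.0 | 0.05/0.25/0.35 | 1.4 |
| −K | 0.25 ± 0.10 | 0.8 | 0.10/0.25/0.50 | 1.0 |

The encoding follows the qualitative symptom structure: N strong
*uniform* chlorosis (hence the tight spread); S similar chlorosis but a
much smaller red-edge response, so N/S separation rests on the edge
region; Mg moderate with high within-leaf variability; P bimodal —
either asymptomatic or in a distinct spotted mode — with extra smooth
variance; K mild, with half of mature leaves asymptomatic. Severity
ratings derive from c by fixed thresholds 0.1/0.4/0.7. Noise is
additive white Gaussian (sd 0.5 percentage points) plus a smooth
correlated component (sd 1.0, Gaussian correlation length 50 nm,
rescaled analytically by the filter-kernel norm), keeping within-class
spread well below the 28.5-point anchor separation. Everything is
reproducible from the scenario seed; no within-class variance is
reported by any real measurement, so these are stated assumptions,
exposed in the configuration.

Young-stage scenarios cover control/−N/−P/−S (the four classes measured
at that stage); intermediate and mature scenarios cover all six.

## What the synthetic results show — and what they don't

On the default young-stage scenario (4 × 40 samples) the full pipeline
(mask → PCA(10) → LDA → stratified 5-fold CV) reaches ≥ 90% overall
accuracy with N-deficient recall ≥ 95% across seeds, a shuffled-label
control collapses to chance (≈ 25% for four classes), information-gain
selection recovers the green-peak (540–560 nm) and red-edge
(690–710 nm) windows, and raising the P asymptomatic fraction from 0 to
0.4 sharply lowers P recall — the misclassification mechanism whereby
asymptomatic deficient leaves are read as controls. These are
demonstrations that the pipeline recovers structure the generator put
in, at desk-scale sample sizes (160 spectra per scenario, chosen to
keep the full test suite fast); they are not evidence about greenhouse
data, where within-class variance, instrument artefacts, and
between-class overlap are unknown. Six-class intermediate/mature
scenarios are harder (more classes, higher asymptomatic fractions) and
show the same qualitative ordering — N best classified, P and K
poorest — without matching any particular accuracy value.

## Numerical choices and degenerate inputs

- Entropy of an all-equal sequence is 0 (single occupied bin);
  information gain with a single class present is 0.
- Histogram binning follows the half-open-bins-except-last convention;
  values at the band maximum fall in the last bin.
- The SG edge fit needs at least poly_order + 1 points; `window ≥
  poly_order + 2` (odd) guarantees it.
- Gap-segment derivatives require uniform spacing and reject shorter
  inputs than the filter; the second order requires an odd segment so
  the centre segment is symmetric about the evaluation point.
- An empty subset result is legal; every downstream operation guards
  (PCA needs ≥ 2 samples, LDA ≥ 2 classes with ≥ 2 samples each, CV ≥ k
  samples per class, with errors naming the offending class).
- Pipeline runs are byte-identical given the same config and seed;
  report tables are written with fixed float formatting.

## Known limitations

- The reflectance curve is phenomenological: no pigment chemistry, no
  necrosis modelling (necrotic tissue was deliberately excluded from
  the measurement protocol it emulates), no canopy or UAV geometry.
- Class identity lives mostly on two latent axes (chlorosis level and
  red-edge response); real deficiencies differ in richer ways, so
  synthetic class separability should be read as a calibrated
  illustration, not a claim about field performance.
- The class-free entropy scorer is faithful to its definition but is
  not a good band selector when noise-only regions exist; use the
  information-gain default for class-aware selection.
- No scatter correction (SNV/MSC) or grid resampling is provided; the
  pipeline assumes spectra already share a grid.
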