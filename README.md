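# specdx

Hyperspectral discrimination of macronutrient deficiencies in leaf
reflectance spectra.

Nutrient disorders — nitrogen, phosphorus, potassium, magnesium, and
sulfur deficiencies — change how a leaf reflects light: chlorophyll loss
raises visible reflectance (especially the green peak near 550 nm) and
shifts the red edge, the steep rise between red absorption (~680 nm) and
the NIR plateau (~750 nm), toward shorter wavelengths. `specdx`
implements the full leaf-clip analysis pipeline for separating these
symptoms from point spectra (percent reflectance on a 1-nm grid,
nominally 350–2500 nm), for crop scientists and spectroscopists who want
a tested, reproducible reference implementation:

- **Band selection.** Each wavelength is scored by Shannon entropy of its
  discretised reflectance, H = −Σ p_b log₂ p_b, or by class-aware
  information gain, IG = H(y) − Σ_b p(b)·H(y | b); score curves are
  smoothed with a Savitzky–Golay filter (3rd-order polynomial, window 11)
  and spectral derivatives are computed with the gap-segment filter
  (segment 3, gap 2, filter length 11). Peaks — strict local maxima
  within a ±10-band span, plateaus aggregated to their central
  wavelength — are ranked and the top five reported.
- **Classification.** Spectra (water-absorption bands 1355–1450 and
  1800–1950 nm excluded) are reduced to 10 principal components and
  classified with linear discriminant analysis,
  δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + log π_k, under stratified five-fold
  cross-validation, reporting confusion matrices, per-class recall, and
  overall accuracy.
- **Synthetic data.** A calibrated generator produces leaf spectra with
  the structure the analysis assumes — a latent chlorosis level drives a
  closed-form curve anchored at 12.6% (healthy) and 41.1% (severely
  chlorotic) green-peak reflectance with a red edge that shifts from
  712 nm to shorter wavelengths — so the entire pipeline is exercisable
  with no external data.

## Worked example

```python
import specdx as sd

scenario = sd.default_scenario("young", n_per_class=40, seed=7)
spectra  = sd.apply_band_mask(sd.simulate_dataset(scenario))  # drop water bands
bands    = sd.select_bands(spectra, method="infogain")
cv       = sd.crossvalidate(spectra, k=5, n_components=10, seed=7)
print(bands[["rank", "wavelength_nm"]].head(4).to_string(index=False))
print(f"overall accuracy: {cv.overall_accuracy:.1f} %")
```

Output:

```
 rank  wavelength_nm
    1          547.0
    2          572.0
    3          534.0
    4          705.0
overall accuracy: 94.4 %
```

The top-ranked wavelengths sit on the green peak (534–572 nm) and the
red edge (705 nm) — the regions where chlorosis separates the treatment
classes — and the cross-validated PCA→LDA model recovers the four
young-stage classes (control, −N, −P, −S) at 94% overall, with
N-deficient leaves nearly perfectly identified and the residual errors
concentrated in P/S confusions and asymptomatic P leaves read as
controls. Longer narrative versions of this and the other capabilities
(red-edge localisation, dataset simulation and CSV round-trips) are in
`examples/`; a thin CLI mirrors the pipeline:

```bash
specdx simulate --scenario young --n-per-class 40 --seed 7 --out spectra.csv
specdx select-bands --in spectra.csv --method infogain --out bands.csv
specdx classify --in spectra.csv --pcs 10 --folds 5 --seed 7 --out cm.csv
specdx run --seed 7 --out-dir report/
```

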