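"""Cross-validated PCA-LDA classification of deficiency symptoms.

Simulates the young-stage scenario, masks the SWIR water-absorption
bands, reduces the ~1900 remaining bands to 10 principal components
inside each training fold, and classifies treatments with a linear
discriminant model under stratified five-fold cross-validation.  Prints
the aggregate confusion matrix (rows = true class) and per-class recall;
the control class is essentially never confused, while P-deficient
leaves are occasionally read as controls — the asymptomatic-leaf effect.
"""

import specdx as sd

scenario = sd.default_scenario("young", n_per_class=40, seed=7)
spectra = sd.apply_band_mask(sd.simulate_dataset(scenario))

cv = sd.crossvalidate(spectra, k=5, n_components=10, scope="fold_safe", seed=7)

print("confusion matrix (rows = true class):")
print(cv.confusion.to_frame())
print("\nper-class accuracy (recall):")
for cls, acc in cv.per_class_accuracy.items():
    print(f"  {cls.value:>8s}: {acc:5.1f} %")
print(f"\noverall accuracy: {cv.overall_accuracy:.1f} %")
print(
    "dimensionality reduction:"
    f" {sd.dimensionality_reduction_percent(spectra.n_bands, 10):.2f} %"
    f" ({spectra.n_bands} bands -> 10 components)"
)
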