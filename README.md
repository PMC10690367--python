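# dscradiomics

Tracer-kinetic quantification of dynamic susceptibility contrast (DSC) MRI
and radiomics-based prediction of IDH mutation status in gliomas.

DSC-MRI records the T2\*-weighted signal drop during the first pass of a
gadolinium bolus. This package turns those 4D series into physiological
parametric maps, extracts radiomic features from a tumor ROI on each map,
and trains a cross-validated SVM to separate IDH-mutant from IDH-wildtype
tumors, with Shapley-value explanations of the fitted models. It is aimed
at neuroimaging researchers who want a self-contained, testable
implementation of the whole chain — no external perfusion software, no
black-box feature extractor — driven end to end by a synthetic phantom
cohort with known kinetic ground truth.

## Models

**Signal to concentration.** For each voxel,
`C_t(t) = -(1/TE) ln(S(t)/S(0))`, with `S(0)` the pre-bolus baseline mean.

**Gamma transport-function model.** The tissue curve is
`C_t(t) = F_t (AIF ⊛ R)(t)` with residue function `R(t) = 1 − ∫₀ᵗ h`,
where the transit-time density is a shifted gamma variate
`h(t) ∝ (t−t₁)^{a₁} e^{−(t−t₁)/σ₁}`. Voxelwise least squares yields
`rCBF = F_t`, `rMTT = t₁ + σ₁(1+a₁)` and, by the central volume
principle, `rCBV = rCBF·rMTT`. The curve itself gives `TMAX` (time of the
concentration maximum) and `MSI` (mean slope of increase between the end
of baseline and TMAX).

**Leakage-corrected blood volume.** With a disrupted blood–brain barrier,
the voxel curve is modelled through the whole-brain average concentration
`ref(t)` of non-enhancing tissue: unidirectional exchange
`C_t = K₁·ref − K₂·∫ref`, bidirectional exchange
`C_t = K₁·ref − K₂·(ref ⊛ e^{−K_ep t})`. The leakage term is added back to
give the corrected curve, and `nrCBV` is the trapezoidal integral between
bolus arrival and replenish time points.

**Radiomics and classification.** First-order, GLCM, GLRLM, GLSZM, GLDM
and shape features — plus wavelet, Laplacian-of-Gaussian, gradient,
logarithmic/exponential and LBP-2D filtered variants — are computed per
map inside the tumor ROI. Selection is variance threshold → univariate
ANOVA → L1-penalized logistic regression (C = 0.3); SMOTE balances the
training folds (41 minority vs 119 majority at full scale); an RBF-kernel
SVM is evaluated in stratified 5-fold cross-validation with sensitivity,
specificity, F1, accuracy and AUROC, and exact or permutation-sampled
Shapley values rank the selected features.

## Worked example

```python
import numpy as np
from dscradiomics import synth, kinetics, leakage

t = np.arange(60) * 1.87                       # 60 frames at 1.87 s
aif = synth.make_aif(synth.GammaBolusParams(), t)

curve = kinetics.simulate_tissue_curve(aif, t, ft=0.8, t1=3.0, sigma1=1.5, a1=2.5)
fit = kinetics.fit_gamma_model(curve, aif, t)
print(f"rCBF = {fit.ft:.4f}, rMTT = {fit.rmtt:.4f} s, rCBV = {fit.rcbv:.4f}")

ref = kinetics.simulate_tissue_curve(aif, t, 0.05, 2.0, 1.5, 3.0)
leaky = leakage.contaminate_with_leakage(ref, k1=1.2, k2=0.05, kep=0.1, dt=1.87)
p = leakage.fit_bidirectional(leaky, ref, 1.87)
print(f"K1 = {p.k1:.4f}, K2 = {p.k2:.4f} 1/s, Kep = {p.kep:.4f} 1/s")
```

prints

```
rCBF = 0.8000, rMTT = 8.2500 s, rCBV = 6.6000
K1 = 1.2000, K2 = 0.0500 1/s, Kep = 0.1000 1/s
```

The gamma fit recovers the simulated flow and transit-time parameters of
the forward curve exactly (rMTT = 3 + 1.5·(1+2.5) = 8.25 s), and the
bidirectional fit recovers the leakage parameters used to contaminate the
curve; correcting and integrating the contaminated curve then restores
the leak-free blood volume (35.72 vs 20.73 uncorrected in this example).

A command-line interface chains the stages on files:

```sh
dscradiomics simulate --out sim/ --n-class0 2 --n-class1 4
dscradiomics fit-leakage --series sim/phantom000_series.nii.gz \
    --brain-mask sim/phantom000_mask_brain.nii.gz \
    --tumor-mask sim/phantom000_mask_tumor.nii.gz \
    --aif sim/phantom000_aif.csv --out maps/
dscradiomics features --maps-dir maps/ \
    --mask sim/phantom000_mask_tumor.nii.gz --out features.csv
dscradiomics run-all --out run/      # simulate + full pipeline to a CV report
```

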