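# Methods

## Perfusion model

The tissue concentration curve follows the indicator-dilution model
`C_t(t) = F_t (AIF ⊛ R)(t)`. The transport function (transit-time
density) is a shifted gamma variate with arrival delay `t₁`, scale `σ₁`
and shape `a₁`, normalized by `A₁ = σ₁^{1+a₁} Γ(1+a₁)` so it integrates
to one; its first moment, `rMTT = t₁ + σ₁(1+a₁)`, is the mean transit
time, and the residue function is evaluated through the regularized lower
incomplete gamma function rather than by quadrature. Discrete
convolutions carry the `dt` factor so the central volume principle
(`rCBV = rCBF·rMTT`) holds numerically; on coarse clinical grids
(dt ≈ 1.9 s) the rectangle-rule integral of `R` overshoots its continuous
value by O(dt), so integral-ratio identities are only expected to hold on
well-resolved grids, which is how the tests check them.

Fitting: the flow amplitude enters the model linearly, so the solver
profiles `F_t` out (nonnegative linear projection) and runs bounded
least squares on `(t₁, σ₁, a₁)` only. Defaults: init `t₁` at the AIF
arrival plus one frame, `σ₁ = 1.5 s`, `a₁ = 3`; bounds `t₁ ∈ [0, 30] s`,
`σ₁ ∈ [0.05, 20] s`, `a₁ ∈ [0, 20]`. A small multistart grid over
`(t₁, a₁)` guards against local minima and is skipped as soon as the
first solution's residual is negligible; voxelwise map computation
disables multistart for speed, which is safe because phantom curves are
well inside the basin of the default init. Non-converged voxels carry
NaN parameters and propagate as invalid.

Signal conversion uses `C = −ln(S/S₀)/TE` with `S₀` the mean over the
configured pre-bolus frames; nonpositive samples are clamped to
`10⁻³·S₀` with a counted warning rather than discarding the voxel.
TMAX and MSI are computed on the measured (not fitted) concentration
curve; `t₀` is the last baseline frame, and the MSI divisor is the number
of increments between `t₀` and TMAX, so the explicit sum telescopes to
`(C(TMAX) − C(t₀))/N` — both evaluations are compared in the tests.

## Leakage models

The unidirectional model is linear in `(K₁, K₂)` and solved by ordinary
least squares (verified against the closed-form normal equations). The
bidirectional model adds the return-flow kernel `e^{−K_ep t}`; it is
fitted by unconstrained Levenberg–Marquardt from the near-unidirectional
init `(K₁, K₂, K_ep) = (1, 0, 0.01 s⁻¹)`, with a profiled fallback
(linear inner solve, bounded 1-D search on `K_ep`) if LM fails. No sign
constraints are imposed: with unconstrained `K₂` both T1- and
T2\*-dominant leakage regimes are representable. When `K₂ ≈ 0` the
leakage term vanishes and `K_ep` is flagged unidentifiable.

All cumulative integrals use the trapezoid rule at the native `dt`, and
the exponential-kernel convolution uses trapezoid weights via an exact
recurrence, so its `K_ep → 0` limit equals the running trapezoid
integral to machine precision — this makes the bidirectional model nest
the unidirectional one exactly, which the tests exploit.

The reference curve is the mean concentration over brain voxels outside
the tumor mask dilated by 2 voxels (partial-volume rim exclusion). The
nrCBV integration window runs from the reference bolus arrival (first
sample above 5% of peak) to its replenish point (first local minimum
after the peak, falling back to the last frame on monotone tails);
neither bound is standardized in the literature, so both are exposed in
the API.

## Synthetic phantoms

A phantom is a concentric-block geometry: a brain box inside a 1-voxel
border, containing a central tumor box split into enhancement / oedema /
necrosis slabs (the whole-tumor ROI is their union). Default acquisition
matches a common clinical protocol: 60 frames at `dt = 1.87 s`,
`TE = 40 ms`, 128-like in-plane geometry scaled down to a 16×16×7 grid so
a 160-phantom cohort runs in minutes. The AIF is a peak-normalized gamma
bolus (peak ΔR2\* 10 s⁻¹, arrival 10 s). Normal tissue uses
`F_t = 0.05`, `t₁ = 2 s`, `σ₁ = 1.5 s`, `a₁ = 3` (rMTT = 8 s). Tumor
voxel curves are scaled copies of the normal response minus the
bidirectional leakage term, which makes the exchange-model `K₁` exactly
the tumor-to-normal flow ratio and keeps the forward data inside the
model class the fitters assume. Gaussian noise (default sd 2 on a
baseline of 100) is added to the *signal*, where scanner thermal noise
enters; a Rician option is deliberately out of scope.

The default cohort reproduces a 160-patient imbalance: 41 IDH-mutant vs
119 IDH-wildtype phantoms. Class effects are phantom-level draws of
tumor `(F_t, K₂, K_ep)`: mutant `F_t ~ N(0.06, 0.012)`,
`K₂ ~ N(0.008, 0.003) s⁻¹`; wildtype `F_t ~ N(0.11, 0.022)`,
`K₂ ~ N(0.020, 0.006) s⁻¹`; `K_ep ~ N(0.06–0.08, ~0.013) s⁻¹`. These
were chosen once as a clearly separable but overlapping benchmark
(standardized mean differences near 2, mirroring the strong perfusion
contrast reported between the phenotypes); the null configuration samples
both classes from the mutant distribution. What the phantoms do **not**
emulate: realistic anatomy, partial-volume mixing, motion, susceptibility
artifacts, multi-center protocol variation, or within-tumor continuous
heterogeneity — so a passing end-to-end benchmark demonstrates that the
pipeline recovers a planted class difference through every stage, not
that it attains any particular accuracy on clinical data.

## Radiomics

Discretization defaults to a fixed bin count of 32 inside the ROI:
parametric maps carry heterogeneous physical units (s, s⁻¹,
dimensionless), which makes absolute bin widths meaningless. GLCM uses
the 13 unique 3D offsets at distance 1, symmetric, features averaged
over offsets; GLRLM runs along the same 13 directions; GLSZM zones are
26-connected; GLDM uses the 26-neighbourhood with dependence threshold
α = 0. The wavelet filter is a one-level undecimated separable 2-tap
decomposition (averaging/differencing kernels), chosen for exact
invertibility and trivial fixtures; LBP is computed slice-wise along the
axial axis. Shape descriptors use face-counting surface area and
principal-moment elongation/flatness. Feature names encode provenance as
`map__filter__class__feature` and are stable across runs. Exact parity
with any particular external feature bank is a non-goal; every feature
here is defined by its own documented formula and tested against
hand-worked or brute-force oracles.

## Selection, balancing, classification

The selection chain is variance threshold (default 0.5) → one-way ANOVA
(keep p < 0.05) → L1-penalized logistic regression at C = 0.3 (features
with nonzero weight, |w| > 10⁻⁵). Features are z-scored with
training-fold statistics before the penalized fit and the SVM, because
both are scale-sensitive. Survivors are nested across steps by
construction. Degenerate folds never produce an empty design: if ANOVA
retains nothing (the expected outcome on null data) the chain keeps the
single best feature by F statistic, and if the L1 step zeroes every
weight it keeps the ANOVA survivors; both fallbacks are recorded.

SMOTE interpolates each synthetic sample uniformly on the segment
between a minority sample and one of its k = 5 nearest minority
neighbours (Euclidean), balancing classes 1:1 inside the training fold
only; parent indices and the interpolation coefficient are recorded so
the convex-combination property is verifiable. The classifier is an
RBF-kernel SVM with C = 1 and the 1/(p·Var) bandwidth heuristic — kept
flat (no inner grid search) to mirror a single-stage evaluation design.
Metrics per test fold: sensitivity, specificity, F1, accuracy, and AUROC
from decision-score ranks (Mann–Whitney with half-credit ties). All fold
and resampling seeds derive from one run seed.

Shapley attributions use the coalition definition directly: exact
enumeration of all 2^p coalitions for p ≤ 12 with out-of-coalition
features replaced by background samples, or permutation Monte-Carlo for
larger p. Both satisfy efficiency (attributions sum to the prediction
minus the mean background prediction); the summary ranking is by mean
absolute attribution.

## Problem sizes and numerical choices

The shipped benchmark sizes are the package's own defaults: 100-curve
recovery studies, 100-replicate noise studies at SNR 20, 1000-draw
identity checks, and a 160-phantom cohort on 16×16×7 grids whose
end-to-end run (curve-derived and unidirectional maps, original+wavelet
features on MSI/nrCBV/K2, selection, SMOTE, 5-fold SVM) completes in
about a minute. The cohort benchmark deliberately uses the maps that need
no voxelwise nonlinear fit; the gamma and bidirectional map fits are
exercised at full accuracy on smaller phantoms in the unit tests.
Solver tolerances are 10⁻¹⁴ (xtol/ftol/gtol) for curve fits; the L1
logistic solver runs to tol 10⁻⁶ with a 10⁴ iteration cap and raises on
non-convergence. Ties in TMAX resolve to the first maximum; intervals
are half-open and 0-based throughout the I/O layer.

## Known limitations

- The gamma-model and exchange-model fits assume the forward model
  class; model-independent (SVD) deconvolution is out of scope.
- No automated AIF detection; the AIF is an input (or synthetic).
- No T1-dominant dual-echo leakage modelling or preload correction.
- Feature values on degenerate ROIs (single voxel, constant intensity)
  are flagged NaN rather than imputed; downstream selection treats NaN
  p-values as non-significant.
- The phantom benchmark bounds what the tests can show about clinical
  data (see above); reported cohort metrics on real multi-center data
  are expected to be far lower than on phantoms.
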