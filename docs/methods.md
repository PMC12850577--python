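# Methods

This note documents the models behind `qsmhead`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions a user should know before trusting a number.

## Signal model and forward problem

A susceptibility distribution χ (ppm) perturbs the main field B0 by a
dipole convolution, computed spectrally with the unit kernel
D(k) = 1/3 − (k·b̂)²/|k|². The zero-frequency sample of D is undefined and
set to 0 (Lorentz-sphere convention: the mean induced shift is pinned to
zero, so absolute/mean susceptibility is not an observable — only
contrasts are). The convolution grid is zero-padded by a factor of 2 per
axis by default to suppress circular wrap-around; the factor is
configurable everywhere a kernel is built.

GRE phase follows φ_e = γ·ΔB·TE_e with the proton gyromagnetic ratio
γ = 2.675221874×10⁸ rad s⁻¹ T⁻¹ and a null phase offset at TE = 0. Field
maps carry an explicit unit tag (ppm or Hz) with Hz = (γ/2π)·B0·ppm·10⁻⁶.

Default acquisition: 3 T, TEs 4/8/12/16 ms, TR 61 ms, flip angle 20°,
B0 along z. Magnitude is piecewise constant per structure via a proton
density / T2* table (air ≈ 0 signal, bone very low, CSF high). Noise,
when enabled, is i.i.d. complex Gaussian on the complex signal with
standard deviation expressed relative to mean tissue magnitude.

**Partial volume.** The simulator applies a Gaussian blur (σ = 0.7 voxel,
configurable, 0 disables) to χ before computing fields. Acquired MRI data
is band-limited: tissue interfaces never produce voxel-sharp field steps.
Without this, the rasterized phantom creates inter-voxel phase jumps
larger than π at bone interfaces, which no unwrapping method can resolve
— with integer TE ratios a 2π jump at the first echo is aliased
self-consistently at every echo, so such voxels are unrecoverable in
principle. The blur models the acquisition point-spread function, not a
processing step.

## Head phantom

Nested ellipsoids on a voxel grid: air background, a scalp (muscle)
layer, a closed skull shell at least two voxels thick (verified by flood
fill in tests), a CSF ring, cortical gray matter, white matter, two
deep-gray nuclei (seed-jittered placement), and an optional air sinus at
the anterior skull base. Default water-referenced susceptibility values
are literature-standard: air +9.4 ppm, cortical bone −2.1 ppm, CSF 0,
GM +0.02, WM −0.03, deep gray +0.10, scalp −0.05; all overridable
per-structure. A spherical tumor (GTV) of configurable radius and χ can
be inserted anywhere; the benchmark places it at the skull base, and the
erosion benchmark places it touching the inner skull surface, where
background-removal erosion is most damaging.

The phantom captures the features that drive whole-head QSM difficulty —
air/bone/tissue interfaces, an interior air cavity, a boundary-adjacent
tumor — but not cortical folding, vessels, lesion texture, or
susceptibility anisotropy. Passing tests therefore demonstrate correct
algorithmic behavior under realistic field structure, not clinical-grade
accuracy on real anatomy.

## Phase unwrapping

`quality_guided_unwrap` is an exact region-growing method: edges between
neighboring voxels are weighted by the product of a phase-coherence term
max(0, 1 − |wrapped gradient|/π) and a magnitude-similarity term
min(m_i,m_j)/max(m_i,m_j); when a multi-echo series is available, a
coherence term multiplies in the per-echo phase-gradient agreement (a
small single-echo floor breaks ties among fully distrusted edges). Growth
starts at the highest-quality voxel of each connected component (ties:
lowest linear index) and always crosses the best remaining edge,
resolving each 2π ambiguity against the already-unwrapped neighbor. A
quality-weighted neighborhood voting pass afterwards repairs sub-regions
that entered through a mis-resolved edge. Output equals the continuous
phase up to one global 2π·k per connected component; all error metrics
remove the best single 2π·k per ROI before scoring, since that constant
is unidentifiable.

`laplacian_unwrap` is the approximate spectral baseline: a least-squares
Poisson integration of the wrapped phase gradients (divergence of
wrapped forward differences), solved with Neumann boundary conditions via
DCT. It is exact on phase whose true voxel increments stay below π
(ramps) and errs near genuine discontinuities — the standard failure mode
of spectral methods and the reason the exact method is preferred.

`temporal_unwrap_and_fieldmap` spatially unwraps the first echo, anchors
the global 2π·k against the (wrap-free) phase evolution between the first
two echoes, propagates later echoes by rounding against the TE-ratio
prediction, and fits φ vs TE through the origin per voxel by
magnitude²-weighted least squares. Field returned in Hz.

## Background field removal

Fields from sources outside the ROI are harmonic inside it. Four methods:

- **SMV / RESHARP**: subtract the spherical mean over radius-r balls
  (rasterized spheres in voxel units); the eroded mask keeps voxels whose
  ball fits inside the ROI. RESHARP deconvolves by Tikhonov-regularized
  CG on the normal equations (default λ = 10⁻⁴, tol 10⁻⁶, zero init).
- **VSHARP**: per-voxel largest admissible radius descending from r_max
  (default 10) to r_min; each radius's high-pass output is deconvolved
  with its own kernel via a thresholded spectral inverse (threshold 0.05
  on 1 − ball FFT) and the per-voxel composite assembled. Effective mask
  erodes by r_min.
- **PDF**: least-squares fit of susceptibility supported strictly outside
  the (optionally pre-eroded) mask to the interior field, CG on the
  normal equations with uniform weighting, relative tolerance 10⁻² —
  the Krylov iteration count acts as implicit regularization, standard
  practice for this method.
- **LBV**: 7-point finite-difference Laplace solve on the peeled mask
  with the total field as Dirichlet boundary data (CG, tol 10⁻⁶; direct
  sparse solve below 4000 unknowns). The `depth` parameter sets the
  grid-coarsening level (2^depth) used to build the initial guess by a
  coarse solve + trilinear prolongation; equivalence with any particular
  reference implementation's depth semantics is not claimed.

`residual_field_correction` fits and subtracts a full 3D polynomial
(total degree ≤ order) or real solid spherical harmonics (degree ≤ 4)
over the mask.

**Scoring convention.** When a polynomial-corrected estimate is compared
against ground truth (erosion sweep, annihilation benchmark), the same
polynomial projection is applied to both maps, i.e. the comparison lives
in the orthogonal complement of the polynomial subspace. This makes the
metric insensitive to smooth components of the truth itself — which no
background-removal method can preserve, since low-order fields are
harmonic and indistinguishable from background — and guarantees the
corrected RMSE never exceeds the raw one. Methods are compared on the
intersection of effective supports where they differ.

**Known behavior worth stating plainly:** every method removes the
harmonic-in-ROI component of the *local* field too. For a tumor near the
ROI boundary the SMV-family deconvolution additionally truncates low
spatial frequencies of the tumor's own field and biases the downstream
susceptibility low by tens of percent; LBV, which subtracts only the
harmonic interpolant of the boundary values, preserves interior detail
best on this phantom geometry. The reconstruction pipeline therefore
defaults to VSHARP (the configuration intended for in-vivo use, where
VSHARP's robustness to imperfect masks matters) but exposes
`bg_method = lbv|resharp|pdf`, and the susceptibility-recovery benchmark
uses LBV. PDF's exterior fit can absorb a smooth harmonic component of an
interior source's field; its recovery example is scored after the same
second-order projection that the pipeline's correction stage applies.

## Dipole inversion

Least-norm whole-head objective
‖W(Mₛ·Cχ − Mₛ·δB)‖² + λ₁·TV(χ) + λ₂·‖WMₛχ‖², χ constrained to the
soft-tissue mask, W = first-echo magnitude normalized to unit brain mean.
Defaults λ₁ = 4×10⁻⁴, λ₂ = 1×10⁻³, isotropic TV, 250 outer iterations
max, tolerance 10⁻³ on relative iterate change, deterministic zero
initialization.

Solver: monotone FISTA. Gradient steps on the smooth part with the
Lipschitz bound L = 2·max(W²)·(4/9 + λ₂) (‖D‖∞ ≤ 2/3); the TV proximal
operator by fast gradient projection on the dual (15 inner iterations,
dual variables warm-started across outer iterations); accelerated
iterates are accepted only when they decrease the objective, with a
momentum restart otherwise, so the recorded objective is non-increasing
by construction. An increase beyond the inexact-prox tolerance (10⁻⁴
relative) for 10 consecutive iterations raises a divergence error. The
automatic soft-tissue mask uses an Otsu threshold, largest connected
component, and small-hole filling (< 10 voxels); larger enclosed
low-signal cavities are genuine air/bone and stay excluded.

## Cohort simulation and statistics

The synthetic cohort draws latent bivariate normals with Pearson
correlation 2·sin(π·ρ_target/6) (Gaussian copula), so the Spearman
correlation between per-patient maximum tumor susceptibility and Ki-67
equals ρ_target in expectation. Ki-67 is mapped to 1–30 % (both sides of
the 5 % low/high threshold); each patient's ≥ 100 voxel draws are the
patient maximum minus exponential deviates (scale 0.05 ppm), so the
sample maximum is exactly the latent maximum; `noise_sd` (ppm) perturbs
the maxima and attenuates the correlation. The cohort emulates the
feature–proliferation *link structure* only — not spatial texture, not
segmentation error, not scanner effects — so classifier results on it
validate the machinery, not clinical discriminability.

First-order features: mean, median, max, min, std (ddof 1), SEM, IQR,
ICV, CV, skewness, excess kurtosis, P25, P75, mean/median absolute
deviation, energy, each over all tumor voxels and over the χ > 0 and
χ < 0 subsets (empty subsets yield NaN markers), plus volume in mm³.
Percentiles use linear interpolation between order statistics. ICV is
defined as the quartile coefficient of dispersion (P75−P25)/(P75+P25),
switchable to IQR/median.

Spearman correlations report the asymptotic two-sided p always and the
exact full-permutation p for n ≤ 10. Kruskal–Wallis uses the tie-corrected
H statistic; no multiple-testing correction is applied to the screen by
default (a Benjamini–Hochberg toggle would be a one-line addition at the
call site via `statsmodels`, deliberately left out of the default path to
mirror a raw-alpha screen). Feature selection: |ρ| ≥ 0.8 and p < 0.05
against Ki-67, greedy non-redundant pair (inter-feature |ρ| < 0.7,
ordered by |ρ| with lexicographic tie-break), optional third feature via
RFE with a logistic estimator on standardized features.

The classifier stage uses an outer leave-one-out loop and an inner
stratified 3-fold grid search; scaling is fit inside each training fold
only (enforced by pipeline construction and asserted by an
instrumentation test). Models: logistic regression, linear-kernel SVM
(linear because feature importances are defined as normalized absolute
coefficients), random forest and gradient boosting (importances: mean
impurity decrease). Hyperparameter grids are small fixed defaults
(C ∈ {0.1, 1, 10}; tree depth {2, 4}; learning rate {0.1, 0.3}).

## Problem sizes and determinism

Benchmarks run at 64³ (pipeline, background removal, erosion sweep), 96³
(forward-model oracle) and 48³ (two-sphere inversion); the cohort stage
uses n = 200 for correlation recovery and n = 30 for the classifier
checks, with a 17/13 class split in the permutation null — under an
exactly balanced split, leave-one-out with permuted labels exhibits the
known anti-learning artifact (each fold's training majority is always the
wrong class), which says nothing about the classifier. All stages are
deterministic given seeds: solvers use zero initialization and fixed
iteration schedules, morphology is deterministic, and the pipeline
records per-stage parameters and mask hashes in a provenance record.

## Limitations

- The phantom is ellipsoidal; no cortical geometry, vessels, hemorrhage,
  calcification, or χ anisotropy. Simulated magnitude ignores coil
  sensitivity and flow.
- Absolute susceptibility offsets are unobservable (kernel DC pinned to
  zero) and low-order spatial components of the local field are removed
  with the background; reported χ is relative contrast.
- The LBV `depth` and the published multigrid semantics are analogous,
  not identical.
- Exact-permutation Spearman p-values above n = 10 are not attempted
  (cost grows factorially); the asymptotic value is reported instead.
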