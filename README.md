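# qsmhead

Quantitative susceptibility mapping (QSM) beyond the brain: a whole-head
reconstruction pipeline with an in-silico validation framework, aimed at
susceptibility analysis of skull-base tumors.

QSM estimates voxelwise tissue magnetic susceptibility χ (ppm) from the
phase of multi-echo gradient-echo (GRE) MRI. The phase accrues linearly
with echo time, φ = γ·ΔB·TE, where the field perturbation is a dipole
convolution of the susceptibility distribution:

    δB/B0 = F⁻¹ [ D(k) · F(χ) ],    D(k) = 1/3 − (k·b̂)² / |k|²

Recovering χ requires three ill-conditioned steps, each implemented and
testable in isolation here:

1. **Phase unwrapping** — the measured phase lives in (−π, π]; an exact
   quality-guided region-growing unwrapper (with a multi-echo coherence
   weight) plus an approximate spectral baseline recover the continuous
   phase, and a weighted least-squares fit over echoes yields the total
   field map in Hz.
2. **Background field removal** — sources outside the ROI (air, bone)
   produce fields that are harmonic inside it. Four standard algorithms
   are provided: VSHARP, RESHARP, PDF and LBV, plus polynomial /
   spherical-harmonic residual correction and an erosion-sweep benchmark
   that quantifies how much of a boundary-adjacent tumor volume each
   method erodes.
3. **Dipole inversion** — a whole-head least-norm inversion minimizing
   ‖W(Mₛ F⁻¹DFχ − Mₛ δB)‖² + λ₁·TV(χ) + λ₂·‖WMₛχ‖² (defaults
   λ₁ = 4×10⁻⁴, λ₂ = 1×10⁻³) with a monotone FISTA solver.

Because no patient data ships with the package, a parametric whole-head
phantom (air, scalp, skull, CSF, gray/white matter, deep nuclei, an air
sinus, and an insertable spherical tumor) generates ground-truth
susceptibility, fields and wrapped multi-echo signals for every test, and
a synthetic patient cohort with a tunable Spearman link between tumor
susceptibility and the Ki-67 proliferation index feeds the downstream
statistics: first-order radiomic features over the tumor volume (per sign
subset), Kruskal–Wallis group comparisons, exact-permutation Spearman
correlation, and a nested-cross-validation (leave-one-out outer, 3-fold
grid-search inner) classifier of low vs high proliferation (Ki-67 < 5 % /
≥ 5 %).

## Worked example

```python
import numpy as np
from scipy import ndimage
from qsmhead import phantom, forward, invert

ph = phantom.build_head_phantom((64, 64, 64), (1, 1, 1), seed=11)
ph = phantom.insert_gtv(ph, center=(32, 32, 19), radius_mm=5.0, chi_gtv=0.3)

params = forward.AcquisitionParams(B0=3.0, TEs_ms=(4, 8, 12, 16),
                                   voxel_size=(1, 1, 1))
series, true_phase, field = forward.simulate_multiecho_signal(
    ph.chi, params, seed=2, labels=ph.labels,
    structure_table=ph.structure_table)

masks = {"soft": ph.brain_mask(), "brain": ph.brain_mask(),
         "gtv": ph.mask("GTV"), "exclude": ph.mask("sinus_air")}
chi, provenance = invert.qsm_pipeline(series, masks,
                                      {"bg_method": "lbv", "max_iter": 120})

gtv = ph.mask("GTV") & (chi != 0)
truth = ndimage.gaussian_filter(ph.chi, 0.7)   # partial-volume ground truth
print(f"GTV mean chi: {chi[gtv].mean():.4f} ppm "
      f"(truth {truth[gtv].mean():.4f} ppm)")
```

prints

```
GTV mean chi: 0.2049 ppm (truth 0.2475 ppm)
```

i.e. the full chain — unwrap, field fit, background removal, second-order
polynomial correction, regularized inversion — recovers the inserted
tumor susceptibility to within about 17 % on a noiseless 64³ benchmark.

A command-line surface wraps the same functions:

```
qsmhead simulate --config run.cfg --out out/
qsmhead unwrap --mag m.nii --phase p.nii --mask roi.nii --out field.nii
qsmhead bgremove --field f.nii --mask m.nii --method vsharp --out local.nii
qsmhead invert --field local.nii --mask soft.nii --out chi.nii
qsmhead benchmark-erosion --out sweep.tsv
qsmhead classify --cohort cohort.tsv --out report.tsv
```

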