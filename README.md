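# mtsms — motion-resolved SMS myocardial T1/T2 mapping

`mtsms` is a desk-scale, fully self-contained implementation of non-ECG,
free-breathing, motion-resolved myocardial T1/T2 mapping with
simultaneous-multislice (SMS) golden-angle radial sampling and a low-rank
tensor reconstruction.  It is aimed at researchers who want to study, test or
extend this class of quantitative cardiac MRI methods without scanner data:
the package contains a dynamic digital cardiac phantom and an exact forward
simulator, so every stage of the chain — sampling, self-gating,
reconstruction, parameter fitting, repeatability statistics — can be run and
verified end to end on a laptop.

## The method

A T2prep-IR FLASH sequence interleaves five T2-preparation durations
(τ = 0, 30, 40, 50, 60 ms; τ = 0 is a plain inversion) with two excitation
flip angles (α = 3°, 10°), giving a repeating cycle of **10 (τ, α)
recovery periods**.  Each 2.5 s period contains a continuous FLASH readout
train alternating 1:1 between *training lines* (fixed 0° radial spoke, the
self-gating navigator) and *imaging lines* (golden-angle 111.24°
increments).  Three short-axis slices are excited simultaneously with
CAIPIRINHA phase cycling (−2π/3, 0, +2π/3 per band, advancing one step per
imaging line), which makes the slice dimension a 3-point DFT.

The recovery signal at readout n of period k is

    s(n) = A (1−E1)/(1−E1 cos βα_k) · [1 + (B Q_k e^{−τ/T2} − 1)(E1 cos βα_k)^n] · sin βα_k

with E1 = exp(−TR/T1), amplitude A, signed inversion efficiency B, B1+
scale β, and Q_k = (1−E1 cos βα_k)/(1−E1 cos βα_{k−1}) carrying the steady
state of the previous period's flip angle.

The image series is modelled as a 5-way low-rank tensor

    A = G ×₁ U_x ×₂ U_T1 ×₃ U_τα ×₄ U_c ×₅ U_r

(voxels × recovery index × prep/flip combo × 20 cardiac × 6 respiratory
bins).  Reconstruction proceeds in stages: relaxation subspaces U_T1, U_τα
from the SVD of a Bloch signal dictionary (21 × 21 × 7 × 7 grid over T1, T2,
β, B); self-gated cardiac/respiratory binning of the training lines;
completion of the sampled 5-way training tensor (nuclear norms on the
feature/cardiac/respiratory unfoldings + temporal total variation, subject
to the relaxation subspaces); HOSVD factor extraction into the combined
temporal tensor Φ; and a least-squares/wavelet-regularized solve of the
spatial factor U_x against the imaging lines.  T1 and T2 maps are fitted
voxelwise in two steps (dictionary match + refinement of A, B, β, T2; then
T1 from the 3° periods only, where the Look–Locker perturbation is small).

## Worked example

```bash
python examples/04_full_reconstruction.py
```

runs the complete chain on the tiny preset (48×48 matrix, 3 slices, 16
recovery periods ≈ 40 s of simulated scan, noiseless) and prints, e.g.:

```
imaging-data residual of the spatial solve: 5.827%
myocardial median T1: 1144 ms (truth 1200, error 4.6%)
myocardial median T2: 45.1 ms (truth 42.0, error 7.4%)
(51 interior myocardial voxels pooled over 3 slices)
```

i.e. the motion-resolved reconstruction recovers the phantom's myocardial
relaxation times from a free-breathing, non-gated simulated scan to within a
few percent.  `examples/01...05` each demonstrate one capability (signal
model, simulator, self-gating, reconstruction, statistics) in a few lines.

A thin CLI wraps the same pipeline:

```bash
mtsms simulate scan.h5 --preset tiny --seed 1
mtsms reconstruct scan.h5 --preset tiny
mtsms fit scan.h5 maps/ --preset tiny
mtsms evaluate scan.h5 metrics.json --preset tiny
```

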