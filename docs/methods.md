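# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mtsms`.  Nothing here states an empirical result that the
test-suite or `scripts/acceptance.py` does not itself compute.

## Signal model and sequence schedule

The pulse sequence interleaves five T2prep-IR preparation durations
(0/30/40/50/60 ms; 0 = inversion only) with two FLASH flip angles (3°, 10°),
flip angle toggling every recovery period.  Because 5 and 2 are coprime, one
pass through the preparations flips the toggle parity, so the cycle closes
after 10 periods with every (τ, α) pair visited — the enumeration is
`[(τ₁,α₁),(τ₂,α₂),(τ₃,α₁),…]` and is exposed in `SequenceConfig`.  Each
period runs `N = floor(recovery/TR)` excitations (714 at the default
2.5 s / 3.5 ms), alternating training (0° spoke) and imaging (golden-angle)
readouts 1:1, training first.

The closed-form recovery curve (`signal_curve`) assumes each period starts
from the FLASH steady state of the previous period's flip angle
(the `Q_k` factor).  `bloch_oracle` is an independent per-TR recursion over
the executed schedule; the excitation slot immediately after the preparation
is treated as n = 0 (unrecorded) so the closed form's `(E1·cos βα)^n`
exponent is reproduced exactly.  The two routes agree to ~1e−13
(scale-normalized) whenever the steady-state premise holds numerically,
which the equivalence test enforces by using a long recovery period
(80 s ≫ T1); at the physiological 2.5 s recovery the premise itself — and
hence the closed form — is only a few-percent approximation for the longest
T1 values, which is inherent to the model, not to this implementation.
Echo-time relaxation during the readout is ignored (TE ≪ T2; the model
contains no TE term).

## Dictionary and relaxation subspaces

The dictionary evaluates the closed form on 21 log-spaced T1 ∈ [100, 3000]
ms × 21 log-spaced T2 ∈ [10, 3000] ms × 7 linear B1⁺ scales ∈ [0, 1.5] × 7
signed inversion efficiencies, chosen linear in [−1, −0.7] (an ideal
adiabatic inversion is −1; the span covers realistic efficiency loss).
Rows are the 10 combos at a decimated n-grid (every 15th training position
by default, 24 points).

The n-mode basis is *not* computed from the decimated rows: early inversion
recovery curves are strongly curved, and linear interpolation of a coarse
basis biases every off-grid evaluation.  Instead the n-mode Gram matrix is
accumulated over all atoms at **full temporal resolution** (357 training
positions), the top eigenvectors form the basis, and the decimated
orthonormal basis used by the tensor is its QR factor on the tensor grid;
off-grid queries go through the compatible full-resolution table
(`RelaxSubspaces.eval_table`).  Default ranks: L_T1 = 5, L_τα = 6, which
capture the dictionary to ~0.3% Frobenius (higher temporal ranks add
weakly-observed directions that the data cannot pin down and degrade the
voxelwise fits; see "Spatial factor" below).

## Digital phantom (what it emulates, what it does not)

The phantom is a geometric short-axis torso: elliptical body (fat-like
T1 350/T2 120 ms), liver block (800/34), left-ventricular myocardial annulus
(1200/42, near reported native myocardium at 3 T), blood pool (1900/250),
at three slice levels.  Cardiac contraction narrows the annulus with a
smooth periodic pulse (von-Mises-shaped, peak at phase 0.35, fractional
narrowing 0.35); respiration translates the whole frame along y with an
asymmetric waveform (sin⁴ with a phase warp — long end-expiration dwell),
amplitude 10 mm, period 4 s, with a seeded ±10% slow drift in rate and
amplitude.  Coils are 8 smooth loop-like complex sensitivities (RSS ≈ 1);
B1⁺ is a smooth low-order polynomial map clipped to [0.7, 1.3].  Partial
volume is handled by supersampled area-weighted rasterization, and the
simulator computes the exact forward model of the package's own encoding
(per-voxel closed-form contrast per readout, coil weighting, CAIPIRINHA
phasors, band sum, per-line non-uniform DFT, complex Gaussian noise whose σ
defaults to 2% of the peak training-line magnitude).  Frames are cached on
a 32-cardiac × 16-displacement quantization grid; the truth sidecar stores
the continuous per-line phases.

Not emulated: through-plane motion, flow, off-resonance/B0, realistic
anatomy, arrhythmia.  Passing tests therefore demonstrate correctness of
the algorithmic chain under rigid-translation breathing and smooth periodic
contraction, not robustness to everything real scans contain.

### Desk scaling (the "tiny" preset)

The tiny preset reconstructs a 48×48 matrix over the 270 mm FOV
(5.6 mm pixels) from 16 recovery periods (~40 s of scan).  A clinically
sized ventricle at this pixel size would leave a myocardial wall under two
pixels wide — a regime in which *no* method can measure wall T2 (the
partial-volume/ringing contamination from the adjacent blood pool, T2 250
ms, dominates).  The preset therefore enlarges the ventricle
(outer radii 36/40/44 mm, wall 15/16/17 mm) so the wall spans ~3 pixels,
matching the wall-to-voxel ratio of a full-resolution acquisition.  The
default (96×96, 72 periods ≈ 3 min) preset keeps anatomical sizes.
Myocardial summary values are medians over interior (one-pixel-eroded)
pure-myocardium voxels, the standard way segmentation avoids edge voxels.

## Encoding

The non-uniform Fourier transform is an exact direct-evaluation NUDFT: each
radial line's transform matrix is built by a geometric recursion from k = 0
outward (the negative-k half is the conjugate mirror), and the adjoint is
the exact conjugate transpose — the adjointness identity holds to machine
precision by construction, and there is no gridding/apodization error at
all.  At the package's matrix sizes this is faster than setting up a
gridding NUFFT, and it doubles as its own accuracy reference.  Operators
support complex64 sweeps (pipeline default; measured ~2e−6 agreement with
complex128 and ~4e−9 adjointness) for the iterative solvers.  Coil maps can
be taken from the truth sidecar (simulation mode) or estimated by
ramp-compensated gridding per CAIPIRINHA step followed by a per-voxel
3-point inverse DFT and RSS normalization.  SVD coil compression (default 6
virtual coils) is applied consistently to data and maps; localized loop
coils are not globally low-rank, and keeping too few virtual coils costs
the coil diversity the SMS slice separation relies on.

## Self-gating

Training features are the central 35% of each training readout across coils
(motion information concentrates at low |k|; thermal noise is white across
samples).  The relaxation-contrast sweep is removed by regressing the
feature time-series onto the per-line kron basis `u_T1(n) ⊗ u_τα(k)`; the
residual is smoothed with a short moving average (well above the cardiac
band) and decomposed by PCA.

*Respiration*: low-passed (<0.7 Hz) leading components, k-means (k-means++,
50 restarts, seeded) into 6 bins ordered by the first component's mean;
end-expiration = the most occupied bin.  A spectral detector (low band vs
high-frequency noise floor) collapses everything into one bin when no
respiratory signal exists.

*Cardiac*: the heartbeat is a narrow contraction pulse whose spectrum is
dominated by harmonics, and it is amplitude-modulated by the sign-flipping
inversion-recovery envelope, so naive broadband phase tracking fails.  The
heart rate is detected by scoring fundamental + 2nd-harmonic prominence
across components (components dominated by sub-0.7 Hz respiratory power are
excluded), the winning component is narrow-band filtered at the fundamental,
and the analytic-signal phase is partitioned into 20 uniform bins refined by
k-means on the unit circle, anchored at the band-passed extremum.

## Tensor completion and Φ

Training lines are deposited at (feature, n-grid, combo, cardiac, resp)
cells.  Before averaging, each line's contrast is shifted from its own n to
the cell's grid n through the subspace (first-order correction); without
this the ±15-TR averaging window blurs the early inversion recovery and
biases T1.  Unobserved cells are initialized by nearest-neighbor fill along
the cardiac (cyclic), respiratory, n and combo axes — view sharing as an
initialization only.  The completion solver minimizes data consistency +
λ(nuclear norms of the feature/cardiac/respiratory unfoldings) + cyclic
cardiac TV + non-cyclic respiratory TV, subject to the mode-2/3 subspace
constraints, by a monotone proximal alternating scheme (backtracking step;
λ = 0.01·σ_max heuristic, λ_c = λ_r = 0.02 λ; optional λ-continuation), and
then polishes with alternating exact data consistency / hard
multilinear-rank truncation, returning the best (lowest data-objective)
iterate.  Multilinear ranks are capped adaptively by the energy spectrum of
the view-shared tensor (motion modes at 99.99%, feature mode much tighter)
so that, e.g., a static scan collapses the motion modes to rank ~1 instead
of inventing bin-to-bin variation.  HOSVD factors with the fixed relaxation
subspaces give the core, and Φ is stored factored and queried lazily.

## Spatial factor

Each imaging line inherits its (cardiac, respiratory) bin from the
temporally nearest training line (≤ 1 TR by the 1:1 interleave) and its
temporal weight vector from Φ.  With the default λ_w = 0 the problem is
pure least squares and is solved by conjugate gradients on the normal
equations with Jacobi scaling of the temporal components (their data
content spans orders of magnitude) and a small ridge (1e−4 of the largest
normal eigenvalue); the quadratic objective is non-increasing over CG
iterations.  With λ_w > 0 a monotone FISTA iterates gradient steps with
orthogonal-wavelet (db4, 3 levels, periodization) soft-thresholding per
basis image, real and imaginary parts separately; candidates that raise
the objective trigger a momentum restart.  Raising the temporal or spatial
rank beyond the defaults consistently *degrades* the voxelwise fits on the
desk-scale problem: the extra directions are weakly observed and act as a
sink for the model-mismatch residual, which re-appears as structured curve
errors near tissue boundaries.  The default spatial rank (feature-mode
rank) is therefore capped at 16 and further reduced adaptively.

## Parameter fitting

Rendered curves at end-expiration/diastole are phase-corrected by their
late-n (steady-state) phase per combo and fitted as real signals.  Step 1:
maximum normalized inner product over the dictionary, then bounded
nonlinear least squares over (A, B, β, T2) with T1 free but discarded.
Step 2: (A′, T1) on the 3° periods only with (B, β, T2) fixed, T1 bounded
to [100, 3000] ms.  Curve SNR in the Monte-Carlo tests is defined as
rms(signal)/σ.  Diastole is chosen as the cardiac bin with the lowest mean
truth contraction in simulation (a config index otherwise); end-expiration
is the modal respiratory bin.

## Statistics

ICC is two-way, absolute-agreement, single-measure (the flavor is a config
enum); Bland–Altman uses 1.96 sample standard deviations; scan–rescan CoV
uses the two-point sd |x₁−x₂|/√2, RMS-aggregated (segment-wise: RMS over
segments, divided by the subject mean, then RMS over subjects — the
normalization order is one reading of an ambiguous convention and is fixed
here); segment SNR is mean/sd within the segment and SNR efficiency divides
by √(scan minutes).  AHA-16 labels are 60° sectors counter-clockwise from
the anterior RV insertion at basal/mid levels and 90° quadrants apically.

## Numerical conventions

Image coordinates in FOV units on pixel centers; k in cycles/FOV with 2×
readout oversampling (dk = ½, 96 samples at 48²).  All randomness flows
from a single seed through named substreams.  Completion and CG record
their objective each iteration; non-convergence (sustained objective rise)
raises with the trace attached.  HDF5 datasets are written with
`track_times=False` so reruns are bit-identical.

## Known limitations

- The closed-form/recursion equivalence is exact only under the per-period
  steady-state premise (long recovery); at 2.5 s recovery the model itself
  is approximate for T1 ≳ recovery.
- Desk-scale resolution leaves residual partial-volume/leakage T2 bias at
  the blood–myocardium interface even in interior voxels (a few percent at
  the tiny preset's geometry; worse for clinically thin walls at 48²).
- Binning assumes quasi-periodic motion; arrhythmia or bulk motion is out
  of scope, as are through-plane motion, flow and off-resonance.
- The real-time (ungated) reconstruction is provided and tested but the
  default pipeline gates directly on training-line features, which is
  cheaper and is the committed design.
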