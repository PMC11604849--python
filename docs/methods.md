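# Methods

## Signal model

A voxel of chemically shifted water and fat signal acquired with a
spoiled multi-echo gradient-echo readout is modelled as

    y(t_n) = ( W + Σ_m ρ_m(cl, ndb, nmidb) · e^{i 2π f_m t_n} )
             · e^{i 2π ψ t_n} · e^{iφ} · e^{−R2* t_n}

with nine triglyceride resonances m ∈ {A..I} at chemical shifts 0.90,
1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19 and 5.29 ppm.  Each resonance
magnitude ρ_m is an affine function of the mean-triglyceride
parameters: chain length `cl`, number of double bonds `ndb`, and number
of methylene-interrupted double bonds `nmidb` (e.g. the methylene peak
carries `6(cl−4) − 8 ndb + 2 nmidb` protons).  Splitting each ρ_m into
its constant, ∝ndb and ∝nmidb parts yields a linear model in the four
real amplitudes `x = (W, Fntg, Fndb, Fnmidb)`; composition follows as
`ndb = |Fndb|/|Fntg|`, `nmidb = |Fnmidb|/|Fntg|`, and the fatty-acid
fractions as `UFA = (ndb − nmidb)/3`, `PUFA = nmidb/3`,
`MUFA = UFA − PUFA`, `SFA = 1 − UFA`.

### Amplitude units

The resonance table counts protons per triglyceride, so the raw fat
columns of the design matrix are two orders of magnitude larger than
the water column at equal proton density.  The fat columns are
therefore divided by `s0 = (6 cl + 2 − 2 ndb)/(1 + ndb + nmidb)`,
evaluated at the assumed composition, which puts `F = Fntg + Fndb +
Fnmidb` in water-proton units so that `PDFF = F/(F + W)` is the proton
density fat fraction.  Without this normalisation a pure-fat voxel
would read `F ≈ 0.01 W`-scale amplitudes and the PDFF ratio would be
destroyed by any amount of signal mixing; composition ratios are
invariant to the choice.  The raw convention remains available
(`basis_matrix(..., normalize="raw")`) and is what the printed
component-weight matrix contains.

Frequencies are computed as `f_m = γ̄ B0 (δ_m − δ_w) · 10⁻⁶` with
γ̄ = 42.577478518 MHz/T and a water reference shift of δ_w = 4.7 ppm
(configurable; the methyl resonance then sits near −485 Hz at 3 T).

## Acquisition design

The reference protocol interleaves two 8-echo trains starting at 1.8
and 2.7 ms with 1.8 ms intra-train spacing, giving 16 TEs from 1.8 to
15.3 ms at an effective 0.9 ms spacing; TR is 18.5 ms with 8
excitations per heartbeat over 12 beats, i.e. 48 radial spokes per TE
(rate ≈ 6 for a 192 matrix under the radial Nyquist convention of
(π/2)·matrix spokes).  Variable flip angles keep the transverse signal
constant across the excitations of a beat for an assumed adipose T1 of
350 ms; the schedule is found by bisection on the common signal level
with the final pulse at 90°, assuming full longitudinal magnetisation
at each trigger (configurable).  This reproduces the published 22–48°
ramp with a maximal final pulse.

Projection angles follow golden-ratio increments at the spoke level
(π·(√5−1)/2 per spoke, modulo π) plus a golden-ratio sub-rotation of
the spoke gap per echo, so no two echoes share an angle and every TE
aliases differently.

## Digital phantoms

`phantom_sim` builds an oil-emulsion phantom mirroring a physical
validation phantom: five plant oils (coconut, olive, avocado, sesame,
flaxseed — plus 50/50 coconut/avocado and 25/75 coconut/sesame
mixtures) at emulsion volume fractions 25/50/75/100%, as discs in a
finite water bath surrounded by air.  Because no per-oil composition
values are published for the original oils, the bundled table is built
from literature-typical chain-fraction profiles (fractions of chains
with 0/1/2/3 double bonds and mean chain length); it is simulation
ground truth only.  Volume fractions are converted to nominal PDFF via
densities, molar masses and protons per molecule against the water
reference (2 protons, 18.015 g/mol, 0.997 g/mL).

Vials are drawn at ~6 px radius where the grid allows — the size of a
50 mL tube at the reference 192 matrix over a 450 mm field of view —
because patch-based denoising and point-spread-function mixing act on
absolute pixel scales.  The field map is a low-order 2-D polynomial
with |ψ| ≤ ~150 Hz (inside one amplitude-aliasing period of the 0.9 ms
spacing), the initial phase a smooth polynomial, R2* uniform per
region.  Eight birdcage-style synthetic coils with smooth magnitude
and phase are used; their ground-truth maps are exported so the
sensitivity-calibration step can be bypassed in controlled tests.

Radial k-space is sampled with an exact non-uniform DFT (2× readout
oversampling, |k| ≤ N/2 in cycles/FOV; a k = 0 sample equals the image
sum) and i.i.d. complex Gaussian noise per channel.  The target SNR is
defined in the image domain: the k-space noise level is back-computed
through the (linear) gridding operator as
`σ_k = ref / (SNR · √Σw² / n_pix)` with `ref` the mean first-echo
object magnitude.

What the generator does **not** emulate: cardiac/respiratory motion,
slice profiles, B1 transmit effects, T1 saturation of the variable
flip-angle train, eddy currents beyond a linear gradient delay, or
emulsion stabiliser protons.  Passing tests therefore demonstrate the
correctness of the reconstruction/estimation chain under the stated
signal model, not robustness to physiological confounds.

## Reconstruction

1. **Gradient-delay correction** shifts each spoke's coordinates along
   its readout by `dk · (τ_x cos²θ + τ_y sin²θ)/dwell`; data untouched.
2. **Coil compression**: principal components across the coil
   dimension, keeping the fewest virtual coils whose discarded energy
   is ≤ 5% (tolerance configurable); the mixing matrix is kept for
   provenance.
3. **Gridding**: density-compensated adjoint NDFT per coil and TE.
   Density compensation is a ramp |k|·Δθ·dk with per-spoke angular
   gaps (golden-angle sets are only quasi-uniform) and a regularised
   DC floor; at or above the radial Nyquist spoke count the radial
   weight profile is refined once per design by an apodised
   fixed-point iteration (Pipe–Menon style) that drives the weighted
   point-spread function toward a delta, reducing smooth-object NRMSE
   from ~3% to <2%.  For undersampled trajectories the plain ramp is
   the appropriate choice and the fixed point is not used.
4. **Coil combination**: SENSE-style `Σ S̄_c I_c / Σ|S_c|²`.  The
   default sensitivity backend is an autocalibrating eigen-estimate:
   the dominant eigenvector of the locally smoothed coil covariance at
   each pixel (adaptive-combine style), unit-norm across coils with
   the first coil taken real-positive; an oracle backend accepts
   simulator ground truth.  Estimated maps are unit-norm, so the
   combined image carries the true RSS shading — a smooth real factor
   the voxelwise fit is invariant to.
5. **LLR denoising**: 4×4 patches (stride 2, uniform overlap
   averaging; disjoint tiling available), complex SVD of each P×N
   Casorati matrix, hard threshold λ = (4/√3)·√N·σ₅ where σ₅, the
   first singular value beyond the four model components, estimates
   the noise floor.  Rectangular patches fall back to the
   β-dependent coefficient.  Noiseless rank-4 data pass through
   bit-near-identically; pure-noise patches are annihilated.

## Voxelwise estimation

For fixed (ψ, R2*) the real amplitudes and initial phase have closed
forms (`x̂ = Re(AᴴA)⁻¹ Re(Aᴴ Ψᴴ y e^{−iφ})`,
`φ̂ = ½ arg(zᵀ Re(AᴴA)⁻¹ z)`, `z = Aᴴ Ψᴴ y`; the π ambiguity of the
half-argument is resolved by requiring Fntg ≥ 0).  The residual J is
evaluated on a discrete grid: R2* from 0 to 300 s⁻¹ in steps of 2
(marginalised by its per-ψ minimum) and ψ over ±556 Hz (half the
amplitude-aliasing bandwidth of the 0.9 ms spacing) in steps of 2 Hz.

The off-resonance label field is chosen by a coarse-to-fine (4×, 2×,
1×) iterated-conditional-modes sweep with a checkerboard update and a
capped absolute-difference pairwise penalty (cap 80 Hz, weight 0.5 on
the per-voxel-normalised residual), which resolves the water–fat
ambiguity at region level.  Because strong smoothing flattens steep
but genuine gradients, each voxel then re-picks its label from the
already-computed residuals within a ±20 Hz window, and parabolic
interpolation through the chosen label and its neighbours refines both
ψ and R2* below the grid step.  With zero smoothness weight the search
reduces to the exhaustive per-voxel grid minimiser.

Amplitudes are estimated in two stages: stage 1 solves a 3-component
model in which the Fnmidb column is folded into Fndb with an assumed
nmidb/ndb ratio (default 0.26; the default chain length is 17.4, and
the assumed ndb used for basis normalisation follows the chain-length
heuristic inversion, ndb = (cl − 16.8)/0.25).  Stage 2 re-solves the
full 4-component real linear system with every amplitude bounded to
[0.5, 2]× its initial estimate (bounds act on magnitudes with signs
restored and a flag when an initial component is negative) using
scipy's trust-region reflective bounded least-squares solver with
tolerance 1e-12; the initial phase comes from the full 4-component
closed form and is held fixed through both stages.

## Phantom validation protocol

As in physical phantom practice, per-oil reference compositions
parameterise the fit of each oil's vials: a single global confounder
search (generic assumptions) fixes the smooth field map, then each
oil group's (ψ, R2*) are re-minimised locally (±30 Hz, excluding the
aliased decoys) under the oil's own (cl, ndb, nmidb) and the
amplitudes are fit with the matched ratio.  Vial statistics use
2-px-eroded ROI means; regression of fitted vs true ndb/nmidb is
restricted to the 100%-PDFF vials, which are closest to adipose
tissue.

## Problem sizes and reproduction settings

The bundled validation study uses an 80×80 matrix (which preserves the
paper-scale vial-to-pixel geometry), 8 coils, image-domain SNR 100 and
the Nyquist spoke count (126), with denoising enabled — the recovery
study isolates estimation accuracy at full sampling, while the
separate denoising study runs the 48-spoke undersampled protocol at
three SNRs (20/50/100) on a 64×64 grid and compares denoised against
plain gridded reconstructions.  The whole validation suite runs in
minutes on one CPU.

## Known limitations

* PDFF and FAC accuracy at emulsion (partial-fat) vials is limited by
  point-spread-function mixing with the surrounding bath and by patch
  thresholding at vial borders; errors grow as vial size approaches
  the patch size, mirroring the poorer low-concentration accuracy seen
  in physical phantom work.
* The ICM field-map optimiser is a local scheme; the interface allows
  swapping in a graph-based optimiser for harder field topologies.
* T1 bias of the variable flip-angle train is not modelled or
  corrected; analyses are intended for high-PDFF regions (>75%).
* A single common R2* is shared by all resonances.
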