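# Methods

This note documents the models, numerical choices, and limitations of the
`mrcdi` package in the order the pipeline runs.

## Head phantom

The phantom is a stack of strictly nested ellipsoids with the tissue
topology that conductivity optimization needs: scalp ⊃ skull ⊃ cortical CSF
⊃ gray matter ⊃ white matter, plus a ventricular-CSF ellipsoid inside the
white matter.  Default outer semi-axes (mm) are scalp (78, 92, 72), skull
(70, 84, 64), cCSF (62, 76, 56), GM (55, 69, 49), WM (46, 60, 40), vCSF
(12, 24, 10) — adult-head proportions with shell thicknesses of 7–9 mm so
that every compartment survives voxelization at the default resolutions.
Grids are axis-aligned RAS with the origin at the head centre; the default
is 48³ voxels at 4 mm for tests and interactive use (96³ at 2 mm remains
available for finer studies — the solver cost scales roughly linearly in
voxel count).

Validation requires each shell to be at least one voxel thick
(`max(voxel_size)`), not merely positive: a thinner shell voxelizes to an
empty compartment, which `build_phantom` additionally detects and rejects.
Synthetic cohorts are made by multiplying each compartment's semi-axes by
an independent factor drawn uniformly from ±5% (resampled until the nesting
invariant holds).  This emulates inter-subject anatomical variability in
size only; it does not emulate cortical folding, tissue heterogeneity, or
segmentation error.

Electrodes are modelled as Dirichlet patches: the set of scalp-surface
voxels within an angular radius (default 25°) of a patch axis.  Right–left
(RL) places them on ±x, anterior–posterior (AP) on ±y.  There is no
gel/contact-impedance layer; only the total injected current (default
1 mA) is physically meaningful, which the solver enforces by rescaling
(below).

## Forward model

The potential solves ∇·(σ∇φ)=0 with a 7-point finite-volume stencil.  Face
conductivities are harmonic means of the adjacent voxels, so current is
conserved exactly across tissue interfaces and insulating background
(σ = 0) yields natural zero-flux boundaries.  The linear system is solved
with Jacobi-preconditioned conjugate gradients to a relative residual of
1e-8 (deterministic zero start; repeated solves during optimization
warm-start from the previous potential, which typically cuts iterations by
several-fold).

A unit-Dirichlet solve (φ = ±1 V on the patches) is rescaled post hoc so
the net anode current equals the requested injection current.  Because only
the total current is enforced, scaling all conductivities by a common
factor leaves J = −σ∇φ and hence B_z unchanged — the global degeneracy that
motivates anchoring the optimization with a fixed vCSF conductivity.  The
test suite asserts this degeneracy to solver tolerance, charge conservation
through electrode-separating planes to 0.5%, and exact antisymmetry under
electrode swap.

B_z is the z-component of the Biot–Savart integral over J, evaluated as a
discrete convolution with the analytic kernel d/|d|³ sampled at voxel-centre
displacements, the singular self-cell set to zero.  Zero padding to at
least 2N−1 per axis makes the circular convolution linear (no wrap-around);
kernel FFTs are cached per grid.  A direct Riemann-sum implementation
serves as the oracle (they agree to ~1e-15 relative on 16³ random fields;
the contract is 1e-3).  Wire fields (loop validation, lead stray fields)
use the exact finite-segment formula, with the denominator floored at
ε⁴ (ε = 0.1 voxel) for points on a segment; a 360-segment polygon matches
the circular-loop on-axis closed form to well under 0.5%.

μ0 is fixed at 4π×10⁻⁷ T·m/A and γ (proton) at 2.6752218744×10⁸ rad/s/T.

## Measurement model and reconstruction

The acquisition alternates current polarity every repetition.  Phase at
echo e of repeat k is s_k·γ·T_E·(B_z + n_k) + baseline + thermal noise,
wrapped to (−π, π], where s_k = ±1, n_k is a per-repeat spatially smooth
random field (physiological noise), the baseline is a fixed smooth
background phase, and thermal phase noise has sd = 1/tSNR (high-SNR
regime).  Magnitude images are 1 + N(0, 1/tSNR), so their temporal mean/sd
recovers the configured tSNR.  Defaults follow a double-echo EPI protocol
(T_E = 25.6/63.48 ms, T_R = 120 ms); an 8-echo MGRE preset
(T_E = 5.6…67.2 ms, T_R = 80 ms) is included.  Acquisition-level effects —
k-space readout, geometric distortion, eddy currents, T2* decay — are not
simulated.

Reconstruction takes the phase difference of each polarity pair as the
argument of the complex ratio (never by subtracting wrapped phases),
averages pairs, and divides by 2γT_E.  Per-echo variances follow from tSNR
error propagation, var(B_z,e) = 1/(2·n_pairs·γ²·T_E²·tSNR²); the published
description states the weighting principle (variance from magnitude tSNR)
without a formula, so this propagation of the reconstruction equation is
the package's own choice, as is the inverse-variance *weighted mean* across
echoes (a weighted regression over echoes would be the main alternative).
Zero temporal sd (noiseless simulations) floors the variance at machine
epsilon with a warning so weights stay finite.  Any polarity-independent
phase cancels exactly; the noiseless round trip is exact to well below
1e-12 T wherever |γT_E·B_z| < π.

The physiological noise field is white noise smoothed with a Gaussian
kernel of standard deviation L/√2, giving autocorrelation exp(−d²/2L²)
(L is the "correlation length", default 30 mm), rescaled to a requested RMS
over the head.  The MGRE-like noise amplitude (default 0.5 nT RMS) and L
are configuration values chosen to produce noise floors resembling
published low-frequency patterns; they are not measured constants.

## Conductivity optimization

δB_z(σ) is minimized over the five free tissues with bounds
0.1<σ_WM<0.4, 0.1<σ_GM<0.6, 0.2<σ_cCSF<1, 0.2<σ_scalp<1,
0.003<σ_skull<0.04 S/m, the ordering constraint σ_WM ≤ σ_GM, and vCSF
fixed at 1.79 S/m (CSF at body temperature).  Literature starting values
are σ_WM=0.126, σ_GM=0.275, σ_cCSF=0.8, σ_scalp=0.465, σ_skull=0.01 S/m.

The optimizer is bound-constrained Nelder–Mead with the ordering constraint
reparameterized as σ_GM = clip(σ_WM + slack, bounds), slack ≥ 0, so every
iterate is feasible; the initial simplex steps 10% of each bound range.
Each evaluation is a full forward solve per dataset (no surrogate model —
direct re-evaluation is cheap at these sizes), memoized on σ rounded to
1e-6 S/m.  Termination: simplex size below `xatol` (1e-4 S/m for precise
fits, 1e-3 for the statistical experiment drivers) or the evaluation budget
(default 500; drivers use 120–400).  Multiple montages are fit jointly by
concatenating their masked voxels into one residual vector with equal
per-voxel weight (no stated inter-montage weighting exists; equal weighting
is the package's choice).  N in the objective is the total masked voxel
count over all datasets.

On noiseless data the joint RL+AP fit recovers the generating
conductivities to ≲0.05% at 32³–48³; scaling the vCSF anchor by c rescales
all recovered conductivities by ≈c, as the degeneracy predicts.

## Experiment drivers and problem sizes

*Loop validation*: a 2 mA loop (default radius 120–130 mm) around the head;
measurement simulated, reconstructed, and the modelled loop field
subtracted; residual RMS reported per slice (5 slices, 10 mm apart, 3 mm
thick — the slice prescription is configurable since exact slice placement
relative to the electrodes is a free protocol choice).

*Noise-floor study*: B_z simulated from ground-truth conductivities
(σ_WM=0.11, σ_GM=0.23, σ_cCSF=0.9, σ_scalp=0.3, σ_skull=0.012 S/m, chosen
close to the literature start so convergence is fast) with an RL montage;
a reconstructed zero-current noise floor is added; white ("EPI-like") and
white+correlated ("MGRE-like") floors are rescaled to a common RMS
(default 0.3 nT, ~15% of the in-brain field RMS at 1 mA) so the comparison
isolates the noise *structure*.  δJ is evaluated over all tissues above the
lowest imaging slice, with no upper boundary.  Correlated noise projects
onto field patterns the conductivities can (mis)explain, so it degrades the
fit more than white noise of equal power — the drivers reproduce this
ordering over ≥10 paired seeds.

*LOOCV*: five perturbed phantoms share ground-truth conductivities;
each fold fits the other four jointly and evaluates the held-out subject's
δB_z against the literature initialization, reporting per-fold
before/after and the mean ± SE of the group conductivities.

On an ellipsoid phantom the RL and AP montages are geometrically
symmetric, so montage-dependent residual asymmetries seen in vivo will not
appear unless a deliberate model mismatch (e.g. a skull-thickness error
between the data-generating and fitting phantoms, via `perturb_phantom`)
is injected.

Problem sizes: the unit/property tests run at 12³–32³ and the statistical
drivers in the test suite and acceptance script at 32³ (6 mm) with 10
paired seeds and 5 cohort subjects; parameter recovery in the acceptance
script runs at 48³ (4 mm).  These sizes were chosen so a full run completes
in minutes on one CPU; the methodology is identical at larger sizes, and
recovery accuracy is resolution-independent because the fit is an inverse
crime (simulated and fitted fields share the discretization).  What passing
these experiments does *not* show: robustness to segmentation error,
anisotropy, electrode mis-modelling, or any discrepancy between a real head
and its model — on real data those systematic errors dominate residuals.

## Determinism

All randomness flows through explicit seeds (`numpy.random.default_rng`);
per-condition seeds are derived from a base seed by fixed offsets so
noise-type comparisons are paired.  Metrics use single-threaded NumPy
reductions, making report JSONs bitwise reproducible for identical
config + seed.
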