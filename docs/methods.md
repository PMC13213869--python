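# Methods

`cineimoco` implements a free-breathing 3D cardiac cine method end to end
at desk scale: stack-of-spirals acquisition design with variable-density
slice ordering and tiny-golden-angle rotation, DC self-gated
respiratory/cardiac binning, and a 4D iterative motion-compensated
("iMoCo") reconstruction, validated against a synthetic beating/breathing
multi-coil phantom with known ground truth.

## Acquisition model

A stack-of-spirals acquisition covers 3D k-space with 2D variable-density
spiral readouts in-plane and Cartesian phase encoding along the slice
(kz, "partition") axis.  Every TR (4.5 ms) acquires one spiral readout at
one (kz partition, rotation angle) pair.  The full-scale protocol is
2 mm isotropic: 384 mm field of view, 192×192 matrix, 80 partitions
(64 + 25% slice oversampling), a 32-interleave variable-density spiral
with 2.5 ms readouts, 119 discrete rotation angles, bSSFP contrast at
flip angle 50° and ~350 s of scanning (77 777 TRs).

### Spiral design

`design_vd_spiral` builds a spiral-out readout as a two-region Archimedean
spiral: fully (Nyquist-) sampled out to an inner radius (default 25% of
k_max) with a linear density taper to 25% of Nyquist at the k-space edge.
The gradient waveform comes from time-optimal path parametrization: the
speed along the geometric spiral is capped by the gradient amplitude limit
(default 16 mT/m) and, through the local curvature, by the slew-rate limit
(180 mT/m/ms), with a forward acceleration pass from rest.  The design is
infeasible (raises, naming the binding constraint) when k_max cannot be
reached within the requested readout duration.  Gradients and k-space
positions are mutually consistent: trapezoidal re-integration of the
gradient reproduces the trajectory to a few 1e-4 of k_max.

### Slice orderings and rotation

Three per-TR orderings are implemented:

1. *fixed angle per slice loop*: sweep all partitions linearly at one
   rotation, then advance the angle;
2. *rotation per TR, constant density*: linear partition sweep, rotation
   advancing every TR;
3. *rotation per TR, variable density*: partition drawn from a truncated
   discrete Gaussian over partitions (default sigma = 10.8 partitions of
   80), rotation advancing every TR.

The per-TR rotation increment is the tiny golden angle of order 4,
psi_4 = 180/(tau+3) = 38.98°, quantized to the nearest multiple of
360/119 = 13 steps = 39.33°, so every acquired rotation lands on the
discrete angle grid.

The variable-density order is realized by largest-remainder quota sampling
of the Gaussian (so the empirical partition histogram matches the density
to a total-variation distance < 0.02) followed by a quota-weighted
constrained random walk: each TR acquires a partition within ±8 of the
previous one (small kz steps limit eddy-current excitation), and the walk
is forced back to the kz center early enough that every 360 ms window
contains a center readout — the DC navigator guarantee.  In the rare case
that no partition within reach has remaining quota, the walk steps toward
the remaining mass and may acquire a few off-quota partitions; the
histogram deviates by at most a handful of counts out of 77k.

With sigma = 10.8 the center partition receives ≈3.7% of all TRs, about
3× the uniform rate.  After retrospective sorting into 25 cardiac phases
(stochastic beat model, RR ~ N(1000, 50) ms), the mean per-phase fraction
of the 119 angles acquired at the center partition is ≈63% for the
variable-density ordering versus ≈28% for both constant-density
orderings, closely following the random-occupancy expectation
100·(1−(1−1/119)^m) for m center visits per phase.  A strictly periodic
heartbeat instead aliases against the 360 ms slice loop and can deviate
from that formula by several points, which is why the beat model includes
RR variability.

## Synthetic phantom and simulator

The phantom is a set of ellipsoidal tissues (outer fat, chest wall, two
lungs, liver, an abdominal organ block, LV myocardium and blood pool) with
intensities from the on-resonance bSSFP steady state
pd·sin α(1−E1)/(1−(E1−E2)cos α−E1E2) at low-field-representative T1/T2
(e.g. blood 1120/260 ms, myocardium 700/60 ms, fat 180/110 ms — fat is
bright, as bSSFP at low field makes it).  Rasterization uses a smoothstep
edge of configurable width; quantitative gridding tests use an edge of
~2.5 voxels so the object is band-limited on the test grid.

Cardiac motion scales the blood-pool semi-axes by (1−EF·c(f))^(1/3) with a
C1, strictly periodic contraction c(f) that is exactly 0 at phase 0 and
in diastasis and exactly 1 at the end-systolic phase (default 0.35 of the
RR interval), so the end-systolic blood volume is exactly (1−EF) of
end-diastole by construction.  The myocardial shell thickens mildly
(outer-axis contraction 8%).

Respiratory motion is a bulk translation of the heart, liver and abdomen
(superior-inferior dominant, default 12 mm full-scale; anterior-posterior
4 mm) following the standard even-power breathing waveform
u(t) = env(t)·cos²(θ(t)) with a time-asymmetric phase
θ = πt/T + (a/2)·sin(2πt/T), a = 0.35: inspiration is brisk and the
expiratory pause long (roughly 2:1 dwell), so end-expiration (u = 0) is
the most occupied position, as in real breathing — without the asymmetry
the "most stable 40%" window can land on the inspiration plateau instead.
The slow envelope varies the breath depth by ±15% cycle to cycle:
end-expiration is the one reproducible — and hence modal — position,
while inspiration excursions wander, the familiar irregularity of free
breathing.  The chest wall and fat are static and the lungs are static
dark structures that inflate mildly with inspiration (10% z-growth),
so the diaphragm (liver/abdomen tops) slides over the lungs.  It is this
moving tissue/lung interface — not the bulk translation itself, which the
k-space origin cannot see under a uniform coil — that modulates the DC
samples and drives self-gating, at the level of a few percent per channel
against ~1% of cardiac modulation.

The simulator quantizes the motion to (16 respiratory × 24 cardiac)
rendered frames, applies static smooth complex coil profiles, samples
stack-of-spirals k-space with the same encoding operator the
reconstruction uses (an inverse-crime setup, acknowledged; an oversampled
rasterization option softens it), and adds circularly symmetric complex
noise.  Ground truth (waveforms, trigger times, coil maps, per-TR
displacement) is stored alongside.  Identical seeds give bit-identical
output.

## Encoding operators

The encoding factorizes as coil sensitivity multiplication, a 1D DFT
along the uniformly sampled partition axis, and a 2D NUFFT onto the
rotated spiral coordinates.  The NUFFT is Kaiser-Bessel gridding on a 2×
oversampled grid (kernel width 6, Fessler/Beatty beta; deapodization by
numerical quadrature of the kernel transform).  The interpolation step is
an explicit sparse matrix, so the adjoint is the exact conjugate
transpose (adjoint identity at machine precision) while accuracy against
the naive Fourier sum is ~1e-5.  Per pass, the oversampled in-plane FFT
is computed once per (kz plane, coil) and the sparse kernel touches each
distinct (angle, kz) pair once; duplicated readouts only gather/sum.

Coil maps are estimated from apodized central k-space (Gaussian taper over
the central 25% of k-space, with a floor of 16 cycles/FOV so tiny desk
grids keep enough calibration resolution), divided by the
root-sum-of-squares image, lightly smoothed and RSS-normalized inside a
support mask.  On simulated data with known coils the complex correlation
with truth exceeds 0.99 inside the mask.  Coil compression is plain PCA
across channels.

Density compensation is separable per bin: an in-plane per-sample profile
times per-readout factors.  The profile is seeded with the analytic
area-per-sample of the spiral (arc length × local track spacing) and
refined by Pipe-Menon fixed-point iteration on the fully rotated
trajectory set; the analytic separable picture alone is wrong near the
spiral origin, where all rotations pile up, and the refined profile is
what makes plain density-compensated adjoint gridding quantitatively
accurate (NRMSE < 0.05 against a band-limited phantom at full sampling).
Within a bin, each readout is weighted by (n_angles / angles present in
its kz plane) and duplicated (kz, angle) acquisitions split their weight
equally.  The weights are normalized to maximum 1 per bin, and the solver
additionally applies one global scalar (a pooled Rayleigh quotient) so
the normal operator is approximately the identity: the density-compensated
adjoint then sits at the solution's scale, the printed TV weights act on
a normalized objective, and conjugate gradient is well preconditioned.
A single global scalar — not per-bin constants — preserves the relative
bin weighting of the printed cost function.

## Self-gating

The navigator takes the first (k-space origin) sample magnitude of every
kz-center readout on all channels, interpolates to a uniform fine grid,
linearly detrends, low-pass filters below the breathing band (Butterworth
order 4, cutoff 0.5 Hz — below the ~1 Hz cardiac fundamental), and takes
the first principal component across channels.  The sign is oriented so
the more densely occupied amplitude extreme — the end-expiration
plateau — is positive, and the result is resampled to the nominal 360 ms
navigator grid.  Degenerate inputs raise: a flat signal (respiratory-band
energy fraction below 0.3) or fewer than two estimated breathing periods.

Respiratory binning is amplitude-based with equal counts (quantile
edges): equal-count bins balance the conditioning of the per-bin
reconstructions, which matters more here than equal amplitude coverage.
The reference bin is the one holding the modal amplitude.  Cardiac phases
come from ECG triggers as per-beat relative phase floor(C·(t−t_i)/RR_i);
readouts outside the trigger span are discarded, and optional RR-outlier
rejection (beats outside ±25% of the median RR) is off by default.  The
"most stable position" subset is the narrowest navigator-amplitude window
containing the requested fraction (default 40%) of readouts, found by an
exhaustive sweep over sorted amplitudes.

## Reconstructions

Stage 1 reconstructs K = 8 (desk tests: 4) cardiac-averaged respiratory
states by minimizing the W-weighted data misfit plus smoothed isotropic
spatial TV and an open-chain temporal TV across amplitude-ordered bins
(respiration is an amplitude axis, not a cycle).  Defaults
lambda_s = 0.05, lambda_t = 1, 10 iterations — this stage only needs to be
good enough for registration.

Deformation fields from the end-expiration reference state to every other
bin are estimated with a self-contained multi-resolution Horn-Schunck
optical flow (3 octaves, 50 Jacobi iterations per level, two warp updates
with increments clipped to ±1 voxel, smoothness weight 0.1 on
median-normalized magnitudes).  On coarse desk grids whose anatomy has
sub-voxel-sharp edges, the flow is estimated on cubically upsampled
images and the field downsampled (`upsample`, default 2 in the
reconstruction config; 3 in the desk tests): interpolation restores the
smooth intensity gradients that brightness-constancy linearization
needs, and turns a flow that *worsened* the inter-bin match into one
that cuts it by 50-80%.  Fields map the reference into each bin
(moving(x+d(x)) ≈ fixed(x)), which is exactly the direction the
reconstruction needs.

Before entering the reconstruction the per-bin flow is post-processed by
vector soft-shrinkage (|d| ← max(0, |d| − 0.3 voxels)) and a light
Gaussian smoothing (0.7 voxels).  The shrinkage zeroes the spurious
sub-voxel displacements that the smoothness prior leaks into static
tissue — warping bright static structures by even a fraction of a voxel
costs more than the correction of an equally small true motion gains —
while genuine organ displacements of one or more voxels pass through
nearly unchanged.  With ground-truth organ-aware fields the
motion-compensated reconstruction clearly outperforms both comparison
arms; shrinkage closes most of the gap between estimated and true
fields.

Warping is a sparse clamped-trilinear interpolation matrix, so its
adjoint is exact and row sums are ≤ 1.

Stage 2 (iMoCo) solves

    argmin_X sum_{n,k,c} || W_{k,c}^(1/2) (F S_n M_k X_c − d_{n,k,c}) ||²
             + lambda_s TV_s(X) + lambda_t TV_t(X)

for C = 25 (desk tests: 8) cardiac phases at end-expiration, with
lambda_s = 0.05, lambda_t = 5 and 15 iterations as defaults; the temporal
TV is cyclic (phase C−1 wraps to 0 — the heartbeat is periodic).  W sits
inside the data norm exactly as written.  The solver is Fletcher-Reeves
nonlinear conjugate gradient with restarts every 5 iterations, a
data-curvature-seeded Armijo backtracking line search, and smoothed-TV
epsilon of 1e-6 of the initial adjoint's maximum; only non-increasing
steps are accepted, so the objective trace is non-increasing by
construction.  Initialization is the density-compensated motion-averaged
adjoint.  Empty (k, c) cells contribute nothing.  The respiratory-averaged
and end-expiration-40% comparison arms run the identical solver without
motion operators; with one bin and a zero field the motion-compensated
path reduces to that plain path to machine precision.

## Desk-scale study conditions

The reconstruction tests run a scaled-down protocol chosen once:
32×32×24 grid at (8, 8, 10) mm voxels, 8-interleave spiral at 21 angles,
24 partitions, 16 s of data (3 555 readouts; per cardiac-respiratory cell
roughly 20% of the (partition, angle) pairs, mirroring the strongly
undersampled per-cell regime of the full protocol), 6 coils compressed to
4, K = 4, C = 8, complex noise 1.5%.  The comparison of reconstruction
arms is evaluated over the moving organs (heart, liver, abdomen), the
region where respiratory motion and its correction act — mirroring the
cardiac-focused regions of interest the method is judged by.  Three
deliberate deviations from pure proportional scaling, each forced by the
coarse grid and documented here:

- the kz density is relatively wider (sigma = 0.25·P instead of 0.135·P)
  so every partition is visited in a short scan — at the full protocol's
  ratio the outer partitions receive a handful of samples across 78k TRs,
  which a 6k-TR desk scan cannot reproduce;
- the breathing amplitude is 28 mm superior-inferior (≈2.8 desk voxels) —
  *conservative* against the ~6 voxels that ~12 mm of breathing spans at
  2 mm resolution, but large enough that motion matters at all on a
  10 mm grid;
- flow upsampling 3 (see above).

What passing desk tests do and do not show: they verify the machinery —
navigator fidelity, binning, operator exactness, descent, registration
accuracy, and that motion compensation recovers a sharper end-expiration
cine than averaging — under translation-dominant breathing with smooth
coils and no off-resonance.  They do not certify in-vivo image quality,
streaking behavior at 2 mm with 18 real coils, fat off-resonance (not
modeled; the full method also omits off-resonance correction), in-flow
contrast (not modeled), or reconstruction wall-times on scanner hardware.

## Numerical choices and degenerate inputs

- NUFFT: oversampling 2.0, kernel width 6; exact sparse adjoints
  throughout (encoding, warping), verified to 1e-6 relative or better.
- TV smoothing constant: 1e-6 of the maximum initial-adjoint magnitude.
- Line search: Armijo c1 = 1e-4, up to 20 halvings from the
  curvature-seeded step; a failed search terminates the solve with the
  trace still non-increasing.
- NaN in the objective aborts with a diagnostic error.
- Degenerate registration inputs (constant images) return a zero field
  with a warning; displacement fields are validated finite and bounded
  (default 20 voxels).
- Empty respiratory bins raise in stage 1 (reduce K); empty (k, c) cells
  in stage 2 are skipped with zero contribution.
- Sampling schedules validate the navigator-window guarantee and raise
  when the requested density cannot satisfy it.

## Known limitations

- The simulator and reconstruction share the encoding operator (inverse
  crime); the oversampled-rendering option and added noise soften but do
  not remove this.
- Respiratory motion is piecewise bulk translation with lung inflation;
  no intra-organ deformation, no sliding-interface modeling beyond what
  the smooth flow can express, no hysteresis.
- No off-resonance, concomitant-field, fat chemical shift, or in-flow
  effects.
- The Horn-Schunck flow is accurate to a few tenths of a voxel for the
  motions tested; diffeomorphic consistency and field invertibility are
  not guaranteed and not needed (only forward warps enter the model).
- Apparent SNR/CNR at desk scale are not comparable in magnitude to
  human-study values; only orderings and mechanisms transfer.
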