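# cineimoco

Free-breathing, ECG-gated 3D cardiac cine imaging with a stack-of-spirals
acquisition and a 4D motion-compensated iterative reconstruction — built
end to end at desk scale, with a synthetic beating/breathing multi-coil
phantom as ground truth.

## Who this is for

Researchers in non-Cartesian cardiac MR reconstruction who want a
self-contained, testable implementation of the full chain: trajectory and
slice-ordering design, DC self-gating, retrospective cardiac/respiratory
binning, respiratory-resolved total-variation reconstruction, optical-flow
registration, and the motion-compensated ("iMoCo") solve — without scanner
hardware or raw patient data.

## The method

A balanced-SSFP stack-of-spirals acquisition fills 3D k-space with one
variable-density spiral readout per TR (4.5 ms) at a slice-encode
partition `kz` and an in-plane rotation.  Three per-TR orderings are
implemented; the preferred one rotates by the quantized tiny golden angle
psi_4 = 180/(tau+3) ≈ 39.3° every TR and draws `kz` from a Gaussian
density (sigma = 10.8 of 80 partitions), which concentrates samples at the
k-space center: after retrospective sorting into 25 cardiac phases, the
central partition holds ~62% of the rotation angles per phase versus ~28%
for constant-density orderings.

Respiration is self-gated from the k-space-origin ("DC") samples of the
kz-center readouts.  The data are binned into K = 8 respiratory amplitude
bins (equal counts) and C = 25 cardiac phases, a respiratory-resolved
cardiac-averaged image per bin is reconstructed with spatio-temporal TV,
deformation fields M_k to the end-expiration state are estimated with
multi-resolution Horn–Schunck optical flow, and the final cine solves

    argmin_X  Σ_{n,k,c} ‖ W_{k,c}^{1/2} (F S_n M_k X_c − d_{n,k,c}) ‖²
              + λ_s TV_s(X) + λ_t TV_t(X)

(λ_s = 0.05, λ_t = 5, 15 nonlinear-CG iterations) so that 100% of the
data, from every respiratory position, reconstructs a single
end-expiration cardiac-resolved volume series X.  Here F is the
stack-of-spirals non-uniform Fourier transform, S_n the coil
sensitivities, W the density-compensation weights, TV_s/TV_t smoothed
spatial and cyclic-temporal total variation.

## Worked example

```
$ python examples/compare_sampling_schemes.py
ordering                                   central-partition fill (% of 119 angles/phase)
fixed_angle_constant_kz                     27.7
rotation_per_tr_constant_kz                 27.7
rotation_per_tr_variable_kz                 63.0
```

Each row simulates the full 350 s schedule (77 777 TRs), assigns every TR
a cardiac phase under a stochastic beat model (RR ~ N(1000, 50) ms) and
reports how many of the 119 rotation angles the central kz partition
collects per phase, on average.  The golden-angle + variable-density
ordering fills the k-space center more than twice as densely — fewer
large gaps after cardiac binning, hence less aliasing and better contrast.

`examples/self_gating_demo.py` checks the navigator against the known
breathing waveform (prints `|r| = 0.983`, detected rate 0.238 Hz for a
4 s breathing period) and `examples/imoco_reconstruction_demo.py` runs
the full simulate → gate → register → reconstruct chain:

```
moving-organ NRMSE vs noiseless end-expiration ground truth:
  4D iMoCo (all data, motion-compensated)    0.1652
  respiratory-averaged (all data)            0.1715
  end-expiration only (40% of data)          0.1857
```

Motion compensation recovers the sharpest heart/liver region because it
uses all of the data while mapping every respiratory state to
end-expiration; plain averaging blurs the moving organs and the
end-expiration arm discards 60% of the samples.  A thin CLI wraps the
same calls:
`cineimoco design-schedule`, `cineimoco coverage`, `cineimoco run --out DIR`,
`cineimoco metrics`.

## Layout

- `src/cineimoco/trajectory.py` — spiral design, orderings, coverage
- `src/cineimoco/phantom.py` — dynamic phantom + raw-data simulator
- `src/cineimoco/gating.py` — DC navigator, respiratory/cardiac binning
- `src/cineimoco/operators.py` — NUFFT, sensitivities, coil compression, DCF
- `src/cineimoco/respiratory.py`, `motion.py`, `imoco.py` — the two-stage
  motion-compensated reconstruction
- `src/cineimoco/metrics.py` — aSNR/aCNR, edge sharpness, phantom NRMSE
- `src/cineimoco/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, HDF5/NIfTI
- `docs/methods.md` — models, parameters, numerical choices, limitations
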