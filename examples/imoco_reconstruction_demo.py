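"""Full desk-scale chain: simulate, self-gate, register, reconstruct.

Simulates 16 s of free-breathing stack-of-spirals data on a beating/
breathing phantom, bins it into 4 respiratory states and 8 cardiac
phases from the DC navigator and ECG, reconstructs the respiratory-
resolved volumes, estimates deformation fields to end-expiration, and
runs the motion-compensated (iMoCo) reconstruction plus the two
comparison arms: respiratory-averaged (all data, no motion model) and
end-expiration-only (the most stable 40% of readouts).

Printed NRMSE values compare each cine to the known noiseless
end-expiration ground truth over the moving organs (heart, liver,
abdomen): motion compensation should recover them sharper than
averaging, without discarding data like the end-expiration arm.
Takes a few minutes on one CPU.
"""

import dataclasses

import numpy as np

from cineimoco.trajectory import build_schedule, design_vd_spiral, kz_density_profile
from cineimoco.phantom import (default_phantom, make_coil_maps,
                               reference_cine, simulate_acquisition)
from cineimoco.gating import gate, select_end_expiration
from cineimoco.operators import compress_coils, estimate_sensitivities
from cineimoco.solvers import ReconConfig
from cineimoco.respiratory import reconstruct_respiratory_resolved
from cineimoco.motion import estimate_bin_deformations
from cineimoco.imoco import reconstruct_cine_tv, reconstruct_imoco
from cineimoco.metrics import reconstruction_rmse

GRID, VOX = (32, 32, 24), (8.0, 8.0, 10.0)
K, C = 4, 8

phantom = default_phantom(matrix=GRID, voxel_mm=VOX,
                          resp_amp_si_mm=28.0, resp_amp_ap_mm=10.0)
spiral = design_vd_spiral(256.0, 32, 8, 2.5, 16.0, 180.0, dwell_us=8.0)
schedule = build_schedule(
    "rotation_per_tr_variable_kz", 24, 21, 4.5, 16_000.0,
    density=kz_density_profile(24, 6.0), seed=11, max_kz_step=3,
)
coils = make_coil_maps(GRID, 6, seed=1)
raw = simulate_acquisition(phantom, schedule, spiral, coils,
                           noise_sd=0.015, resp_period_s=4.0, seed=7)
comp, _, kept = compress_coils(np.moveaxis(raw.readouts, -1, 0), 4)
raw = dataclasses.replace(
    raw, readouts=np.ascontiguousarray(np.moveaxis(comp, 0, -1)), n_channels=4)
print(f"simulated {raw.n_readouts} readouts; coil compression kept "
      f"{kept:.1%} of energy in 4 virtual channels")

assignment, navigator = gate(raw, K=K, C=C)
smaps = estimate_sensitivities(raw)
config = ReconConfig(K=K, C=C)

stage1 = reconstruct_respiratory_resolved(raw, assignment, smaps, config)
fields = estimate_bin_deformations(stage1.volumes, stage1.reference_bin,
                                   upsample=3)
imoco = reconstruct_imoco(raw, assignment, smaps, fields, config)
respavg = reconstruct_cine_tv(raw, assignment.cardiac_phase, smaps, config)
ee = select_end_expiration(assignment, navigator, raw, 0.4)
endexp = reconstruct_cine_tv(raw, assignment.cardiac_phase, smaps, config,
                             readout_subset=ee)

u = raw.ground_truth["resp_waveform"]
u_ref = np.median(u[assignment.resp_bin == assignment.reference_bin])
rss = np.sqrt((np.abs(coils) ** 2).sum(axis=0))
truth = reference_cine(phantom, C, resp_u=u_ref) * rss[None]

# region where respiratory motion acts: heart, liver and abdomen
x = (np.arange(GRID[0]) - GRID[0] // 2) * VOX[0]
y = (np.arange(GRID[1]) - GRID[1] // 2) * VOX[1]
z = (np.arange(GRID[2]) - GRID[2] // 2) * VOX[2]
X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
organs = (((X + 25) / 49) ** 2 + ((Y + 15) / 49) ** 2 + ((Z - 5) / 62) ** 2 < 1)
organs |= ((X - 40) / 78) ** 2 + (Y / 78) ** 2 + ((Z + 35) / 58) ** 2 < 1
organs |= ((X + 50) / 58) ** 2 + (Y / 65) ** 2 + ((Z + 50) / 52) ** 2 < 1
organs &= np.abs(truth[0]) > 0.1 * np.abs(truth).max()
mm = np.broadcast_to(organs, truth.shape)

print("\nmoving-organ NRMSE vs noiseless end-expiration ground truth:")
for name, rec in [("4D iMoCo (all data, motion-compensated)", imoco),
                  ("respiratory-averaged (all data)", respavg),
                  ("end-expiration only (40% of data)", endexp)]:
    print(f"  {name:42s} {reconstruction_rmse(rec.phases, truth, mask=mm):.4f}")
print("\nlower is better; iMoCo should be sharpest because it uses 100% of"
      "\nthe data while mapping every respiratory state to end-expiration.")
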