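"""Shared fixtures: desk-scale phantom simulations reused across test modules.

The heavy end-to-end chain (simulate -> gate -> stage-1 -> registration ->
motion-compensated reconstruction) is computed once per session and shared.
"""

import dataclasses

import numpy as np
import pytest

from cineimoco.trajectory import (
    build_schedule, design_vd_spiral, kz_density_profile,
)
from cineimoco.phantom import (
    default_phantom, make_coil_maps, simulate_acquisition,
)


# Desk-scale protocol used by the reconstruction tests: a 32x32x24 grid with
# (8, 8, 10) mm voxels, 8-interleave spiral at 21 rotations, 16 s of data.
# The kz density is relatively wider than the full protocol's (sigma/P = 0.25)
# so every partition is visited within the short scan, and the breathing
# amplitude is 2.8 z-voxels -- conservative against the ~6 voxels that 12 mm
# of breathing spans at the full protocol's 2 mm resolution.
DESK = dict(
    grid=(32, 32, 24),
    voxel=(8.0, 8.0, 10.0),
    n_partitions=24,
    sigma=6.0,
    n_angles=21,
    n_interleaves=8,
    duration_ms=16_000.0,
    tr_ms=4.5,
    n_channels=6,
    noise_sd=0.015,
    resp_amp_si=28.0,
    resp_amp_ap=10.0,
    resp_period_s=4.0,
)


@pytest.fixture(scope="session")
def desk_spiral():
    return design_vd_spiral(256.0, 32, DESK["n_interleaves"], 2.5, 16.0,
                            180.0, dwell_us=8.0)


@pytest.fixture(scope="session")
def desk_schedule(desk_spiral):
    density = kz_density_profile(DESK["n_partitions"], DESK["sigma"])
    return build_schedule(
        "rotation_per_tr_variable_kz", DESK["n_partitions"], DESK["n_angles"],
        DESK["tr_ms"], DESK["duration_ms"], density=density, seed=11,
        max_kz_step=3,
    )


@pytest.fixture(scope="session")
def desk_phantom():
    return default_phantom(
        matrix=DESK["grid"], voxel_mm=DESK["voxel"],
        resp_amp_si_mm=DESK["resp_amp_si"], resp_amp_ap_mm=DESK["resp_amp_ap"],
    )


@pytest.fixture(scope="session")
def desk_coils():
    return make_coil_maps(DESK["grid"], DESK["n_channels"], seed=1)


@pytest.fixture(scope="session")
def desk_raw(desk_phantom, desk_schedule, desk_spiral, desk_coils):
    """Breathing/beating desk acquisition, compressed from 6 to 4 channels."""
    from cineimoco.operators import compress_coils

    raw = simulate_acquisition(
        desk_phantom, desk_schedule, desk_spiral, desk_coils,
        noise_sd=DESK["noise_sd"], resp_period_s=DESK["resp_period_s"],
        seed=7,
    )
    comp, _, _ = compress_coils(np.moveaxis(raw.readouts, -1, 0), 4)
    return dataclasses.replace(
        raw, readouts=np.ascontiguousarray(np.moveaxis(comp, 0, -1)),
        n_channels=4,
    )


@pytest.fixture(scope="session")
def desk_gating(desk_raw):
    from cineimoco.gating import gate

    assignment, signal = gate(desk_raw, K=4, C=8)
    return assignment, signal


@pytest.fixture(scope="session")
def desk_smaps(desk_raw):
    from cineimoco.operators import estimate_sensitivities

    return estimate_sensitivities(desk_raw)


@pytest.fixture(scope="session")
def desk_recon_config():
    from cineimoco.solvers import ReconConfig

    return ReconConfig(K=4, C=8, n_iter=15, stage1_n_iter=10)


@pytest.fixture(scope="session")
def desk_stage1(desk_raw, desk_gating, desk_smaps, desk_recon_config):
    from cineimoco.respiratory import reconstruct_respiratory_resolved

    assignment, _ = desk_gating
    return reconstruct_respiratory_resolved(
        desk_raw, assignment, desk_smaps, desk_recon_config
    )


@pytest.fixture(scope="session")
def desk_fields(desk_stage1):
    from cineimoco.motion import estimate_bin_deformations

    return estimate_bin_deformations(
        desk_stage1.volumes, desk_stage1.reference_bin, upsample=3
    )


@pytest.fixture(scope="session")
def desk_imoco(desk_raw, desk_gating, desk_smaps, desk_fields,
               desk_recon_config):
    from cineimoco.imoco import reconstruct_imoco

    assignment, _ = desk_gating
    return reconstruct_imoco(
        desk_raw, assignment, desk_smaps, desk_fields, desk_recon_config
    )


@pytest.fixture(scope="session")
def static_raw():
    """Static phantom (no breathing, no heartbeat), noiseless, band-limited
    rendering -- the configuration under which density-compensated adjoint
    gridding is quantitatively accurate."""
    ph = default_phantom(
        matrix=(32, 32, 16), voxel_mm=(8.0, 8.0, 15.0),
        resp_amp_si_mm=0.0, resp_amp_ap_mm=0.0, ejection_fraction=0.0,
        edge_mm=10.0,
    )
    sp = design_vd_spiral(256.0, 32, 8, 2.5, 16.0, 180.0, dwell_us=8.0)
    density = kz_density_profile(16, 4.0)
    sched = build_schedule(
        "rotation_per_tr_variable_kz", 16, 21, 4.5, 8000.0,
        density=density, seed=5, max_kz_step=3,
    )
    maps = make_coil_maps((32, 32, 16), 4, seed=2)
    raw = simulate_acquisition(ph, sched, sp, maps, noise_sd=0.0, seed=9)
    return ph, raw, maps


def moving_organ_mask(grid=DESK["grid"], voxel=DESK["voxel"]):
    """Voxels of the respiration-displaced organs (heart, liver, abdomen),
    with a 30% margin -- the region where motion and its correction act."""
    nx, ny, nz = grid
    x = (np.arange(nx) - nx // 2) * voxel[0]
    y = (np.arange(ny) - ny // 2) * voxel[1]
    z = (np.arange(nz) - nz // 2) * voxel[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    heart = ((X + 25) / 49) ** 2 + ((Y + 15) / 49) ** 2 + ((Z - 5) / 62) ** 2 < 1
    liver = ((X - 40) / 78) ** 2 + (Y / 78) ** 2 + ((Z + 35) / 58) ** 2 < 1
    abdo = ((X + 50) / 58) ** 2 + (Y / 65) ** 2 + ((Z + 50) / 52) ** 2 < 1
    return heart | liver | abdo


@pytest.fixture(scope="session")
def desk_respavg(desk_raw, desk_gating, desk_smaps, desk_recon_config):
    from cineimoco.imoco import reconstruct_cine_tv

    assignment, _ = desk_gating
    return reconstruct_cine_tv(desk_raw, assignment.cardiac_phase,
                               desk_smaps, desk_recon_config)


@pytest.fixture(scope="session")
def desk_endexp(desk_raw, desk_gating, desk_smaps, desk_recon_config):
    from cineimoco.gating import select_end_expiration
    from cineimoco.imoco import reconstruct_cine_tv

    assignment, signal = desk_gating
    idx = select_end_expiration(assignment, signal, desk_raw, 0.4)
    return reconstruct_cine_tv(desk_raw, assignment.cardiac_phase,
                               desk_smaps, desk_recon_config,
                               readout_subset=idx)
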