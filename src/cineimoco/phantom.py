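"""Analytic beating/breathing phantom and multi-coil raw-data simulator.

The phantom is a set of ellipsoidal tissues (chest wall, liver, left
ventricular myocardium and blood pool, background fat) with balanced-SSFP
steady-state intensities computed from T1/T2 at the protocol's flip angle
and TR.  Cardiac motion is modeled as a smooth periodic contraction of the
LV (blood-pool volume at end-systole is (1-EF) times end-diastole by
construction); respiratory motion as a smooth quasi-periodic bulk
translation with an end-expiration plateau, which is the dominant bulk
component of free breathing and is known exactly for validating
registration and motion-compensated reconstruction.

The simulator renders the phantom at each TR's cardiac/respiratory state
(quantized and cached), applies static coil sensitivities, and samples
stack-of-spirals k-space with the same encoding operator the reconstruction
uses (an inverse-crime setup, acknowledged; rendering can be oversampled to
soften it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

from cineimoco.trajectory import SamplingSchedule, SpiralReadout
from cineimoco.operators import StackOfSpiralsEncoding

__all__ = [
    "TissueEllipsoid",
    "DynamicPhantom",
    "RawAcquisition",
    "bssfp_steady_state",
    "default_phantom",
    "make_coil_maps",
    "render_phantom_frame",
    "simulate_acquisition",
    "simulate_ecg_triggers",
    "respiratory_displacement",
    "cardiac_contraction",
]


def bssfp_steady_state(
    T1_ms: float, T2_ms: float, flip_deg: float, tr_ms: float,
    proton_density: float = 1.0,
) -> float:
    """On-resonance balanced-SSFP steady-state transverse signal.

    ``pd * sin(a) (1 - E1) / (1 - (E1 - E2) cos(a) - E1 E2)`` with
    ``Ei = exp(-TR/Ti)``.
    """
    if min(T1_ms, T2_ms, tr_ms) <= 0:
        raise ValueError("T1, T2 and TR must be positive")
    if not 0.0 <= flip_deg <= 180.0:
        raise ValueError("flip angle must be in [0, 180] degrees")
    if T2_ms > T1_ms:
        warnings.warn("T2 > T1 is unphysical", stacklevel=2)
    a = math.radians(flip_deg)
    e1 = math.exp(-tr_ms / T1_ms)
    e2 = math.exp(-tr_ms / T2_ms)
    return proton_density * math.sin(a) * (1 - e1) / (
        1 - (e1 - e2) * math.cos(a) - e1 * e2
    )


@dataclass
class TissueEllipsoid:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    T1_ms: float
    T2_ms: float
    proton_density: float
    label: str


@dataclass
class DynamicPhantom:
    """Ellipsoid phantom with cardiac contraction and respiratory translation."""

    tissues: list[TissueEllipsoid]
    matrix: tuple[int, int, int]
    voxel_mm: tuple[float, float, float]
    ejection_fraction: float = 0.60
    wall_thickening: float = 0.08      # outer LV axis contraction fraction
    resp_amp_si_mm: float = 12.0       # superior-inferior (z)
    resp_amp_ap_mm: float = 4.0        # anterior-posterior (y)
    lung_inflation: float = 0.10       # lung z semi-axis growth per unit u
    systole_phase: float = 0.35        # fraction of the RR interval
    flip_deg: float = 50.0
    tr_ms: float = 4.5
    edge_mm: float = 2.0               # smooth rasterization edge width

    def __post_init__(self):
        for t in self.tissues:
            if min(t.semi_axes_mm) <= 0:
                raise ValueError(f"non-positive semi-axis in {t.label}")
        if min(self.voxel_mm) <= 0:
            raise ValueError("voxel size must be positive")

    def intensity(self, t: TissueEllipsoid) -> float:
        return bssfp_steady_state(
            t.T1_ms, t.T2_ms, self.flip_deg, self.tr_ms, t.proton_density
        )


def default_phantom(
    matrix=(64, 64, 16), voxel_mm=(4.0, 4.0, 8.0), **kwargs
) -> DynamicPhantom:
    """Thorax-like phantom scaled to the requested grid.

    T1/T2 values are representative of low-field (0.55T) tissue relaxation,
    giving the bright-blood bSSFP contrast the protocol relies on.
    """
    tissues = [
        TissueEllipsoid((0, 0, 0), (120, 90, 220), 180, 110, 0.9, "background fat"),
        TissueEllipsoid((0, 0, 0), (110, 80, 210), 600, 50, 0.8, "chest wall"),
        TissueEllipsoid((48, -5, 40), (52, 55, 75), 1300, 20, 0.05, "lung"),
        TissueEllipsoid((-52, -5, 40), (45, 50, 65), 1300, 20, 0.05, "lung"),
        TissueEllipsoid((40, 0, -35), (60, 60, 45), 450, 50, 0.9, "liver"),
        TissueEllipsoid((-50, 0, -50), (45, 50, 40), 750, 55, 0.85, "abdomen"),
        TissueEllipsoid((-25, -15, 5), (38, 38, 48), 700, 60, 0.85, "myocardium"),
        TissueEllipsoid((-25, -15, 5), (26, 26, 36), 1120, 260, 1.0, "blood"),
    ]
    return DynamicPhantom(
        tissues=tissues, matrix=tuple(matrix), voxel_mm=tuple(voxel_mm), **kwargs
    )


def cardiac_contraction(phase_fraction, systole_phase=0.35, relax_end=0.70):
    """Smooth periodic contraction in [0, 1].

    Exactly 0 at end-diastole (phase 0, and through late diastasis beyond
    ``relax_end``), exactly 1 at end-systole (``systole_phase``), with C1
    smoothstep ramps for contraction and relaxation.
    """
    f = np.mod(np.asarray(phase_fraction, dtype=float), 1.0)
    c = np.zeros_like(f)
    up = f < systole_phase
    c[up] = _smoothstep(f[up] / systole_phase)
    down = (f >= systole_phase) & (f < relax_end)
    c[down] = 1.0 - _smoothstep(
        (f[down] - systole_phase) / (relax_end - systole_phase)
    )
    if np.ndim(phase_fraction) == 0:
        return float(c)
    return c


def respiratory_displacement(
    t_ms, period_s: float = 4.0, exponent: int = 2,
    asymmetry: float = 0.35,
    depth_variability: float = 0.3, variability_period_s: float = 23.0,
    drift_mm_per_min: float = 0.0,
):
    """Normalized inspiration waveform u(t) in [0, 1] plus optional drift.

    The cycle is the standard even-power breathing model
    ``u = env(t) cos(theta)**exponent`` with a time-asymmetric phase
    ``theta(t) = pi t/T + (asymmetry/2) sin(2 pi t/T)``: inspiration is
    brisk and the expiratory pause long (about a 3:1 dwell ratio at the
    default asymmetry 0.5), so end-expiration (u = 0) is the most occupied
    position, as in real breathing.  The slowly varying envelope ``env``
    modulates the breath depth cycle to cycle (default +/-15% about 0.85 of
    full depth), the familiar irregularity of free breathing:
    end-expiration is the one reproducible position (and hence the modal
    navigator amplitude), while the inspiration excursions wander.
    Returns u (unitless); multiply by the phantom amplitudes for mm.
    """
    t = np.asarray(t_ms, dtype=float)
    env = 1.0 - depth_variability * (
        0.5 + 0.5 * np.sin(2.0 * math.pi * t / (variability_period_s * 1000.0))
    )
    omega_t = math.pi * t / (period_s * 1000.0)
    theta = omega_t + 0.5 * asymmetry * np.sin(2.0 * omega_t)
    u = env * np.cos(theta) ** exponent
    if drift_mm_per_min:
        u = u + drift_mm_per_min * (t / 60000.0)
    return u


def _smoothstep(x):
    """C1 ramp 0->1 on x in [0,1]."""
    y = np.clip(x, 0.0, 1.0)
    return y * y * (3.0 - 2.0 * y)


STATIC_LABELS = frozenset({"background fat", "chest wall", "lung"})


def render_phantom_frame(
    phantom: DynamicPhantom,
    cardiac_phase_fraction: float = 0.0,
    respiratory_displacement_mm: tuple[float, float, float] | float = 0.0,
    respiratory_u: float | None = None,
) -> np.ndarray:
    """Rasterize the phantom at one motion state onto its grid (complex).

    The LV blood ellipsoid's semi-axes scale as (1 - EF*c)^(1/3) with the
    contraction c; the myocardial outer shell contracts by the wall
    thickening fraction.  The heart and liver translate by the respiratory
    displacement over the static chest wall and lungs; the lungs inflate
    mildly with inspiration (``respiratory_u``, derived from the
    displacement amplitude when not given).  The moving diaphragm (liver
    over lung) is what modulates the k-space center and drives self-gating.
    """
    if not 0.0 <= cardiac_phase_fraction < 1.0 + 1e-9:
        raise ValueError("cardiac_phase_fraction must be in [0, 1)")
    if np.isscalar(respiratory_displacement_mm):
        disp = np.array([0.0, 0.0, float(respiratory_displacement_mm)])
    else:
        disp = np.asarray(respiratory_displacement_mm, dtype=float)
    if respiratory_u is None:
        amp = math.hypot(phantom.resp_amp_ap_mm, phantom.resp_amp_si_mm)
        respiratory_u = float(np.linalg.norm(disp) / amp) if amp > 0 else 0.0

    nx, ny, nz = phantom.matrix
    vx, vy, vz = phantom.voxel_mm
    x = (np.arange(nx) - nx // 2) * vx
    y = (np.arange(ny) - ny // 2) * vy
    z = (np.arange(nz) - nz // 2) * vz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    c = float(cardiac_contraction(cardiac_phase_fraction, phantom.systole_phase))
    blood_scale = (1.0 - phantom.ejection_fraction * c) ** (1.0 / 3.0)
    myo_scale = 1.0 - phantom.wall_thickening * c

    img = np.zeros((nx, ny, nz), dtype=float)
    for t in phantom.tissues:
        ax = np.array(t.semi_axes_mm, dtype=float)
        if t.label == "blood":
            ax = ax * blood_scale
        elif t.label == "myocardium":
            ax = ax * myo_scale
        elif t.label == "lung":
            ax = ax * np.array(
                [1.0, 1.0, 1.0 + phantom.lung_inflation * respiratory_u]
            )
        ctr = np.array(t.center_mm, dtype=float)
        if t.label not in STATIC_LABELS:
            ctr = ctr + disp
        q = np.sqrt(
            ((X - ctr[0]) / ax[0]) ** 2
            + ((Y - ctr[1]) / ax[1]) ** 2
            + ((Z - ctr[2]) / ax[2]) ** 2
        )
        # convert the normalized level q to an approximate mm distance
        a_eff = float(np.mean(ax))
        w = _smoothstep((1.0 - q) * a_eff / phantom.edge_mm + 0.5)
        img = img * (1.0 - w) + w * phantom.intensity(t)
    return img.astype(complex)


def make_coil_maps(
    matrix: tuple[int, int, int], n_channels: int = 8, seed: int = 0
) -> np.ndarray:
    """Smooth complex coil sensitivities: Gaussian lobes on a ring around
    the body with gentle linear phase ramps (n_channels, nx, ny, nz)."""
    nx, ny, nz = matrix
    rng = np.random.default_rng(seed)
    xs = np.linspace(-0.5, 0.5, nx)
    ys = np.linspace(-0.5, 0.5, ny)
    zs = np.linspace(-0.5, 0.5, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    maps = np.empty((n_channels, nx, ny, nz), dtype=complex)
    for n in range(n_channels):
        phi = 2.0 * math.pi * n / n_channels
        cx, cy = 0.55 * math.cos(phi), 0.55 * math.sin(phi)
        cz = 0.3 * math.sin(2.0 * phi) + 0.1 * rng.standard_normal()
        sigma = 0.45
        amp = np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2 + 0.5 * (Z - cz) ** 2)
            / (2 * sigma**2)
        )
        ramp = 2.0 * math.pi * (
            0.3 * rng.standard_normal() * X
            + 0.3 * rng.standard_normal() * Y
            + 0.2 * rng.standard_normal() * Z
        )
        maps[n] = amp * np.exp(1j * (phi + ramp))
    # normalize so the RSS is O(1) over the FOV
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss.max()
    return maps


def simulate_ecg_triggers(
    duration_ms: float, rr_mean_ms: float = 1000.0, rr_sd_ms: float = 50.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Beat-trigger times with per-beat RR ~ N(mean, sd), truncated at 4 sd."""
    if rng is None:
        rng = np.random.default_rng()
    times = [0.0]
    while times[-1] < duration_ms:
        rr = rng.normal(rr_mean_ms, rr_sd_ms)
        rr = float(np.clip(rr, rr_mean_ms - 4 * rr_sd_ms, rr_mean_ms + 4 * rr_sd_ms))
        times.append(times[-1] + max(rr, 1.0))
    return np.array(times)


@dataclass
class RawAcquisition:
    """Multi-channel raw stack-of-spirals data with timing and ground truth."""

    readouts: np.ndarray          # (n_readouts, n_samples, n_channels) complex
    timestamps: np.ndarray        # ms
    schedule: SamplingSchedule
    spiral: SpiralReadout
    ecg_triggers: np.ndarray      # ms
    n_channels: int
    grid_shape: tuple[int, int, int]
    ground_truth: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.readouts.shape[0] != len(self.schedule):
            raise ValueError("readout count must equal schedule length")
        if not np.allclose(self.timestamps, self.schedule.times):
            raise ValueError("timestamps must match schedule times")

    @property
    def n_readouts(self) -> int:
        return self.readouts.shape[0]


def simulate_acquisition(
    phantom: DynamicPhantom,
    schedule: SamplingSchedule,
    spiral: SpiralReadout,
    coil_maps: np.ndarray,
    noise_sd: float = 0.0,
    rr_mean_ms: float = 1000.0,
    rr_sd_ms: float = 50.0,
    resp_period_s: float = 4.0,
    resp_drift_mm_per_min: float = 0.0,
    seed: int | None = None,
    n_resp_levels: int = 32,
    n_cardiac_levels: int = 24,
    oversample_render: int = 1,
) -> RawAcquisition:
    """Simulate the full free-breathing acquisition along a schedule.

    Motion states are quantized to ``n_resp_levels`` x ``n_cardiac_levels``
    rendered frames (cached), each multiplied by the coil maps and sampled
    at its readouts' (kz, angle) spiral coordinates.  Complex
    circularly-symmetric noise with per-component standard deviation
    ``noise_sd`` is added.  Identical seeds give identical output.
    """
    if coil_maps.shape[1:] != tuple(phantom.matrix):
        raise ValueError("coil maps must cover the phantom grid")
    rng = np.random.default_rng(seed)
    n_ch = coil_maps.shape[0]
    times = schedule.times
    duration = float(times[-1]) + schedule.tr

    triggers = simulate_ecg_triggers(duration, rr_mean_ms, rr_sd_ms, rng)
    beat = np.clip(np.searchsorted(triggers, times, side="right") - 1, 0, None)
    rr = np.diff(triggers)
    frac = (times - triggers[beat]) / rr[np.minimum(beat, rr.size - 1)]
    frac = np.clip(frac, 0.0, 1.0 - 1e-9)

    u = respiratory_displacement(
        times, period_s=resp_period_s, drift_mm_per_min=resp_drift_mm_per_min
    )
    u_range = max(float(u.max() - u.min()), 1e-12)

    # quantize motion to a cache of rendered frames
    if phantom.resp_amp_si_mm == 0 and phantom.resp_amp_ap_mm == 0:
        ri = np.zeros(len(times), dtype=int)
        r_levels = np.array([0.0])
    else:
        r_levels = np.linspace(u.min(), u.max(), n_resp_levels)
        ri = np.clip(
            np.round((u - u.min()) / u_range * (n_resp_levels - 1)).astype(int),
            0, n_resp_levels - 1,
        )
    c_levels = (np.arange(n_cardiac_levels) + 0.5) / n_cardiac_levels
    ci = np.clip(
        np.floor(frac * n_cardiac_levels).astype(int), 0, n_cardiac_levels - 1
    )

    state = ri * n_cardiac_levels + ci
    data = np.empty(
        (len(times), spiral.n_samples, n_ch), dtype=complex
    )
    nufft_cache: dict = {}
    angles = np.arange(schedule.n_angles) * 360.0 / schedule.n_angles
    disp_per_readout = np.zeros((len(times), 3))
    disp_per_readout[:, 1] = phantom.resp_amp_ap_mm * u
    disp_per_readout[:, 2] = phantom.resp_amp_si_mm * u

    for s in np.unique(state):
        idx = np.nonzero(state == s)[0]
        r_lev = r_levels[s // n_cardiac_levels]
        c_lev = c_levels[s % n_cardiac_levels]
        disp = (
            0.0,
            phantom.resp_amp_ap_mm * r_lev,
            phantom.resp_amp_si_mm * r_lev,
        )
        frame = _render_maybe_oversampled(
            phantom, c_lev, disp, oversample_render, resp_u=max(float(r_lev), 0.0)
        )
        op = StackOfSpiralsEncoding(
            phantom.matrix, spiral, angles,
            schedule.kz_index[idx], schedule.angle_index[idx],
            nufft_cache=nufft_cache,
        )
        for n in range(n_ch):
            data[idx, :, n] = op.forward(coil_maps[n] * frame)

    if noise_sd > 0:
        data += noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    gt = {
        "resp_waveform": u,
        "resp_displacement_mm": disp_per_readout,
        "cardiac_fraction": frac,
        "triggers_ms": triggers,
        "coil_maps": coil_maps,
        "resp_levels": r_levels,
        "resp_level_index": ri,
    }
    return RawAcquisition(
        readouts=data,
        timestamps=times.copy(),
        schedule=schedule,
        spiral=spiral,
        ecg_triggers=triggers,
        n_channels=n_ch,
        grid_shape=tuple(phantom.matrix),
        ground_truth=gt,
        seed=seed,
    )


def _render_maybe_oversampled(phantom, c_lev, disp, factor, resp_u=None):
    if factor <= 1:
        return render_phantom_frame(phantom, c_lev, disp, respiratory_u=resp_u)
    import dataclasses

    hi = dataclasses.replace(
        phantom,
        matrix=tuple(m * factor for m in phantom.matrix),
        voxel_mm=tuple(v / factor for v in phantom.voxel_mm),
        tissues=phantom.tissues,
    )
    frame = render_phantom_frame(hi, c_lev, disp, respiratory_u=resp_u)
    # box-average back to the acquisition grid
    nx, ny, nz = phantom.matrix
    return frame.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))


def reference_cine(
    phantom: DynamicPhantom, n_phases: int, resp_u: float = 0.0
) -> np.ndarray:
    """Noiseless ground-truth cine at a fixed respiratory position:
    (n_phases, nx, ny, nz) magnitudes at cardiac phase centers."""
    disp = (
        0.0,
        phantom.resp_amp_ap_mm * resp_u,
        phantom.resp_amp_si_mm * resp_u,
    )
    frames = [
        render_phantom_frame(
            phantom, (c + 0.5) / n_phases, disp, respiratory_u=resp_u
        )
        for c in range(n_phases)
    ]
    return np.stack(frames, axis=0)
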