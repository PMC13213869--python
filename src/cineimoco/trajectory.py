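"""Stack-of-spirals acquisition design.

Variable-density spiral readouts, tiny-golden-angle rotation schedules, and
the three slice-encoding (kz) orderings compared in this package: a fixed
angle per slice loop, a rotation every TR with a linear kz sweep, and a
rotation every TR with a Gaussian variable-density kz distribution.  A
coverage analysis quantifies how densely each ordering fills the center of
k-space once readouts are sorted retrospectively into cardiac phases.

Units: k-space coordinates are in cycles per field-of-view, gradients in
mT/m, slew in mT/m/ms, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "SpiralReadout",
    "SamplingSchedule",
    "KzDensity",
    "CoverageReport",
    "GOLDEN_RATIO",
    "GAMMA_KHZ_PER_MT",
    "tiny_golden_angle",
    "pseudo_rotation_increment",
    "kz_density_profile",
    "design_vd_spiral",
    "build_schedule",
    "coverage_report",
    "InfeasibleTrajectoryError",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

#: Gyromagnetic ratio of 1H in kHz/mT (== MHz/T).
GAMMA_KHZ_PER_MT = 42.5774785

SCHEME_FIXED = "fixed_angle_constant_kz"
SCHEME_PER_TR = "rotation_per_tr_constant_kz"
SCHEME_VARIABLE = "rotation_per_tr_variable_kz"
SCHEMES = (SCHEME_FIXED, SCHEME_PER_TR, SCHEME_VARIABLE)


class InfeasibleTrajectoryError(ValueError):
    """Raised when a spiral readout cannot reach k_max under the limits."""


@dataclass
class SpiralReadout:
    """A single spiral-out readout.

    ``k_coords`` holds the per-sample in-plane k-space position in cycles
    per FOV; ``gradient_waveform`` the gradient in mT/m that produces it.
    """

    n_samples: int
    dwell_time: float            # ms
    k_coords: np.ndarray         # (n_samples, 2) cycles/FOV
    gradient_waveform: np.ndarray  # (n_samples, 2) mT/m
    readout_duration: float      # ms
    k_max: float                 # cycles/FOV (matrix/2)
    fov_mm: float
    n_interleaves: int

    def radius(self) -> np.ndarray:
        return np.hypot(self.k_coords[:, 0], self.k_coords[:, 1])

    def rotated(self, angle_deg: float) -> np.ndarray:
        """k-space coordinates of this readout rotated by ``angle_deg``."""
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, -s], [s, c]])
        return self.k_coords @ rot.T


@dataclass
class KzDensity:
    """Discrete sampling density over slice-encode partitions."""

    probabilities: np.ndarray
    sigma: float  # partitions; inf encodes the uniform profile

    @property
    def n_partitions(self) -> int:
        return self.probabilities.size


@dataclass
class SamplingSchedule:
    """Per-TR acquisition order: which partition and rotation at each time."""

    times: np.ndarray        # ms, strictly increasing by tr
    kz_index: np.ndarray     # int in [0, n_partitions)
    angle_index: np.ndarray  # int in [0, n_angles)
    is_dc_navigator: np.ndarray  # bool; kz-center readouts
    tr: float
    n_partitions: int
    n_angles: int
    scheme: str
    rotation_increment_deg: float = 0.0
    seed: int | None = None

    def __len__(self) -> int:
        return self.times.size

    @property
    def center_partition(self) -> int:
        return self.n_partitions // 2

    def to_table(self) -> np.ndarray:
        """(n, 4) float table: time_ms, kz_index, angle_index, nav_flag."""
        return np.column_stack(
            [self.times, self.kz_index, self.angle_index,
             self.is_dc_navigator.astype(float)]
        )

    def save_txt(self, path) -> None:
        np.savetxt(
            path, self.to_table(), fmt=["%.6f", "%d", "%d", "%d"],
            header=(
                f"tr={self.tr} n_partitions={self.n_partitions} "
                f"n_angles={self.n_angles} scheme={self.scheme} "
                f"rotation_increment_deg={self.rotation_increment_deg}\n"
                "time_ms kz_index angle_index nav_flag"
            ),
        )

    @classmethod
    def load_txt(cls, path) -> "SamplingSchedule":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=") for item in meta if "=" in item)
        tab = np.loadtxt(path, skiprows=2, ndmin=2)
        return cls(
            times=tab[:, 0],
            kz_index=tab[:, 1].astype(int),
            angle_index=tab[:, 2].astype(int),
            is_dc_navigator=tab[:, 3].astype(bool),
            tr=float(kv["tr"]),
            n_partitions=int(kv["n_partitions"]),
            n_angles=int(kv["n_angles"]),
            scheme=kv.get("scheme", SCHEME_VARIABLE),
            rotation_increment_deg=float(kv.get("rotation_increment_deg", 0.0)),
        )


def tiny_golden_angle(order: int) -> float:
    """Return the tiny golden angle psi_N = 180 / (tau + N - 1) in degrees.

    ``order=1`` gives the classic golden angle (111.246 deg); larger orders
    give smaller per-TR rotations that retain near-uniform angular coverage.
    """
    if int(order) != order or order < 1:
        raise ValueError(f"order must be a positive integer, got {order!r}")
    return 180.0 / (GOLDEN_RATIO + order - 1)


def pseudo_rotation_increment(ideal_angle: float, n_angles: int) -> float:
    """Quantize an ideal rotation increment onto the discrete angle grid.

    Every acquired rotation must land on one of ``n_angles`` equispaced
    angles, so the per-TR increment is the integer multiple of
    ``360 / n_angles`` nearest to ``ideal_angle``.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if not 0.0 < ideal_angle < 360.0:
        raise ValueError("ideal_angle must lie in (0, 360)")
    step = round(ideal_angle * n_angles / 360.0)
    return step * 360.0 / n_angles


def rotation_step_count(ideal_angle: float, n_angles: int) -> int:
    """Integer index step on the angle grid corresponding to the increment."""
    return int(round(ideal_angle * n_angles / 360.0))


def kz_density_profile(n_partitions: int, sigma: float) -> KzDensity:
    """Truncated discrete Gaussian over partitions, centered on kz = 0.

    ``sigma`` is in partitions; ``sigma = inf`` returns the uniform profile.
    """
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")
    if not (sigma > 0):
        raise ValueError("sigma must be positive (or inf)")
    if math.isinf(sigma):
        p = np.full(n_partitions, 1.0 / n_partitions)
        return KzDensity(p, sigma)
    center = n_partitions // 2
    idx = np.arange(n_partitions)
    p = np.exp(-((idx - center) ** 2) / (2.0 * sigma**2))
    p /= p.sum()
    return KzDensity(p, sigma)


# ---------------------------------------------------------------------------
# Variable-density spiral design
# ---------------------------------------------------------------------------

def _density_factor(r, r0, k_max, taper_end):
    """Relative sampling density: 1 (Nyquist) inside r0, linear taper after."""
    r = np.asarray(r, dtype=float)
    d = np.ones_like(r)
    outer = r > r0
    if k_max > r0:
        d[outer] = 1.0 + (taper_end - 1.0) * (r[outer] - r0) / (k_max - r0)
    return np.maximum(d, 1e-3)


def design_vd_spiral(
    fov_mm: float,
    matrix: int,
    n_interleaves: int,
    readout_ms: float,
    gmax: float = 16.0,
    smax: float = 180.0,
    density_transition: float = 0.25,
    taper_end: float = 0.25,
    dwell_us: float = 5.0,
) -> SpiralReadout:
    """Design a variable-density spiral-out readout.

    The spiral is Archimedean with a fully (Nyquist-) sampled inner region
    out to ``density_transition * k_max`` and a linear density taper down to
    ``taper_end`` at the k-space edge.  The gradient waveform is found by
    time-optimal path parametrization: the speed along the geometric spiral
    is capped by the gradient amplitude limit and, through the local
    curvature, by the slew-rate limit.

    Raises
    ------
    InfeasibleTrajectoryError
        If k_max cannot be reached within ``readout_ms`` under the limits;
        the message names the binding constraint.
    """
    if n_interleaves < 1:
        raise ValueError("n_interleaves must be >= 1")
    if min(fov_mm, readout_ms, gmax, smax) <= 0:
        raise ValueError("physical parameters must be positive")

    k_max = matrix / 2.0
    r0 = density_transition * k_max
    fov_m = fov_mm * 1e-3

    # speed limits in cycles/FOV per ms (and per ms^2 for slew)
    v_g = GAMMA_KHZ_PER_MT * gmax * fov_m
    a_s = GAMMA_KHZ_PER_MT * smax * fov_m

    # --- geometry: integrate r(theta) with dr/dtheta from the density ------
    dtheta = 2.0 * math.pi / 2000.0
    thetas = [0.0]
    rs = [0.0]
    r = 0.0
    theta = 0.0
    max_steps = 10_000_000
    for _ in range(max_steps):
        drdth = n_interleaves / (2.0 * math.pi * _density_factor(r, r0, k_max, taper_end))
        dr_step = float(drdth) * dtheta
        r += dr_step
        theta += dtheta
        thetas.append(theta)
        rs.append(r)
        # run a few steps past k_max so edge stencils stay interior
        if r >= k_max + 4 * dr_step:
            break
    else:  # pragma: no cover
        raise InfeasibleTrajectoryError("spiral geometry failed to close")
    th = np.array(thetas)
    rr = np.array(rs)

    x = rr * np.cos(th)
    y = rr * np.sin(th)
    dr = np.gradient(rr, th)
    d2r = np.gradient(dr, th)
    ds = np.hypot(rr, dr) * dtheta
    s = np.concatenate([[0.0], np.cumsum(ds[1:])])

    denom = (rr**2 + dr**2) ** 1.5
    kappa = np.abs(rr**2 + 2 * dr**2 - rr * d2r) / np.maximum(denom, 1e-12)
    kappa = np.maximum(kappa, 1e-9)

    # --- time-optimal speed profile (forward pass; spiral-out, no stop) ----
    margin = 0.995
    v_lim = np.minimum(margin * v_g, np.sqrt(margin * a_s / kappa))
    v = np.empty_like(v_lim)
    v[0] = 0.0
    for i in range(1, v.size):
        centr = kappa[i - 1] * v[i - 1] ** 2
        a_t = math.sqrt(max((margin * a_s) ** 2 - centr**2, 1e-12))
        dsi = s[i] - s[i - 1]
        v[i] = min(v_lim[i], math.sqrt(v[i - 1] ** 2 + 2 * a_t * dsi))

    # elapsed time along the path (exact per segment for constant accel)
    vsum = np.maximum(v[1:] + v[:-1], 1e-9)
    t_path = np.concatenate([[0.0], np.cumsum(2.0 * np.diff(s) / vsum)])
    # readout ends where the spiral first reaches k_max (geometry extends past)
    s_end = float(np.interp(k_max, rr, s))
    duration = float(np.interp(s_end, s, t_path))
    if duration > readout_ms:
        frac_g = float(np.mean(v >= margin * v_g * 0.999))
        binding = "gradient amplitude (gmax)" if frac_g > 0.5 else "slew rate (smax)"
        raise InfeasibleTrajectoryError(
            f"cannot reach k_max={k_max:g} cycles/FOV in {readout_ms} ms: "
            f"time-optimal duration is {duration:.3f} ms; binding constraint: {binding}"
        )

    # --- resample at the dwell time ----------------------------------------
    dwell = dwell_us * 1e-3
    if duration / dwell < 32:  # keep short readouts resolved
        dwell = duration / 32
    n_samples = int(math.floor(duration / dwell)) + 1
    # stretch the dwell by <1 sample so the last sample lands exactly on k_max
    dwell = duration / (n_samples - 1)
    t = np.arange(n_samples) * dwell
    s_t = np.interp(t, t_path, s)
    v_t = np.interp(s_t, s, v)
    th_t = np.interp(s_t, s, th)
    r_t = np.interp(s_t, s, rr)
    dr_t = np.interp(s_t, s, dr)
    # unit tangent of the polar curve
    norm = np.hypot(r_t, dr_t)
    tx = (dr_t * np.cos(th_t) - r_t * np.sin(th_t)) / norm
    ty = (dr_t * np.sin(th_t) + r_t * np.cos(th_t)) / norm

    g_scale = GAMMA_KHZ_PER_MT * fov_m  # (cycles/FOV per ms) per (mT/m)
    gx = v_t * tx / g_scale
    gy = v_t * ty / g_scale
    # exact geometric k-space position at each sample time
    kx = r_t * np.cos(th_t)
    ky = r_t * np.sin(th_t)

    return SpiralReadout(
        n_samples=n_samples,
        dwell_time=dwell,
        k_coords=np.column_stack([kx, ky]),
        gradient_waveform=np.column_stack([gx, gy]),
        readout_duration=float(t[-1]),
        k_max=k_max,
        fov_mm=fov_mm,
        n_interleaves=n_interleaves,
    )


# ---------------------------------------------------------------------------
# Acquisition ordering
# ---------------------------------------------------------------------------

def _largest_remainder_quota(probabilities: np.ndarray, n: int) -> np.ndarray:
    """Integer counts per partition summing to n (largest-remainder rule)."""
    exact = probabilities * n
    base = np.floor(exact).astype(int)
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(-(exact - base))
        base[order[:short]] += 1
    return base


def _variable_density_order(
    quota: np.ndarray,
    n_entries: int,
    center: int,
    max_step: int,
    nav_window_trs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Order kz acquisitions under the bounded-step and navigator constraints.

    Constrained random walk: each TR acquires a partition within ``max_step``
    of the previous one, chosen with probability proportional to its
    remaining quota.  Whenever the walk could no longer return to the kz
    center before the current 360 ms navigator window expires, it is forced
    to walk back at full step size.  The forced path (and the rare case of
    an empty in-window candidate set) may acquire a partition whose quota is
    exhausted; the resulting histogram deviates from the quota by at most a
    few counts.
    """
    n_part = quota.size
    remaining = quota.astype(float).copy()
    out = np.empty(n_entries, dtype=int)
    pos = center
    last_nav = 0
    out[0] = center
    remaining[center] -= 1
    for t in range(1, n_entries):
        dist = abs(pos - center)
        trs_home = -(-dist // max_step)  # ceil
        trs_left = (last_nav + nav_window_trs) - t
        if trs_left <= trs_home and dist > 0:
            nxt = pos - int(np.sign(pos - center)) * min(max_step, dist)
        else:
            lo = max(0, pos - max_step)
            hi = min(n_part - 1, pos + max_step)
            cand = np.arange(lo, hi + 1)
            w = np.maximum(remaining[cand], 0.0)
            tot = w.sum()
            if tot > 0:
                nxt = int(rng.choice(cand, p=w / tot))
            else:
                # nothing reachable has quota left: step toward remaining mass
                alive = np.nonzero(remaining > 0)[0]
                if alive.size == 0:
                    nxt = pos
                else:
                    nearest = alive[np.argmin(np.abs(alive - pos))]
                    stepv = int(np.clip(nearest - pos, -max_step, max_step))
                    nxt = pos + stepv
        out[t] = nxt
        remaining[nxt] -= 1
        if nxt == center:
            last_nav = t
        pos = nxt
    return out


def build_schedule(
    scheme: str,
    n_partitions: int,
    n_angles: int,
    tr_ms: float,
    duration_ms: float,
    density: KzDensity | None = None,
    rotation_increment_deg: float | None = None,
    seed: int | None = None,
    max_kz_step: int = 8,
    nav_window_ms: float = 360.0,
) -> SamplingSchedule:
    """Build the per-TR acquisition order for one of the three schemes.

    ``fixed_angle_constant_kz`` sweeps all partitions linearly at a fixed
    rotation, then advances the angle; ``rotation_per_tr_constant_kz`` keeps
    the linear sweep but rotates every TR; ``rotation_per_tr_variable_kz``
    rotates every TR and draws partitions from ``density`` (by
    largest-remainder quota) ordered so consecutive kz steps stay within
    ``max_kz_step`` and the kz center is revisited within every
    ``nav_window_ms`` window.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if duration_ms < tr_ms:
        raise ValueError("duration_ms must be at least one TR")
    if rotation_increment_deg is None:
        rotation_increment_deg = pseudo_rotation_increment(
            tiny_golden_angle(4), n_angles
        )
    n_entries = int(math.floor(duration_ms / tr_ms))
    step = rotation_step_count(rotation_increment_deg, n_angles)
    t_idx = np.arange(n_entries)
    times = t_idx * tr_ms
    center = n_partitions // 2

    if scheme == SCHEME_FIXED:
        kz = t_idx % n_partitions
        angle = (step * (t_idx // n_partitions)) % n_angles
    elif scheme == SCHEME_PER_TR:
        kz = t_idx % n_partitions
        angle = (step * t_idx) % n_angles
    else:
        if density is None:
            raise ValueError("variable-density scheme requires a KzDensity")
        if density.n_partitions != n_partitions:
            raise ValueError(
                f"density has {density.n_partitions} partitions, expected {n_partitions}"
            )
        nav_window_trs = max(1, int(math.floor(nav_window_ms / tr_ms)))
        exp_center_per_window = density.probabilities[center] * nav_window_trs
        if exp_center_per_window < 0.5:
            raise ValueError(
                "navigator guarantee unsatisfiable: expected center-partition "
                f"visits per {nav_window_ms} ms window is {exp_center_per_window:.2f} < 0.5"
            )
        rng = np.random.default_rng(seed)
        quota = _largest_remainder_quota(density.probabilities, n_entries)
        kz = _variable_density_order(
            quota, n_entries, center, max_kz_step, nav_window_trs, rng
        )
        angle = (step * t_idx) % n_angles

    return SamplingSchedule(
        times=times.astype(float),
        kz_index=np.asarray(kz, dtype=int),
        angle_index=np.asarray(angle, dtype=int),
        is_dc_navigator=(np.asarray(kz) == center),
        tr=tr_ms,
        n_partitions=n_partitions,
        n_angles=n_angles,
        scheme=scheme,
        rotation_increment_deg=rotation_increment_deg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Coverage analysis
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Per-cardiac-phase k-space angular coverage of a schedule."""

    fill_fraction: np.ndarray   # (n_phases, n_partitions) distinct-angle fraction
    n_phases: int
    n_partitions: int
    n_angles: int
    center_partition: int
    center_fill_percent: float = field(init=False)

    def __post_init__(self):
        self.center_fill_percent = float(
            100.0 * self.fill_fraction[:, self.center_partition].mean()
        )


def coverage_report(
    schedule: SamplingSchedule, cardiac_phase: np.ndarray, n_phases: int | None = None
) -> CoverageReport:
    """Angular fill per (cardiac phase, partition) after retrospective binning.

    ``cardiac_phase`` labels every schedule entry with a phase index; entries
    labeled ``-1`` (outside the ECG trigger span) are excluded.  The fill for
    a (phase, partition) cell is the fraction of the schedule's distinct
    rotation angles acquired at least once in that cell; the headline
    ``center_fill_percent`` is the mean over phases at the center partition,
    times 100.
    """
    cardiac_phase = np.asarray(cardiac_phase)
    if cardiac_phase.shape[0] != len(schedule):
        raise ValueError("cardiac_phase must label every schedule entry")
    if np.any(np.isnan(cardiac_phase.astype(float))):
        raise ValueError("unlabeled (NaN) entries in cardiac_phase")
    keep = cardiac_phase >= 0
    phases = cardiac_phase[keep].astype(int)
    if n_phases is None:
        n_phases = int(phases.max()) + 1
    kz = schedule.kz_index[keep]
    ang = schedule.angle_index[keep]

    seen = np.zeros(
        (n_phases, schedule.n_partitions, schedule.n_angles), dtype=bool
    )
    seen[phases, kz, ang] = True
    fill = seen.sum(axis=2) / schedule.n_angles
    return CoverageReport(
        fill_fraction=fill,
        n_phases=n_phases,
        n_partitions=schedule.n_partitions,
        n_angles=schedule.n_angles,
        center_partition=schedule.center_partition,
    )
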