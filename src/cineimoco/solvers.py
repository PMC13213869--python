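"""Shared machinery for the iterative reconstructions.

Smoothed total-variation penalties, a nonlinear conjugate-gradient driver
with Armijo backtracking (guaranteed non-increasing objective trace), and
the per-bin encoded-data bundle both reconstruction stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cineimoco.operators import (
    StackOfSpiralsEncoding,
    SensitivityMaps,
    compute_density_weights,
)
from cineimoco.phantom import RawAcquisition

__all__ = ["ReconConfig", "EncodedBins", "smoothed_tv_spatial",
           "smoothed_tv_axis", "ncg_minimize"]


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    ``lambda_s``/``lambda_t``/``n_iter`` are the motion-compensated stage's
    spatial and temporal (cardiac) TV weights and iteration count; the
    stage-1 respiratory-resolved reconstruction has its own, weaker
    settings.  Weights apply to data normalized so the initial adjoint has
    unit maximum magnitude.
    """

    lambda_s: float = 0.05
    lambda_t: float = 5.0
    n_iter: int = 15
    n_channels_keep: int = 12
    K: int = 8
    C: int = 25
    tv_epsilon: float = 1e-6
    stage1_lambda_s: float = 0.05
    stage1_lambda_t: float = 1.0
    stage1_n_iter: int = 10
    flow_upsample: int = 2
    oversamp: float = 2.0
    kernel_width: int = 6
    max_halvings: int = 20


# ---------------------------------------------------------------------------
# Smoothed total variation
# ---------------------------------------------------------------------------

def _fdiff(x, axis):
    """Forward difference with zero at the trailing edge (Neumann)."""
    d = np.zeros_like(x)
    sl = [slice(None)] * x.ndim
    sr = [slice(None)] * x.ndim
    sl[axis] = slice(0, -1)
    sr[axis] = slice(1, None)
    d[tuple(sl)] = x[tuple(sr)] - x[tuple(sl)]
    return d


def _fdiff_adj(d, axis):
    """Exact negative-divergence adjoint of :func:`_fdiff`."""
    out = np.zeros_like(d)
    sl = [slice(None)] * d.ndim
    sr = [slice(None)] * d.ndim
    sl[axis] = slice(0, -1)
    sr[axis] = slice(1, None)
    out[tuple(sr)] += d[tuple(sl)]
    out[tuple(sl)] -= d[tuple(sl)]
    return out


def smoothed_tv_spatial(x: np.ndarray, eps: float):
    """Isotropic smoothed spatial TV over the last three axes.

    Returns (value, Wirtinger gradient d/d(conj x), scaled for use with
    2*Re<g, p> directional derivatives -- i.e. value decreases along -g).
    """
    dx = [_fdiff(x, ax) for ax in (-3, -2, -1)]
    mag = np.sqrt(sum(np.abs(d) ** 2 for d in dx) + eps**2)
    val = float(mag.sum())
    safe = np.maximum(mag, 1e-300)  # eps=0 leaves exact zeros
    grad = np.zeros_like(x)
    for ax, d in zip((-3, -2, -1), dx):
        grad += _fdiff_adj(d / safe, ax)
    return val, 0.5 * grad


def smoothed_tv_axis(x: np.ndarray, eps: float, axis: int = 0,
                     cyclic: bool = True):
    """Smoothed TV along one (temporal) axis, optionally cyclic."""
    if cyclic:
        d = np.roll(x, -1, axis=axis) - x
        mag = np.sqrt(np.abs(d) ** 2 + eps**2)
        val = float(mag.sum())
        g = d / np.maximum(mag, 1e-300)
        grad = np.roll(g, 1, axis=axis) - g
        return val, 0.5 * grad
    d = _fdiff(x, axis)
    mag = np.sqrt(np.abs(d) ** 2 + eps**2)
    val = float(mag.sum())  # includes a constant eps per trailing-edge entry
    grad = _fdiff_adj(d / np.maximum(mag, 1e-300), axis)
    return val, 0.5 * grad


# ---------------------------------------------------------------------------
# Encoded per-bin data
# ---------------------------------------------------------------------------

class EncodedBins:
    """Raw data split into bins, each with its encoding operator and DCF.

    A "bin" is any subset of readouts (a respiratory state, a
    (respiratory, cardiac) cell, or a cardiac phase of a pooled subset).
    All operators share one NUFFT cache.  Data are normalized in place by
    ``normalize()`` so the density-compensated adjoint of the full data has
    unit maximum magnitude.
    """

    def __init__(
        self,
        raw: RawAcquisition,
        groups: list[np.ndarray],
        smaps: SensitivityMaps,
        config: ReconConfig,
        grid_shape: tuple[int, int, int] | None = None,
        calib_groups: list[list[int]] | None = None,
    ):
        self.smaps = smaps
        self.config = config
        self.grid_shape = tuple(grid_shape or raw.grid_shape)
        sched = raw.schedule
        angles = np.arange(sched.n_angles) * 360.0 / sched.n_angles
        cache: dict = {}
        self.bins = []
        for idx in groups:
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                self.bins.append(None)
                continue
            op = StackOfSpiralsEncoding(
                self.grid_shape, raw.spiral, angles,
                sched.kz_index[idx], sched.angle_index[idx],
                oversamp=config.oversamp, width=config.kernel_width,
                nufft_cache=cache,
            )
            w = compute_density_weights(
                sched.kz_index[idx], sched.angle_index[idx], raw.spiral
            ).dense()
            d = np.ascontiguousarray(np.moveaxis(raw.readouts[idx], -1, 0))
            self.bins.append({"idx": idx, "op": op, "w": w, "d": d.astype(complex)})
        self.scale = 1.0
        if calib_groups is None:
            calib_groups = [[b] for b in range(len(self.bins))]
        self._calibrate_weights(calib_groups)

    def _calibrate_weights(self, calib_groups: list[list[int]]) -> None:
        """Scale the weights so each calibration group's normal operator is
        approximately the identity.

        Density compensation is only defined up to a scalar per sampling
        geometry; fixing that scalar so that S^H F^H W F S ~= I makes the
        density-compensated adjoint quantitative, puts the printed TV
        weights on a normalized objective, and preconditions conjugate
        gradient.  The scalar is the pooled Rayleigh quotient of the
        normal operator over the group's adjoint images; pooling related
        bins (e.g. the cardiac cells of one respiratory state) stabilizes
        the estimate when individual cells hold few readouts.
        """
        for group in calib_groups:
            num = 0.0
            den = 0.0
            for b in group:
                bin_ = self.bins[b]
                if bin_ is None:
                    continue
                op, w, d = bin_["op"], bin_["w"], bin_["d"]
                v = np.sum(
                    np.conj(self.smaps.maps) * op.adjoint(w[None] * d), axis=0
                )
                nv = float(np.vdot(v, v).real)
                if nv <= 0:
                    continue
                av = op.forward(self.smaps.maps * v[None])
                y = np.sum(
                    np.conj(self.smaps.maps) * op.adjoint(w[None] * av), axis=0
                )
                num += float(np.vdot(v, y).real)
                den += nv
            if den > 0 and num > 0:
                c = num / den
                for b in group:
                    if self.bins[b] is not None:
                        self.bins[b]["w"] = self.bins[b]["w"] / c

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def adjoint_dc(self, b: int) -> np.ndarray:
        """Density-compensated adjoint of one bin's data (coil-combined)."""
        bin_ = self.bins[b]
        if bin_ is None:
            return np.zeros(self.grid_shape, dtype=complex)
        adj = bin_["op"].adjoint(bin_["w"] * bin_["d"])
        return np.sum(np.conj(self.smaps.maps) * adj, axis=0)

    def normalize(self, reference: np.ndarray) -> float:
        """Scale all data by 1/max|reference| and return the scale."""
        s = float(np.abs(reference).max())
        if s <= 0:
            return 1.0
        for bin_ in self.bins:
            if bin_ is not None:
                bin_["d"] /= s
        self.scale = s
        return s

    def residual_norm2_and_grad(self, b: int, vol: np.ndarray):
        """||W^(1/2)(F S vol - d_b)||^2 and its Wirtinger gradient wrt vol."""
        bin_ = self.bins[b]
        if bin_ is None:
            return 0.0, np.zeros(self.grid_shape, dtype=complex)
        op, w, d = bin_["op"], bin_["w"], bin_["d"]
        r = op.forward(self.smaps.maps * vol[None]) - d
        val = float(np.sum(w[None] * np.abs(r) ** 2))
        adj = op.adjoint(w[None] * r)
        grad = np.sum(np.conj(self.smaps.maps) * adj, axis=0)
        return val, grad

    def residual_norm2(self, b: int, vol: np.ndarray) -> float:
        bin_ = self.bins[b]
        if bin_ is None:
            return 0.0
        op, w, d = bin_["op"], bin_["w"], bin_["d"]
        r = op.forward(self.smaps.maps * vol[None]) - d
        return float(np.sum(w[None] * np.abs(r) ** 2))

    def forward_norm2(self, b: int, vol: np.ndarray) -> float:
        """||W^(1/2) F S vol||^2 -- curvature estimate for line search."""
        bin_ = self.bins[b]
        if bin_ is None:
            return 0.0
        op, w = bin_["op"], bin_["w"]
        f = op.forward(self.smaps.maps * vol[None])
        return float(np.sum(w[None] * np.abs(f) ** 2))


# ---------------------------------------------------------------------------
# Nonlinear conjugate gradient with Armijo backtracking
# ---------------------------------------------------------------------------

def ncg_minimize(
    fun_grad,
    fun,
    x0: np.ndarray,
    n_iter: int,
    curvature=None,
    restart_every: int = 5,
    c1: float = 1e-4,
    max_halvings: int = 20,
):
    """Fletcher-Reeves NCG for a real objective of a complex array.

    ``fun_grad(x) -> (f, g)`` with g the Wirtinger gradient (directional
    derivative along p is 2 Re<g, p>); ``fun(x) -> f``; ``curvature(p)``
    optionally returns the quadratic data-term curvature ||A p||^2_W used
    to seed the line-search step.  Only strictly non-increasing steps are
    accepted, so the returned trace is non-increasing; the search stops
    early if no decrease is possible.

    Returns (x, trace) where trace[0] is the initial objective.
    """
    x = x0.copy()
    f, g = fun_grad(x)
    if not np.isfinite(f):
        raise RuntimeError("non-finite objective at initialization")
    trace = [f]
    p = -g
    gg = float(np.vdot(g, g).real)
    t_prev = None
    for it in range(n_iter):
        slope = 2.0 * float(np.vdot(g, p).real)
        if slope >= 0:  # not a descent direction: restart on gradient
            p = -g
            slope = -2.0 * gg
        if gg == 0.0 or slope == 0.0:
            trace.append(f)
            continue
        # seed the step from data-term curvature when available
        if curvature is not None:
            q = curvature(p)
            t = -slope / (2.0 * q) if q > 0 else (t_prev or 1.0)
        else:
            t = t_prev if t_prev else 1.0
        accepted = False
        for _ in range(max_halvings):
            fn = fun(x + t * p)
            if np.isnan(fn):
                raise RuntimeError(
                    f"objective became NaN at iteration {it}, step {t:g}"
                )
            if fn <= f + c1 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            trace.append(f)
            break
        x = x + t * p
        t_prev = t
        f_new, g_new = fun_grad(x)
        trace.append(min(f_new, f))
        f = f_new
        gg_new = float(np.vdot(g_new, g_new).real)
        if (it + 1) % restart_every == 0:
            beta = 0.0
        else:
            beta = gg_new / gg if gg > 0 else 0.0
        p = -g_new + beta * p
        g, gg = g_new, gg_new
    return x, np.array(trace)
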