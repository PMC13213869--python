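"""Linear encoding machinery for stack-of-spirals reconstruction.

The encoding model factorizes as a 1D discrete Fourier transform along the
uniformly sampled slice-encode (kz) axis and a 2D non-uniform Fourier
transform (NUFFT) onto the rotated spiral coordinates in-plane, preceded by
multiplication with per-channel coil sensitivities.

The NUFFT is implemented by Kaiser-Bessel gridding on a 2x oversampled grid.
The interpolation step is materialized as a sparse matrix, so the adjoint is
the exact conjugate transpose of the forward operator (the adjoint
dot-product identity holds to machine precision), while accuracy against the
naive discrete Fourier sum is set by the kernel width (default 6, ~1e-5
relative).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter
from scipy.special import i0

from cineimoco.trajectory import SpiralReadout

__all__ = [
    "Nufft2D",
    "StackOfSpiralsEncoding",
    "SensitivityMaps",
    "DensityWeights",
    "apply_encoding",
    "estimate_sensitivities",
    "compress_coils",
    "compute_density_weights",
]


# ---------------------------------------------------------------------------
# Kaiser-Bessel gridding NUFFT
# ---------------------------------------------------------------------------

def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel on |u| <= width/2 (else 0)."""
    u = np.asarray(u, dtype=float)
    inside = np.abs(u) <= width / 2.0
    arg = np.zeros_like(u)
    arg[inside] = beta * np.sqrt(1.0 - (2.0 * u[inside] / width) ** 2)
    out = np.zeros_like(u)
    out[inside] = i0(arg[inside])
    return out


def _kb_deapodization(n: int, m_os: int, width: int, beta: float) -> np.ndarray:
    """Image-space apodization of the KB kernel on the centered n-grid.

    Computed by direct quadrature of the kernel's Fourier integral, which
    sidesteps normalization pitfalls of the closed-form sinh expression.
    """
    nu = 4096
    u = np.linspace(-width / 2.0, width / 2.0, nu)
    phi = _kb_kernel(u, width, beta)
    x = (np.arange(n) - n // 2) / m_os
    cosmat = np.cos(2.0 * np.pi * np.outer(x, u))
    d = np.trapezoid(cosmat * phi, u, axis=1)
    return d


class Nufft2D:
    """Type-2/type-1 NUFFT between a centered Cartesian grid and arbitrary
    in-plane k-space locations (cycles/FOV).

    Forward evaluates ``s(k) = sum_r x(r) exp(-2 pi i k . r / N)`` with the
    image index ``r`` centered on ``N//2``; adjoint is the exact conjugate
    transpose.
    """

    def __init__(
        self,
        grid_shape: tuple[int, int],
        k_coords: np.ndarray,
        oversamp: float = 2.0,
        width: int = 6,
    ):
        nx, ny = grid_shape
        self.grid_shape = (nx, ny)
        self.k_coords = np.asarray(k_coords, dtype=float)
        self.width = width
        self.os = oversamp
        mx, my = int(round(nx * oversamp)), int(round(ny * oversamp))
        self.os_shape = (mx, my)
        # standard Fessler/Beatty beta for the given width and oversampling
        self.beta = math.pi * math.sqrt(
            (width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8
        )
        self._build_interp()
        dx = _kb_deapodization(nx, mx, width, self.beta)
        dy = _kb_deapodization(ny, my, width, self.beta)
        self.deapod = np.outer(dx, dy)

    def _build_interp(self) -> None:
        m = self.k_coords.shape[0]
        mx, my = self.os_shape
        w = self.width
        px = self.os * self.k_coords[:, 0] / (self.os)  # k in cycles/FOV
        # frequency-grid position of each sample on the oversampled grid
        px = self.k_coords[:, 0] * self.os
        py = self.k_coords[:, 1] * self.os
        offs = np.arange(w) - w // 2 + 1
        jx = np.floor(px)[:, None] + offs[None, :]   # (m, w)
        jy = np.floor(py)[:, None] + offs[None, :]
        wx = _kb_kernel(px[:, None] - jx, w, self.beta)
        wy = _kb_kernel(py[:, None] - jy, w, self.beta)
        cols = (
            np.mod(jx[:, :, None], mx) * my + np.mod(jy[:, None, :], my)
        ).reshape(m, -1)
        vals = (wx[:, :, None] * wy[:, None, :]).reshape(m, -1)
        rows = np.repeat(np.arange(m), w * w)
        G = sp.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(m, mx * my)
        )
        self._G = G
        self._GH = G.conj().T.tocsr()

    @property
    def n_samples(self) -> int:
        return self.k_coords.shape[0]

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Image(s) (..., nx, ny) -> samples (..., m)."""
        nx, ny = self.grid_shape
        mx, my = self.os_shape
        lead = img.shape[:-2]
        x = img.reshape(-1, nx, ny) / self.deapod
        pad = np.zeros((x.shape[0], mx, my), dtype=complex)
        ox, oy = mx // 2 - nx // 2, my // 2 - ny // 2
        pad[:, ox:ox + nx, oy:oy + ny] = x
        f = np.fft.fft2(np.fft.ifftshift(pad, axes=(-2, -1)), axes=(-2, -1))
        s = self._G @ f.reshape(x.shape[0], -1).T
        return np.ascontiguousarray(s.T).reshape(*lead, self.n_samples)

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Samples (..., m) -> image(s) (..., nx, ny); exact transpose."""
        nx, ny = self.grid_shape
        mx, my = self.os_shape
        lead = data.shape[:-1]
        s = data.reshape(-1, self.n_samples)
        f = (self._GH @ s.T).T.reshape(-1, mx, my)
        img = np.fft.fftshift(
            np.fft.ifft2(f, axes=(-2, -1)), axes=(-2, -1)
        ) * (mx * my)
        ox, oy = mx // 2 - nx // 2, my // 2 - ny // 2
        out = img[:, ox:ox + nx, oy:oy + ny] / self.deapod
        return np.ascontiguousarray(out).reshape(*lead, nx, ny)


# ---------------------------------------------------------------------------
# z-axis (partition) DFT with centered kz indexing
# ---------------------------------------------------------------------------

def zdft_forward(img: np.ndarray, axis: int = -1) -> np.ndarray:
    """Uniform DFT along the partition axis; kz index 0..P-1, center P//2."""
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(img, axes=axis), axis=axis), axes=axis
    )


def zdft_adjoint(ksp: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exact conjugate transpose of :func:`zdft_forward`."""
    p = ksp.shape[axis]
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(ksp, axes=axis), axis=axis), axes=axis
    ) * p


# ---------------------------------------------------------------------------
# Stack-of-spirals encoding
# ---------------------------------------------------------------------------

class StackOfSpiralsEncoding:
    """Single-channel stack-of-spirals operator for a set of readouts.

    Each readout is described by a (kz partition, rotation angle) pair; all
    readouts share the base spiral.  ``forward`` maps a complex volume
    (nx, ny, nz) to per-readout sample arrays (n_readouts, n_samples);
    ``adjoint`` is the exact conjugate transpose.  Per-angle NUFFT operators
    are cached across instances sharing a spiral and grid.
    """

    def __init__(
        self,
        grid_shape: tuple[int, int, int],
        spiral: SpiralReadout,
        angles_deg: np.ndarray,
        kz_of_readout: np.ndarray,
        angle_of_readout: np.ndarray,
        oversamp: float = 2.0,
        width: int = 6,
        nufft_cache: dict | None = None,
    ):
        self.grid_shape = tuple(grid_shape)
        nx, ny, nz = self.grid_shape
        self.spiral = spiral
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.kz = np.asarray(kz_of_readout, dtype=int)
        self.angle = np.asarray(angle_of_readout, dtype=int)
        if self.kz.max(initial=-1) >= nz:
            raise ValueError("kz index exceeds grid partitions")
        self.n_readouts = self.kz.size
        self.n_samples = spiral.n_samples
        self._cache = nufft_cache if nufft_cache is not None else {}
        self._os = oversamp
        self._width = width
        # group readouts by angle for batched NUFFT application
        self._groups = [
            np.nonzero(self.angle == a)[0]
            for a in range(self.angles_deg.size)
        ]
        # distinct kz planes per angle group: the sparse kernel only ever
        # needs to touch each (angle, kz) pair once per pass
        self._planes = []
        self._inv = []
        self._scatter = []
        for idx in self._groups:
            if idx.size == 0:
                self._planes.append(None)
                self._inv.append(None)
                self._scatter.append(None)
                continue
            pa, inv = np.unique(self.kz[idx], return_inverse=True)
            self._planes.append(pa)
            self._inv.append(inv)
            self._scatter.append(
                sp.csr_matrix(
                    (np.ones(idx.size), (inv, np.arange(idx.size))),
                    shape=(pa.size, idx.size),
                )
            )

    def _nufft(self, a: int) -> Nufft2D:
        key = (id(self.spiral), self.grid_shape[:2], round(self.angles_deg[a], 9))
        if key not in self._cache:
            self._cache[key] = Nufft2D(
                self.grid_shape[:2],
                self.spiral.rotated(self.angles_deg[a]),
                oversamp=self._os,
                width=self._width,
            )
        return self._cache[key]

    def forward(self, img: np.ndarray) -> np.ndarray:
        """(..., nx, ny, nz) -> (..., n_readouts, n_samples).

        The oversampled in-plane FFT is computed once per kz plane (and
        leading batch element, e.g. coil channel); each readout then only
        costs its sparse kernel interpolation.
        """
        nx, ny, nz = self.grid_shape
        lead = img.shape[:-3]
        L = int(np.prod(lead)) if lead else 1
        nf = self._nufft(0)
        mx, my = nf.os_shape
        ksz = zdft_forward(img.reshape((L, nx, ny, nz)), axis=-1)
        x = np.moveaxis(ksz, -1, 1) / nf.deapod            # (L, nz, nx, ny)
        pad = np.zeros((L, nz, mx, my), dtype=complex)
        ox, oy = mx // 2 - nx // 2, my // 2 - ny // 2
        pad[:, :, ox:ox + nx, oy:oy + ny] = x
        F = np.fft.fft2(np.fft.ifftshift(pad, axes=(-2, -1)), axes=(-2, -1))
        F = F.reshape(L, nz, mx * my)
        out = np.empty((L, self.n_readouts, self.n_samples), dtype=complex)
        for a, idx in enumerate(self._groups):
            if idx.size == 0:
                continue
            pa, inv = self._planes[a], self._inv[a]
            planes = F[:, pa, :]                           # (L, |pa|, M)
            s = self._nufft(a)._G @ planes.reshape(-1, mx * my).T
            s = s.T.reshape(L, pa.size, self.n_samples)
            out[:, idx, :] = s[:, inv, :]
        return out.reshape(lead + (self.n_readouts, self.n_samples))

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """(..., n_readouts, n_samples) -> (..., nx, ny, nz); exact transpose."""
        nx, ny, nz = self.grid_shape
        lead = data.shape[:-2]
        L = int(np.prod(lead)) if lead else 1
        nf = self._nufft(0)
        mx, my = nf.os_shape
        d = data.reshape(L, self.n_readouts, self.n_samples)
        acc = np.zeros((L, nz, mx * my), dtype=complex)
        for a, idx in enumerate(self._groups):
            if idx.size == 0:
                continue
            pa = self._planes[a]
            # sum duplicated readouts onto their distinct planes first
            dsum = self._scatter[a] @ d[:, idx, :].transpose(1, 0, 2).reshape(
                idx.size, -1
            )
            dsum = dsum.reshape(pa.size, L, self.n_samples).transpose(1, 0, 2)
            g = self._nufft(a)._GH @ dsum.reshape(-1, self.n_samples).T
            acc[:, pa, :] += g.T.reshape(L, pa.size, mx * my)
        acc = acc.reshape(L, nz, mx, my)
        img = np.fft.fftshift(
            np.fft.ifft2(acc, axes=(-2, -1)), axes=(-2, -1)
        ) * (mx * my)
        ox, oy = mx // 2 - nx // 2, my // 2 - ny // 2
        out = img[:, :, ox:ox + nx, oy:oy + ny] / nf.deapod
        out = zdft_adjoint(np.moveaxis(out, 1, -1), axis=-1)
        return out.reshape(lead + (nx, ny, nz))


# ---------------------------------------------------------------------------
# Coil sensitivities
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMaps:
    """Per-channel complex sensitivity volumes, RSS-normalized inside mask."""

    maps: np.ndarray   # (n_channels, nx, ny, nz) complex
    mask: np.ndarray   # (nx, ny, nz) bool

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


def apply_encoding(
    image: np.ndarray,
    sensitivities: SensitivityMaps | None,
    op: StackOfSpiralsEncoding,
    direction: str = "forward",
):
    """Multi-channel encoding ``F S_n x`` (forward) or its adjoint.

    Forward maps a volume to (n_channels, n_readouts, n_samples); adjoint
    combines channels with conjugate sensitivities.  With ``sensitivities``
    None a single uniform channel is assumed.
    """
    if direction not in ("forward", "adjoint"):
        raise ValueError("direction must be 'forward' or 'adjoint'")
    if sensitivities is None:
        if direction == "forward":
            return op.forward(image)[None]
        return op.adjoint(image[0] if image.ndim == 3 else image)
    if direction == "forward":
        return op.forward(sensitivities.maps * image[None])
    return np.sum(np.conj(sensitivities.maps) * op.adjoint(image), axis=0)


def estimate_sensitivities(
    raw,
    calib_fraction: float = 0.25,
    min_calib_cycles: float = 16.0,
    smooth_vox: float = 0.5,
    mask_threshold: float = 0.15,
    oversamp: float = 2.0,
    width: int = 6,
) -> SensitivityMaps:
    """Estimate coil maps from apodized central k-space.

    Adjoint-grids each channel of the (respiratory-averaged) raw data after
    a Gaussian k-space apodization passing the central ``calib_fraction``
    of k-space -- but never less than ``min_calib_cycles`` cycles/FOV, so
    small desk-scale grids keep enough calibration resolution -- divides by
    the root-sum-of-squares image, smooths, and normalizes so the RSS of
    the maps is 1 inside the support mask.
    """
    sched = raw.schedule
    angles = np.arange(sched.n_angles) * 360.0 / sched.n_angles
    op = StackOfSpiralsEncoding(
        raw.grid_shape, raw.spiral, angles, sched.kz_index, sched.angle_index,
        oversamp=oversamp, width=width,
    )
    data = np.moveaxis(raw.readouts, -1, 0)
    weights = compute_density_weights(
        sched.kz_index, sched.angle_index, raw.spiral, n_angles=sched.n_angles
    )
    n_ch = data.shape[0]
    frac = min(max(calib_fraction, min_calib_cycles / op.spiral.k_max), 1.0)
    r = op.spiral.radius() / op.spiral.k_max
    apod_r = np.exp(-0.5 * (r / (frac / 2.0)) ** 2)
    nz = op.grid_shape[2]
    fz = (op.kz - nz // 2) / max(nz // 2, 1)
    apod_z = np.exp(-0.5 * (fz / (frac / 2.0)) ** 2)
    w = (apod_z[:, None] * apod_r[None, :]) * weights.dense()
    if not np.any(w > 0):
        raise ValueError("empty calibration region")
    low = op.adjoint(w[None] * data)
    rss = np.sqrt((np.abs(low) ** 2).sum(axis=0))
    mask = rss > mask_threshold * rss.max()
    raw_maps = low / np.maximum(rss, 1e-12 * rss.max())
    sm = np.stack(
        [
            gaussian_filter(m.real, smooth_vox) + 1j * gaussian_filter(m.imag, smooth_vox)
            for m in raw_maps
        ],
        axis=0,
    )
    norm = np.sqrt((np.abs(sm) ** 2).sum(axis=0))
    sm = sm / np.maximum(norm, 1e-12)
    sm[:, ~mask] = 0.0
    return SensitivityMaps(maps=sm, mask=mask)


def compress_coils(data: np.ndarray, n_keep: int):
    """PCA coil compression of (n_channels, ...) complex data.

    Returns (compressed data with ``n_keep`` virtual channels, transform
    matrix (n_keep, n_channels), retained-energy fraction).
    """
    n_ch = data.shape[0]
    if not 1 <= n_keep <= n_ch:
        raise ValueError("n_keep must be in [1, n_channels]")
    flat = data.reshape(n_ch, -1)
    cov = flat @ flat.conj().T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    T = evecs[:, order[:n_keep]].conj().T        # (n_keep, n_ch)
    comp = (T @ flat).reshape((n_keep,) + data.shape[1:])
    total = evals.sum()
    retained = float(evals[:n_keep].sum() / total) if total > 0 else 1.0
    return comp, T, retained


# ---------------------------------------------------------------------------
# Density compensation
# ---------------------------------------------------------------------------

@dataclass
class DensityWeights:
    """Separable non-negative sample weights for one (resp, cardiac) bin.

    ``profile`` is the in-plane weight shared by every readout (the local
    k-space area per sample along the spiral, calibrated so that gridding
    the fully rotated set is quantitatively correct, including the
    many-fold overlap of rotations at the spiral origin);
    ``readout_factor`` rescales each readout for the angular density of
    its kz plane within the bin and divides the weight of duplicated
    (kz, angle) acquisitions.
    """

    profile: np.ndarray        # (n_samples,)
    readout_factor: np.ndarray  # (n_readouts,)

    def dense(self) -> np.ndarray:
        return np.outer(self.readout_factor, self.profile)

    def sqrt_dense(self) -> np.ndarray:
        return np.sqrt(self.dense())


def spiral_sample_area(spiral: SpiralReadout) -> np.ndarray:
    """Analytic in-plane k-space area per sample along the spiral.

    Arc length per dwell times the local radial spacing between adjacent
    turns of the full interleave set (1/density; Nyquist spacing is one
    cycle/FOV in the fully sampled inner region).
    """
    k = spiral.k_coords
    ds = np.hypot(*np.gradient(k, axis=0).T)
    r = spiral.radius()
    # infer local turn spacing from the geometry: d|k|/dtheta * 2pi / n_il
    theta = np.unwrap(np.arctan2(k[:, 1], k[:, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        drdth = np.gradient(r) / np.maximum(np.gradient(theta), 1e-12)
    spacing = np.abs(drdth) * 2.0 * np.pi / spiral.n_interleaves
    area = ds * np.maximum(spacing, 1e-12)
    return area


_DCF_PROFILE_CACHE: dict = {}


def inplane_dcf_profile(
    spiral: SpiralReadout, n_angles: int, n_iter: int = 25
) -> np.ndarray:
    """Per-sample in-plane DCF for the fully rotated spiral set.

    Seeded with the analytic area-per-sample and refined by Pipe-Menon
    fixed-point iteration (w <- w / (G G^H w) with the gridding
    interpolator G), which correctly down-weights the n_angles-fold
    overlap of rotations near the k-space origin where the separable
    analytic picture breaks down.  Cached per (spiral, n_angles).
    """
    key = (id(spiral), int(n_angles))
    if key in _DCF_PROFILE_CACHE:
        return _DCF_PROFILE_CACHE[key]
    matrix = int(round(2 * spiral.k_max))
    coords = np.concatenate(
        [spiral.rotated(a * 360.0 / n_angles) for a in range(n_angles)], axis=0
    )
    op = Nufft2D((matrix, matrix), coords)
    w = np.tile(spiral_sample_area(spiral), n_angles).astype(complex)
    for _ in range(n_iter):
        dens = np.real(op._G @ (op._GH @ w))
        w = w / np.maximum(dens, 1e-12 * dens.max())
    # all rotations share the profile: average over the angle copies
    prof = np.real(w).reshape(n_angles, spiral.n_samples).mean(axis=0)
    prof = np.maximum(prof, 0.0)
    _DCF_PROFILE_CACHE[key] = prof
    return prof


def compute_density_weights(
    kz_of_readout: np.ndarray,
    angle_of_readout: np.ndarray,
    spiral: SpiralReadout,
    n_angles: int | None = None,
) -> DensityWeights:
    """Density-compensation weights for one bin's readouts.

    Separable: the in-plane profile of :func:`inplane_dcf_profile` times,
    per readout, (n_angles / angles present in its kz plane) for the
    plane's angular undersampling and 1/count for duplicated (kz, angle)
    acquisitions, normalized to max weight 1 within the bin.
    """
    import warnings

    kz = np.asarray(kz_of_readout, dtype=int)
    ang = np.asarray(angle_of_readout, dtype=int)
    if n_angles is None:
        n_angles = int(ang.max(initial=0)) + 1
    if kz.size == 0:
        warnings.warn("empty bin: zero density weights", stacklevel=2)
        return DensityWeights(
            profile=spiral_sample_area(spiral), readout_factor=np.zeros(0)
        )
    profile = inplane_dcf_profile(spiral, n_angles)
    pair = kz * n_angles + ang
    _, inv, counts = np.unique(pair, return_inverse=True, return_counts=True)
    factor = 1.0 / counts[inv]
    # angular density of each kz plane: distinct angles present
    n_distinct = np.zeros(int(kz.max()) + 1)
    for p in np.unique(kz):
        n_distinct[p] = np.unique(ang[kz == p]).size
    factor = factor * (n_angles / n_distinct[kz])
    w = DensityWeights(profile=profile / max(profile.max(), 1e-300),
                       readout_factor=factor)
    fm = w.readout_factor.max()
    if fm > 0:
        w.readout_factor = w.readout_factor / fm
    return w
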