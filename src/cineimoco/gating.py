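"""Self-gating: respiratory navigator extraction and data binning.

The k-space center ("DC") sample of every kz-center readout is a surrogate
for bulk respiratory motion: as the diaphragm and heart move through the
static coil profiles and displace the low-signal lungs, the net signal
integral seen by each channel changes slowly at the breathing rate.  The
navigator is built from all channels (low-pass + first principal
component), oriented so end-expiration is positive, and used to sort every
readout into K equal-count respiratory amplitude bins.  Cardiac phases come
from ECG trigger times, as per-beat relative phase in C frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, periodogram

from cineimoco.phantom import RawAcquisition

__all__ = [
    "RespiratorySignal",
    "BinAssignment",
    "FlatSignalError",
    "InsufficientDataError",
    "extract_dc_navigator",
    "cardiac_phase_labels",
    "assign_respiratory_bins",
    "assign_cardiac_phases",
    "select_end_expiration",
    "gate",
]


class FlatSignalError(ValueError):
    """Navigator has no usable respiratory variation."""


class InsufficientDataError(ValueError):
    """Acquisition does not span enough respiratory periods."""


@dataclass
class RespiratorySignal:
    """Respiratory navigator; positive amplitudes point to end-expiration.

    ``times``/``amplitudes`` live on the nominal navigator grid (360 ms);
    when available, the pre-resampling fine-grid signal is kept alongside
    and used for interpolation to readout times, avoiding quantization of
    the brisker mid-cycle excursions.
    """

    times: np.ndarray       # ms, strictly increasing
    amplitudes: np.ndarray  # arbitrary units
    nominal_interval: float = 360.0
    fine_times: np.ndarray | None = None
    fine_amplitudes: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("navigator times must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("navigator amplitudes must be finite")

    def interp(self, t: np.ndarray) -> np.ndarray:
        if self.fine_times is not None:
            return np.interp(t, self.fine_times, self.fine_amplitudes)
        return np.interp(t, self.times, self.amplitudes)

    def dominant_frequency_hz(self) -> float:
        dt = float(np.median(np.diff(self.times))) / 1000.0
        f, p = periodogram(self.amplitudes - self.amplitudes.mean(), fs=1.0 / dt)
        return float(f[1:][np.argmax(p[1:])])


@dataclass
class BinAssignment:
    """Per-readout respiratory bin and cardiac phase labels.

    ``cardiac_phase`` is -1 for readouts outside the ECG trigger span
    (discarded downstream).  ``reference_bin`` is the bin holding the modal
    navigator amplitude, i.e. the end-expiration plateau.
    """

    resp_bin: np.ndarray      # int in [0, K)
    cardiac_phase: np.ndarray  # int in [0, C) or -1
    K: int = 8
    C: int = 25
    reference_bin: int = 0

    def __post_init__(self):
        if self.resp_bin.shape != self.cardiac_phase.shape:
            raise ValueError("per-readout label arrays must align")

    @property
    def valid(self) -> np.ndarray:
        return self.cardiac_phase >= 0

    def readouts_in(self, k: int, c: int | None = None) -> np.ndarray:
        sel = self.resp_bin == k
        if c is not None:
            sel &= self.cardiac_phase == c
        else:
            sel &= self.valid
        return np.nonzero(sel)[0]


def extract_dc_navigator(
    raw: RawAcquisition,
    cutoff_hz: float = 0.6,
    nominal_interval_ms: float = 360.0,
    resp_band_hz: tuple[float, float] = (0.05, 0.7),
    band_energy_threshold: float = 0.3,
) -> RespiratorySignal:
    """Respiratory navigator from the kz-center DC samples of all channels.

    Per channel the first (k-space origin) sample magnitude of every
    kz-center readout is linearly detrended, low-pass filtered below the
    breathing band's upper edge, and the first principal component across
    channels is taken as the navigator.  Its sign is oriented so the more
    densely occupied amplitude extreme -- the end-expiration plateau -- is
    positive, and the result is resampled to the nominal 360 ms grid.
    """
    nav = raw.schedule.is_dc_navigator
    if nav.sum() < 8:
        raise InsufficientDataError("too few kz-center readouts for gating")
    tn = raw.timestamps[nav]
    dc = np.abs(raw.readouts[nav, 0, :])      # (n_nav, n_channels)

    # uniform fine grid for filtering
    dt = min(float(np.median(np.diff(tn))), 90.0)
    tg = np.arange(tn[0], tn[-1] + 0.5 * dt, dt)
    chans = np.stack([np.interp(tg, tn, dc[:, n]) for n in range(dc.shape[1])], 1)
    # linear detrend per channel
    A = np.column_stack([tg - tg.mean(), np.ones_like(tg)])
    chans = chans - A @ np.linalg.lstsq(A, chans, rcond=None)[0]

    fs = 1000.0 / dt
    b, a = butter(4, cutoff_hz / (fs / 2.0), btype="low")
    filt = filtfilt(b, a, chans, axis=0)

    # flat-signal guard: respiratory-band energy must dominate
    scale = float(np.abs(dc).mean())
    total = float((chans**2).sum())
    if total <= (1e-8 * scale) ** 2 * chans.size:
        raise FlatSignalError("DC signal variance is numerically zero")
    f, p = periodogram(chans, fs=fs, axis=0)
    band = (f >= resp_band_hz[0]) & (f <= resp_band_hz[1])
    ratio = float(p[band].sum() / max(p[1:].sum(), 1e-300))
    if ratio < band_energy_threshold:
        raise FlatSignalError(
            f"no respiratory-band energy in DC signal (band fraction {ratio:.2f})"
        )

    # first principal component across channels
    u, s, vt = np.linalg.svd(filt, full_matrices=False)
    score = u[:, 0] * s[0]

    # orient: the modal (most occupied) extreme is end-expiration -> positive
    lo, hi = np.quantile(score, [0.25, 0.75])
    span = score.max() - score.min()
    n_top = int((score > score.max() - 0.25 * span).sum())
    n_bot = int((score < score.min() + 0.25 * span).sum())
    if n_bot > n_top:
        score = -score

    # enough periods?
    sig = RespiratorySignal(times=tg, amplitudes=score,
                            nominal_interval=nominal_interval_ms)
    f0 = sig.dominant_frequency_hz()
    n_periods = (tg[-1] - tg[0]) / 1000.0 * f0
    if n_periods < 2.0:
        raise InsufficientDataError(
            f"signal spans only {n_periods:.1f} respiratory periods (<2)"
        )

    # resample to the nominal navigator grid, keeping the fine signal
    t_out = np.arange(tg[0], tg[-1] + 1e-9, nominal_interval_ms)
    return RespiratorySignal(
        times=t_out,
        amplitudes=np.interp(t_out, tg, score),
        nominal_interval=nominal_interval_ms,
        fine_times=tg,
        fine_amplitudes=score,
    )


def assign_respiratory_bins(
    signal: RespiratorySignal, raw: RawAcquisition, K: int = 8
) -> BinAssignment:
    """Equal-count amplitude binning of every readout into K respiratory bins.

    The navigator is interpolated to each readout time; quantile edges give
    bins whose sizes differ by at most one.  Bin indices are ordered by
    amplitude (bin 0 = lowest); the reference bin is the one containing the
    modal amplitude, i.e. the end-expiration plateau.
    """
    n = raw.n_readouts
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds readout count {n}")
    amp = signal.interp(raw.timestamps)
    order = np.argsort(amp, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = (np.arange(n) * K) // n

    # the bins hold equal counts, so the one spanning the narrowest
    # amplitude range has the highest occupancy density: the plateau
    widths = np.array([
        np.ptp(amp[bins == k]) if np.any(bins == k) else np.inf
        for k in range(K)
    ])
    reference = int(np.argmin(widths))
    return BinAssignment(
        resp_bin=bins,
        cardiac_phase=np.full(n, -1, dtype=int),
        K=K,
        C=0,
        reference_bin=reference,
    )


def cardiac_phase_labels(times: np.ndarray, triggers: np.ndarray,
                         C: int = 25) -> np.ndarray:
    """Cardiac phase in [0, C) for arbitrary event times (-1 = outside span).

    An event at time t inside beat [t_i, t_{i+1}) gets phase
    floor(C (t - t_i) / RR_i), clamped to C-1.
    """
    trig = np.asarray(triggers, dtype=float)
    if trig.size < 2:
        raise ValueError("need at least two ECG triggers")
    t = np.asarray(times, dtype=float)
    beat = np.searchsorted(trig, t, side="right") - 1
    phase = np.full(t.size, -1, dtype=int)
    inside = (beat >= 0) & (beat < trig.size - 1)
    rr = np.diff(trig)
    b = beat[inside]
    ph = np.floor(C * (t[inside] - trig[b]) / rr[b]).astype(int)
    phase[inside] = np.minimum(ph, C - 1)
    return phase


def assign_cardiac_phases(raw: RawAcquisition, C: int = 25,
                          reject_rr_outliers: bool = False,
                          rr_tolerance: float = 0.25) -> np.ndarray:
    """Per-readout cardiac phase in [0, C) from ECG triggers (-1 = discard).

    Readouts before the first or after the last trigger are marked -1, as
    are whole beats outside ``rr_tolerance`` of the median RR when outlier
    rejection is enabled.
    """
    trig = np.asarray(raw.ecg_triggers, dtype=float)
    phase = cardiac_phase_labels(raw.timestamps, trig, C)
    if reject_rr_outliers:
        t = raw.timestamps
        beat = np.searchsorted(trig, t, side="right") - 1
        inside = (beat >= 0) & (beat < trig.size - 1)
        rr = np.diff(trig)
        med = np.median(rr)
        bad_beats = np.abs(rr - med) > rr_tolerance * med
        bad = inside.copy()
        bad[inside] = bad_beats[beat[inside]]
        phase[bad] = -1
    return phase


def select_end_expiration(
    assignment: BinAssignment | None,
    signal: RespiratorySignal,
    raw: RawAcquisition,
    fraction: float = 0.4,
) -> np.ndarray:
    """Indices of the readouts in the most stable respiratory position.

    Finds the narrowest navigator-amplitude window containing ``fraction``
    of all readouts (exhaustive sweep over the sorted amplitudes) -- for
    quasi-periodic breathing with an end-expiration plateau this is the
    plateau.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    amp = signal.interp(raw.timestamps)
    n = amp.size
    m = max(1, int(round(fraction * n)))
    srt = np.sort(amp)
    if m >= n:
        return np.arange(n)
    widths = srt[m - 1:] - srt[: n - m + 1]
    i = int(np.argmin(widths))
    lo, hi = srt[i], srt[i + m - 1]
    return np.nonzero((amp >= lo) & (amp <= hi))[0]


def gate(
    raw: RawAcquisition, K: int = 8, C: int = 25, cutoff_hz: float = 0.6
) -> tuple[BinAssignment, RespiratorySignal]:
    """Full gating: navigator extraction + respiratory and cardiac binning."""
    sig = extract_dc_navigator(raw, cutoff_hz=cutoff_hz)
    assign = assign_respiratory_bins(sig, raw, K=K)
    assign.cardiac_phase = assign_cardiac_phases(raw, C=C)
    assign.C = C
    return assign, sig
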