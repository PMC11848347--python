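"""Zero-phase band-pass filtering and sliding-window envelopes.

Both detectors run on zero-phase (forward-backward) Butterworth band-pass
filtered signal: 0.16-1.25 Hz for slow oscillations, 9-16 Hz for spindles.
Forward-backward application squares the magnitude response and cancels the
phase, so detected event timing carries no group delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

SO_BAND = (0.16, 1.25)
SPINDLE_BAND = (9.0, 16.0)


def design_bandpass(band: tuple[float, float], fs: float, order: int = 2):
    """Second-order-sections Butterworth band-pass design."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} invalid for sampling rate {fs}")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray, padlen: int) -> np.ndarray:
    """Zero-phase filtering, symmetric under time reversal by construction.

    Forward-backward filtering with edge padding is not exactly invariant to
    reversing the input (the two pass orders differ at the boundaries), so
    the result is averaged with its time-reversed twin; the average is
    bit-reversible because IEEE addition commutes. ``padlen`` is scaled to
    the filter's low cutoff so the transient has room to settle.
    """
    x = np.asarray(x, dtype=np.float64)
    padlen = min(padlen, len(x) - 1)
    min_len = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= 3 * min_len:
        raise ValueError(
            f"signal of {len(x)} samples is too short to band-pass filter "
            f"(needs > {3 * min_len} samples)"
        )
    a = sps.sosfiltfilt(sos, x, padlen=padlen)
    b = sps.sosfiltfilt(sos, x[::-1], padlen=padlen)[::-1]
    return (a + b) / 2.0


def bandpass_so(x: np.ndarray, fs: float, band: tuple[float, float] = SO_BAND,
                order: int = 2) -> np.ndarray:
    """Zero-phase band-pass in the slow-oscillation band (default 0.16-1.25 Hz)."""
    padlen = int(round(3 * fs / band[0]))
    return _filtfilt(design_bandpass(band, fs, order), x, padlen)


def bandpass_spindle(x: np.ndarray, fs: float,
                     band: tuple[float, float] = SPINDLE_BAND,
                     order: int = 2) -> np.ndarray:
    """Zero-phase band-pass in the spindle band (default 9-16 Hz)."""
    if fs < 64:
        raise ValueError("spindle filtering requires sampling rate >= 64 Hz")
    padlen = int(round(3 * fs / band[0]))
    return _filtfilt(design_bandpass(band, fs, order), x, padlen)


def filter_gain(band: tuple[float, float], fs: float, freq_hz: float,
                order: int = 2) -> float:
    """Analytic amplitude gain of the zero-phase band-pass at ``freq_hz``.

    Forward-backward filtering applies the squared magnitude response.
    """
    sos = design_bandpass(band, fs, order)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def _window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered window [i-w//2, i+(w-1)//2] clipped to the signal; length n."""
    idx = np.arange(n)
    lo = np.maximum(idx - w // 2, 0)
    hi = np.minimum(idx + (w - 1) // 2 + 1, n)
    return lo, hi


def _sliding_apply(x: np.ndarray, w: int, reduce) -> np.ndarray:
    """Apply ``reduce`` over centered windows; edges use shrunken windows.

    Interior windows are reduced via a strided view so the summation order is
    identical to reducing each slice directly (bit-reproducible against a
    per-index recomputation).
    """
    n = len(x)
    out = np.empty(n, dtype=np.float64)
    lo, hi = _window_bounds(n, w)
    full = np.flatnonzero(hi - lo == w)
    if full.size:
        view = np.lib.stride_tricks.sliding_window_view(x, w)
        # chunk to bound the temporary from the reduction
        step = max(1, 4_000_000 // w)
        for s in range(0, full.size, step):
            ii = full[s : s + step]
            out[ii] = reduce(view[lo[ii]], axis=1)
    edge = np.flatnonzero(hi - lo != w)
    for i in edge:
        out[i] = reduce(x[lo[i] : hi[i]])
    return out


def rms_envelope(x: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """Centered sliding-window RMS, same length as the input.

    Window edges shrink near the signal boundaries so every output sample is
    the RMS of the samples actually available.
    """
    x = np.asarray(x, dtype=np.float64)
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    return np.sqrt(_sliding_apply(x * x, w, np.mean))


def smooth_envelope(x: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """Centered moving average with the same shrunken-edge contract."""
    x = np.asarray(x, dtype=np.float64)
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window must span at least 1 sample")
    return _sliding_apply(x, w, np.mean)
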