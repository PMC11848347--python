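"""Sleep-spindle detection by RMS-envelope thresholding (9-16 Hz band).

The 9-16 Hz filtered signal is reduced to a 0.2-s sliding-window RMS,
smoothed with a 0.2-s moving average, and thresholded at mean + k·SD
(default k = 1.5) of the smoothed envelope over artifact-free N2+N3
samples. Maximal supra-threshold runs lasting 0.5-3.0 s become spindle
events; supra-threshold runs separated by gaps shorter than ``merge_gap_s``
are merged first so envelope ripple does not split one spindle in two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import ArtifactMask, Hypnogram

SPINDLE_DURATION_BOUNDS = (0.5, 3.0)


@dataclass
class SpindleEvent:
    channel: str
    start_s: float
    end_s: float
    duration_s: float
    ptp_amplitude_uv: float
    power_uv2: float          # mean squared filtered amplitude over the event
    energy_uv2s: float        # integrated power: power_uv2 * duration_s
    peak_power_freq_hz: float
    stage: str


def spindle_threshold(smoothed_envelope: np.ndarray, stats_mask: np.ndarray,
                      k: float = 1.5) -> float:
    """mean + k·SD of the envelope over the statistics domain."""
    dom = smoothed_envelope[stats_mask]
    if dom.size == 0:
        raise ValueError("no artifact-free N2/N3 samples to compute the "
                         "spindle threshold from")
    return float(dom.mean() + k * dom.std())


def peak_power_frequency(segment: np.ndarray, fs: float,
                         band: tuple[float, float] = (9.0, 16.0)) -> float:
    """Frequency of maximal spectral density of a filtered event segment.

    The segment is zero-padded to at least 1 s so the frequency resolution
    is at most 1 Hz; the search is restricted to the spindle band.
    """
    nfft = max(len(segment), int(round(fs)))
    f, p = sps.periodogram(segment, fs, nfft=nfft)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        return float("nan")
    fb, pb = f[sel], p[sel]
    return float(fb[int(np.argmax(pb))])


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_spindles(smoothed_envelope: np.ndarray, filtered: np.ndarray,
                    sampling_rate_hz: float, hypnogram: Hypnogram,
                    artifact_mask: ArtifactMask | None, channel: str,
                    k: float = 1.5,
                    duration_bounds: tuple[float, float] = SPINDLE_DURATION_BOUNDS,
                    merge_gap_s: float = 0.1,
                    band: tuple[float, float] = (9.0, 16.0),
                    stages: tuple[str, ...] = ("N2", "N3")) -> list[SpindleEvent]:
    """Detect spindles on one channel.

    Parameters
    ----------
    smoothed_envelope, filtered : ndarray
        Aligned outputs of the envelope pipeline and the band-pass filter.
    k : float
        Threshold multiplier: envelope must exceed mean + k·SD computed over
        artifact-free samples of ``stages`` on this channel.
    """
    if len(smoothed_envelope) != len(filtered):
        raise ValueError("envelope and filtered signal are not aligned")
    fs = sampling_rate_hz
    n = len(filtered)
    stage_mask = hypnogram.sample_mask(stages, n, fs)
    clean = ~artifact_mask.sample_mask(channel, n, fs) if artifact_mask else np.ones(n, bool)
    stats_mask = stage_mask & clean
    threshold = spindle_threshold(smoothed_envelope, stats_mask, k)

    supra = (smoothed_envelope > threshold) & stats_mask
    runs = _runs_bool(supra)
    runs = _merge_runs(runs, int(round(merge_gap_s * fs)))
    lo_d, hi_d = duration_bounds
    events = []
    for i0, i1 in runs:
        dur = (i1 - i0) / fs
        if not lo_d <= dur <= hi_d:
            continue
        seg = filtered[i0:i1]
        power = float(np.mean(seg**2))
        mid_t = (i0 + i1) / 2 / fs
        events.append(
            SpindleEvent(
                channel=channel,
                start_s=i0 / fs,
                end_s=i1 / fs,
                duration_s=dur,
                ptp_amplitude_uv=float(seg.max() - seg.min()),
                power_uv2=power,
                energy_uv2s=power * dur,
                peak_power_freq_hz=peak_power_frequency(seg, fs, band),
                stage=hypnogram.stage_at(mid_t),
            )
        )
    return events


def _runs_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))
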