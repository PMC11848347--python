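"""Slow-oscillation detection by zero-crossing segmentation and amplitude gating.

A candidate SO is the stretch of 0.16-1.25 Hz filtered signal between two
successive positive-to-negative zero crossings (PNZC) lasting 0.8-2.0 s.
Its amplitude is trough-to-peak: the minimum of the segment to the maximum
that follows it. Candidates whose amplitude strictly exceeds the 75th
percentile of all duration-qualifying candidate amplitudes (per channel,
per recording) become events. Only candidates lying entirely inside
artifact-free N2/N3 epochs enter the pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import EPOCH_LEN_S, ArtifactMask, Hypnogram

SO_DURATION_BOUNDS = (0.8, 2.0)


@dataclass
class SOEvent:
    channel: str
    start_s: float
    end_s: float
    duration_s: float
    trough_uv: float
    peak_uv: float
    ptp_amplitude_uv: float
    stage: str


def positive_to_negative_crossings(x: np.ndarray, fs: float) -> np.ndarray:
    """Times (s) where the signal crosses from positive to non-positive.

    The crossing time is linearly interpolated between the bracketing
    samples.
    """
    x = np.asarray(x, dtype=np.float64)
    idx = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0))
    if idx.size == 0:
        return np.empty(0)
    frac = x[idx] / (x[idx] - x[idx + 1])
    return (idx + frac) / fs


@dataclass
class _Candidate:
    start_s: float
    end_s: float
    trough_uv: float
    peak_uv: float
    trough_t: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def ptp(self) -> float:
        return self.peak_uv - self.trough_uv


def _stage_clean(t0: float, t1: float, hypnogram: Hypnogram,
                 artifact_mask: ArtifactMask | None, channel: str,
                 stages: tuple[str, ...]) -> bool:
    e0 = int(t0 // EPOCH_LEN_S)
    e1 = int(np.ceil(t1 / EPOCH_LEN_S))
    for e in range(e0, max(e1, e0 + 1)):
        if e >= hypnogram.n_epochs or hypnogram.stages[e] not in stages:
            return False
    if artifact_mask is not None and artifact_mask.overlaps(channel, t0, t1):
        return False
    return True


def detect_slow_oscillations(filtered: np.ndarray, sampling_rate_hz: float,
                             hypnogram: Hypnogram,
                             artifact_mask: ArtifactMask | None,
                             channel: str,
                             duration_bounds: tuple[float, float] = SO_DURATION_BOUNDS,
                             amplitude_percentile: float = 75.0,
                             stages: tuple[str, ...] = ("N2", "N3"),
                             min_candidates: int = 4) -> list[SOEvent]:
    """Detect SOs on one channel of SO-band filtered signal.

    Parameters
    ----------
    filtered : ndarray
        Output of :func:`sleepmicro.filters.bandpass_so` for ``channel``.
    amplitude_percentile : float
        Trough-to-peak amplitude gate; candidates must strictly exceed this
        percentile (linear interpolation) of the candidate-amplitude pool.
    """
    fs = sampling_rate_hz
    lo_d, hi_d = duration_bounds
    zc = positive_to_negative_crossings(filtered, fs)
    candidates: list[_Candidate] = []
    for t0, t1 in zip(zc[:-1], zc[1:]):
        if not lo_d <= t1 - t0 <= hi_d:
            continue
        if not _stage_clean(t0, t1, hypnogram, artifact_mask, channel, stages):
            continue
        i0 = int(np.ceil(t0 * fs))
        i1 = int(np.floor(t1 * fs)) + 1
        seg = filtered[i0:i1]
        if seg.size < 2:
            continue
        j_tr = int(np.argmin(seg))
        after = seg[j_tr:]
        peak = float(np.max(after))
        trough = float(seg[j_tr])
        if peak <= trough:
            continue
        candidates.append(
            _Candidate(float(t0), float(t1), trough, peak, (i0 + j_tr) / fs)
        )
    if len(candidates) < min_candidates:
        warnings.warn(
            f"only {len(candidates)} SO candidates on {channel}; amplitude "
            "percentile unstable, returning no events"
        )
        return []
    ptps = np.array([c.ptp for c in candidates])
    threshold = float(np.percentile(ptps, amplitude_percentile))
    events = []
    for c in candidates:
        if c.ptp > threshold:
            events.append(
                SOEvent(
                    channel=channel,
                    start_s=c.start_s,
                    end_s=c.end_s,
                    duration_s=c.duration_s,
                    trough_uv=c.trough_uv,
                    peak_uv=c.peak_uv,
                    ptp_amplitude_uv=c.ptp,
                    stage=hypnogram.stage_at(c.trough_t),
                )
            )
    return events


def so_candidate_amplitudes(filtered: np.ndarray, sampling_rate_hz: float,
                            hypnogram: Hypnogram,
                            artifact_mask: ArtifactMask | None,
                            channel: str,
                            duration_bounds: tuple[float, float] = SO_DURATION_BOUNDS,
                            stages: tuple[str, ...] = ("N2", "N3")) -> np.ndarray:
    """Trough-to-peak amplitudes of the duration-qualifying candidate pool.

    Exposed so the percentile gate can be re-verified from outside the
    detector.
    """
    fs = sampling_rate_hz
    lo_d, hi_d = duration_bounds
    zc = positive_to_negative_crossings(filtered, fs)
    out = []
    for t0, t1 in zip(zc[:-1], zc[1:]):
        if not lo_d <= t1 - t0 <= hi_d:
            continue
        if not _stage_clean(t0, t1, hypnogram, artifact_mask, channel, stages):
            continue
        i0 = int(np.ceil(t0 * fs))
        i1 = int(np.floor(t1 * fs)) + 1
        seg = filtered[i0:i1]
        if seg.size < 2:
            continue
        j = int(np.argmin(seg))
        peak = float(np.max(seg[j:]))
        if peak > seg[j]:
            out.append(peak - float(seg[j]))
    return np.array(out)
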