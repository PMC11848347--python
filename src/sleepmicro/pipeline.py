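"""End-to-end detection: filtering, artifact tagging, both detectors, metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import filters
from .metrics import ParticipantMetrics, participant_metrics
from .recording import ArtifactMask, EEGRecording, Hypnogram
from .so import SOEvent, detect_slow_oscillations
from .spindles import SpindleEvent, detect_spindles
from .staging import (
    ArtifactParams,
    SleepArchitecture,
    compute_sleep_architecture,
)

DEFAULT_SPINDLE_CHANNELS = ("C3", "C4")
DEFAULT_SO_CHANNELS = ("F3", "F4")


@dataclass
class DetectionResult:
    spindles: list[SpindleEvent] = field(default_factory=list)
    slow_oscillations: list[SOEvent] = field(default_factory=list)
    artifact_mask: ArtifactMask = field(default_factory=ArtifactMask)
    architecture: SleepArchitecture | None = None
    spindle_channels: list[str] = field(default_factory=list)
    so_channels: list[str] = field(default_factory=list)

    def metrics(self, hypnogram: Hypnogram,
                participant_id: str = "P0001") -> ParticipantMetrics:
        return participant_metrics(
            participant_id, self.spindles, self.slow_oscillations, hypnogram,
            self.artifact_mask, self.spindle_channels, self.so_channels,
            architecture=self.architecture,
        )


def run_detection(recording: EEGRecording, hypnogram: Hypnogram,
                  spindle_channels=DEFAULT_SPINDLE_CHANNELS,
                  so_channels=DEFAULT_SO_CHANNELS,
                  artifact_params: ArtifactParams | None = None,
                  artifact_mask: ArtifactMask | None = None,
                  k: float = 1.5,
                  spindle_band: tuple[float, float] = filters.SPINDLE_BAND,
                  so_band: tuple[float, float] = filters.SO_BAND) -> DetectionResult:
    """Run artifact tagging and both detectors over a recording.

    Channels requested but absent from the recording raise; pass only the
    channels the montage has.
    """
    sp_ch = [c for c in spindle_channels]
    so_ch = [c for c in so_channels]
    recording.require(sp_ch, "spindle detection")
    recording.require(so_ch, "slow-oscillation detection")
    fs = recording.sampling_rate_hz

    if artifact_mask is None:
        from .staging import tag_artifacts

        artifact_mask = tag_artifacts(
            recording, hypnogram, artifact_params,
            channels=sorted(set(sp_ch) | set(so_ch)),
        )

    spindles: list[SpindleEvent] = []
    for ch in sp_ch:
        filt = filters.bandpass_spindle(recording.get(ch), fs, spindle_band)
        env = filters.smooth_envelope(filters.rms_envelope(filt, fs), fs)
        spindles += detect_spindles(env, filt, fs, hypnogram, artifact_mask,
                                    ch, k=k, band=spindle_band)

    sos: list[SOEvent] = []
    for ch in so_ch:
        filt = filters.bandpass_so(recording.get(ch), fs, so_band)
        sos += detect_slow_oscillations(filt, fs, hypnogram, artifact_mask, ch)

    return DetectionResult(
        spindles=spindles,
        slow_oscillations=sos,
        artifact_mask=artifact_mask,
        architecture=compute_sleep_architecture(hypnogram),
        spindle_channels=sp_ch,
        so_channels=so_ch,
    )


def match_events(detected, truth, tolerance_s: float = 0.5) -> dict:
    """Match detected events to ground truth by interval overlap.

    A truth event is recalled if some detected event on the same channel
    overlaps it (or starts/ends within ``tolerance_s``); each detected
    event can claim at most one truth event.

    Returns a dict with recall, precision, f1, and the hit counts.
    """
    truth = list(truth)
    claimed = [False] * len(truth)
    tp = 0
    for d in detected:
        best = None
        for i, t in enumerate(truth):
            if claimed[i] or t.channel != d.channel:
                continue
            t_end = t.start_s + t.duration_s
            overlap = min(d.end_s, t_end) - max(d.start_s, t.start_s)
            if overlap > 0 or (abs(d.start_s - t.start_s) <= tolerance_s
                               and abs(d.end_s - t_end) <= tolerance_s):
                best = i
                break
        if best is not None:
            claimed[best] = True
            tp += 1
    fn = claimed.count(False)
    fp = len(list(detected)) - tp
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"recall": recall, "precision": precision, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}
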