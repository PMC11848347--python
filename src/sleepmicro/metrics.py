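"""Per-participant aggregation of detected events into analysis metrics.

Densities are events per artifact-free 30-s epoch of the analyzed stages —
the denominator every event-density figure in this package uses. Metrics
are computed per channel and then averaged across the requested channels
with equal weight (configurable to pooling the events instead), which keeps
densities interpretable when one channel is partially masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import ArtifactMask, Hypnogram
from .so import SOEvent
from .spindles import SpindleEvent
from .staging import SleepArchitecture

METRIC_FIELDS = ("count", "density_per_30s", "mean_duration_s", "mean_ptp_uv",
                 "mean_power_uv2", "mean_peak_freq_hz")


def clean_epoch_count(hypnogram: Hypnogram, artifact_mask: ArtifactMask | None,
                      channel: str, stage_set: tuple[str, ...]) -> int:
    """Number of artifact-free epochs of ``stage_set`` for ``channel``."""
    epochs = hypnogram.epochs_of(stage_set)
    if artifact_mask is None:
        return len(epochs)
    return int(sum(artifact_mask.epoch_is_clean(channel, int(e)) for e in epochs))


def _event_stage(ev) -> str:
    return ev.stage


def aggregate(events, hypnogram: Hypnogram, artifact_mask: ArtifactMask | None,
              stage_set: tuple[str, ...], channels: list[str],
              mode: str = "average") -> dict[str, float]:
    """Aggregate one event kind over ``stage_set`` and ``channels``.

    Returns count (summed over channels), density (/30-s artifact-free
    epoch), and event-level means. Means are NaN when there are no events.

    mode : {"average", "pooled"}
        "average" computes per-channel metrics and averages them;
        "pooled" pools events and epochs across channels first.
    """
    if not set(stage_set) <= {"N2", "N3"}:
        raise ValueError("stage_set must be a subset of {N2, N3}")
    per_ch = []
    for ch in channels:
        evs = [e for e in events if e.channel == ch and e.stage in stage_set]
        n_epochs = clean_epoch_count(hypnogram, artifact_mask, ch, stage_set)
        per_ch.append((ch, evs, n_epochs))
    if all(n == 0 for _, _, n in per_ch):
        warnings.warn(f"no artifact-free epochs in stages {stage_set}")
        return {f: float("nan") for f in METRIC_FIELDS} | {"count": 0.0}

    def _stats(evs, n_epochs):
        count = len(evs)
        density = count / n_epochs if n_epochs > 0 else float("nan")
        if count == 0:
            return dict(count=0.0, density_per_30s=density,
                        mean_duration_s=float("nan"), mean_ptp_uv=float("nan"),
                        mean_power_uv2=float("nan"), mean_peak_freq_hz=float("nan"))
        return dict(
            count=float(count),
            density_per_30s=density,
            mean_duration_s=float(np.mean([e.duration_s for e in evs])),
            mean_ptp_uv=float(np.mean([e.ptp_amplitude_uv for e in evs])),
            mean_power_uv2=float(np.mean([getattr(e, "power_uv2", np.nan) for e in evs])),
            mean_peak_freq_hz=float(np.mean([getattr(e, "peak_power_freq_hz", np.nan)
                                             for e in evs])),
        )

    if mode == "pooled":
        all_evs = [e for _, evs, _ in per_ch for e in evs]
        total_epochs = sum(n for _, _, n in per_ch)
        return _stats(all_evs, total_epochs)
    if mode != "average":
        raise ValueError("mode must be 'average' or 'pooled'")
    stats = [_stats(evs, n) for _, evs, n in per_ch if n > 0]
    out: dict[str, float] = {}
    out["count"] = float(sum(s["count"] for s in stats))
    out["density_per_30s"] = float(np.mean([s["density_per_30s"] for s in stats]))
    for f in ("mean_duration_s", "mean_ptp_uv", "mean_power_uv2", "mean_peak_freq_hz"):
        vals = [s[f] for s in stats if np.isfinite(s[f])]
        out[f] = float(np.mean(vals)) if vals else float("nan")
    return out


@dataclass
class ParticipantMetrics:
    """One participant's event metrics by kind and stage set, plus architecture."""

    participant_id: str
    spindle: dict[str, dict[str, float]] = field(default_factory=dict)  # keyed "N2","N3","N2N3"
    so: dict[str, dict[str, float]] = field(default_factory=dict)
    architecture: SleepArchitecture | None = None

    def to_row(self) -> pd.Series:
        row: dict[str, float] = {"participant_id": self.participant_id}
        for kind, table in (("sp", self.spindle), ("so", self.so)):
            for stage_key, stats in table.items():
                suffix = stage_key.lower()
                for f, v in stats.items():
                    row[f"{kind}_{f}_{suffix}"] = v
        if self.architecture is not None:
            row.update(self.architecture.to_dict())
        return pd.Series(row)


def participant_metrics(participant_id: str,
                        spindle_events: list[SpindleEvent],
                        so_events: list[SOEvent],
                        hypnogram: Hypnogram,
                        artifact_mask: ArtifactMask | None,
                        spindle_channels: list[str],
                        so_channels: list[str],
                        architecture: SleepArchitecture | None = None,
                        mode: str = "average") -> ParticipantMetrics:
    """Compute the full per-participant metric set (N2, N3, N2+N3 combined)."""
    stage_sets = {"N2": ("N2",), "N3": ("N3",), "N2N3": ("N2", "N3")}
    pm = ParticipantMetrics(participant_id=participant_id)
    for key, ss in stage_sets.items():
        pm.spindle[key] = aggregate(spindle_events, hypnogram, artifact_mask,
                                    ss, spindle_channels, mode)
        pm.so[key] = aggregate(so_events, hypnogram, artifact_mask,
                               ss, so_channels, mode)
    pm.architecture = architecture
    return pm


def events_to_frame(events) -> pd.DataFrame:
    """Detected events as a DataFrame (stable column order for CSV export)."""
    if not events:
        return pd.DataFrame()
    rows = []
    for e in events:
        d = dict(e.__dict__)
        rows.append(d)
    df = pd.DataFrame(rows)
    lead = [c for c in ("channel", "start_s", "end_s", "duration_s") if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest]
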