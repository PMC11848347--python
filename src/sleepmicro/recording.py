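"""Core containers: EEG recordings, hypnograms, artifact masks, and their file I/O.

Conventions used throughout the package:

* all signal amplitudes are in microvolts (µV);
* all times are seconds from the start of the recording, intervals are
  half-open ``[start, end)``;
* hypnogram epoch ``i`` covers ``[30*i, 30*(i+1))`` seconds.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH_LEN_S = 30.0
STAGES = ("W", "N1", "N2", "N3", "REM", "UNSCORED")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")

_CHANNEL_RE = re.compile(r"^(?:EEG\s+)?([A-Za-z]+\d*)(?:[-_]([AM]\d))?$")


def normalize_channel_label(label: str) -> tuple[str, str | None]:
    """Split a raw channel label into (channel, reference).

    ``"C3-A2"`` -> ``("C3", "A2")``; ``"EEG F3-M2"`` -> ``("F3", "M2")``;
    a bare ``"C4"`` keeps reference ``None``.
    """
    m = _CHANNEL_RE.match(label.strip())
    if not m:
        return label.strip(), None
    return m.group(1), m.group(2)


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts with a single sampling rate.

    Parameters
    ----------
    channels : list of str
        Normalized channel labels (e.g. ``["F3", "C3"]``).
    sampling_rate_hz : float
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    reference : str
        Reference description (mastoid labels in clinical recordings).
    """

    channels: list[str]
    sampling_rate_hz: float
    data: np.ndarray
    reference: str = "A1/A2"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def get(self, channel: str) -> np.ndarray:
        """Return the µV series of one channel."""
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in recording; available: {self.channels}"
            ) from None
        return self.data[idx]

    def require(self, channels: list[str], purpose: str = "analysis") -> None:
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise KeyError(
                f"channels {missing} required for {purpose} are missing; "
                f"available channels: {self.channels}"
            )


@dataclass
class Hypnogram:
    """Sleep stages in 30-s epochs (W, N1, N2, N3, REM, UNSCORED)."""

    stages: list[str]
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError("hypnogram epochs must be 30 s")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stages {bad}; expected one of {STAGES}")
        self.stages = list(self.stages)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        i = int(t_s // self.epoch_len_s)
        if not 0 <= i < self.n_epochs:
            return "UNSCORED"
        return self.stages[i]

    def epochs_of(self, stages: set[str] | tuple[str, ...]) -> np.ndarray:
        """Indices of epochs whose stage is in ``stages``."""
        want = set(stages)
        return np.array([i for i, s in enumerate(self.stages) if s in want], dtype=int)

    def sample_mask(self, stages, n_samples: int, fs: float) -> np.ndarray:
        """Boolean per-sample mask: True where the sample's epoch is in ``stages``."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_len_s * fs))
        for i in self.epochs_of(stages):
            mask[i * spe : min((i + 1) * spe, n_samples)] = True
        return mask

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"epoch_index": range(self.n_epochs), "stage": self.stages}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path, sep="\t")
        if "stage" not in df.columns:
            raise ValueError(f"{path}: expected columns epoch_index, stage")
        return cls(stages=[str(s) for s in df["stage"]])


@dataclass
class ArtifactMask:
    """Per-channel bad intervals, half-open ``[start_s, end_s)`` in seconds."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch, s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty/inverted interval ({ch}, {s}, {e})")

    def add(self, channel: str, start_s: float, end_s: float) -> None:
        if end_s <= start_s:
            raise ValueError("end_s must exceed start_s")
        self.intervals.append((channel, float(start_s), float(end_s)))

    def merged(self) -> "ArtifactMask":
        """Union of intervals per channel; idempotent."""
        out: list[tuple[str, float, float]] = []
        by_ch: dict[str, list[tuple[float, float]]] = {}
        for ch, s, e in self.intervals:
            by_ch.setdefault(ch, []).append((s, e))
        for ch, ivs in by_ch.items():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((ch, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((ch, cur_s, cur_e))
        out.sort()
        return ArtifactMask(out)

    def channel_intervals(self, channel: str) -> list[tuple[float, float]]:
        return [(s, e) for ch, s, e in self.intervals if ch == channel]

    def overlaps(self, channel: str, start_s: float, end_s: float) -> bool:
        return any(
            s < end_s and start_s < e for s, e in self.channel_intervals(channel)
        )

    def sample_mask(self, channel: str, n_samples: int, fs: float) -> np.ndarray:
        """True where the sample falls inside an artifact interval of ``channel``."""
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.channel_intervals(channel):
            i0 = max(0, int(np.floor(s * fs)))
            i1 = min(n_samples, int(np.ceil(e * fs)))
            mask[i0:i1] = True
        return mask

    def epoch_is_clean(self, channel: str, epoch: int) -> bool:
        return not self.overlaps(channel, epoch * EPOCH_LEN_S, (epoch + 1) * EPOCH_LEN_S)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.intervals, columns=["channel", "start_s", "end_s"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ArtifactMask":
        df = pd.read_csv(path)
        return cls([(str(r.channel), float(r.start_s), float(r.end_s)) for r in df.itertuples()])


# ---------------------------------------------------------------------------
# File readers/writers


def write_raw_binary(recording: EEGRecording, path) -> None:
    """Write float32 little-endian binary (channel-major) + JSON sidecar."""
    path = Path(path)
    recording.data.astype("<f4").tofile(path)
    sidecar = {
        "channels": recording.channels,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "reference": recording.reference,
        "n_samples": recording.n_samples,
        "dtype": "float32",
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_binary(path) -> EEGRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype="<f4")
    n_ch = len(sidecar["channels"])
    data = raw.reshape(n_ch, -1).astype(np.float64)
    return EEGRecording(
        channels=list(sidecar["channels"]),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        data=data,
        reference=sidecar.get("reference", "A1/A2"),
    )


def read_edf(path) -> EEGRecording:
    """Read an EDF file (via mne) into µV, with channel labels normalized."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels, refs = [], []
    for name in raw.ch_names:
        ch, ref = normalize_channel_label(name)
        labels.append(ch)
        refs.append(ref)
    data_uv = raw.get_data() * 1e6  # mne loads Volts
    ref = "/".join(sorted({r for r in refs if r})) or "A1/A2"
    return EEGRecording(
        channels=labels,
        sampling_rate_hz=float(raw.info["sfreq"]),
        data=data_uv,
        reference=ref,
    )


def read_recording(path, format: str | None = None, require_channels=None,
                   purpose: str = "analysis") -> EEGRecording:
    """Read EEG from EDF or raw+sidecar.

    Parameters
    ----------
    format : {"edf", "raw", None}
        ``None`` infers from the file suffix.
    require_channels : list of str, optional
        Raise (naming available channels) if any is missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "raw"
    if format == "edf":
        rec = read_edf(path)
    elif format == "raw":
        rec = read_raw_binary(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'raw'")
    if require_channels:
        rec.require(list(require_channels), purpose)
    return rec
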