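"""Minimal EDF (16-bit European Data Format) writer.

Writes continuous multi-channel recordings with physical dimension µV and
1-s data records, enough for round-tripping through standard EDF readers.
Values are quantized to the 16-bit digital range spanned by each channel's
physical min/max, so round-trip error is bounded by half a quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path) -> None:
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(recording.channels)
    spr = fs  # samples per record (1-s records)
    n_records = int(np.ceil(recording.n_samples / spr))
    n_total = n_records * spr

    data = np.zeros((n_ch, n_total), dtype=np.float64)
    data[:, : recording.n_samples] = recording.data

    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _pad("0", 8)                      # version
    header += _pad("X X X X", 80)               # patient id (anonymous)
    header += _pad("Startdate X X X X", 80)     # recording id
    header += _pad("01.01.00", 8)               # start date
    header += _pad("00.00.00", 8)               # start time
    header += _pad(str(256 * (n_ch + 1)), 8)    # header bytes
    header += _pad("", 44)                      # reserved
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                      # record duration (s)
    header += _pad(str(n_ch), 4)

    header += b"".join(_pad(c, 16) for c in recording.channels)   # labels
    header += b"".join(_pad("", 80) for _ in range(n_ch))         # transducer
    header += b"".join(_pad("uV", 8) for _ in range(n_ch))        # phys dim
    header += b"".join(_pad(f"{phys_min[i]:g}", 8) for i in range(n_ch))
    header += b"".join(_pad(f"{phys_max[i]:g}", 8) for i in range(n_ch))
    header += b"".join(_pad(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_pad("", 80) for _ in range(n_ch))         # prefilter
    header += b"".join(_pad(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_pad("", 32) for _ in range(n_ch))         # reserved

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.empty((n_ch, n_total), dtype="<i2")
    for i in range(n_ch):
        d = np.rint((data[i] - phys_min[i]) / gain[i]) + dig_min
        digital[i] = np.clip(d, dig_min, dig_max).astype("<i2")

    with open(Path(path), "wb") as fh:
        fh.write(header)
        # record-major layout: for each 1-s record, all channels' samples
        blocks = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())
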