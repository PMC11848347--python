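"""Synthetic EEG and cohort generation with known ground truth.

The EEG generator renders spindles as Hann-windowed (waxing-waning)
sinusoids in the 9-16 Hz band and slow oscillations as single biphasic
<1.25 Hz cycles, superimposed on 1/f (pink) background noise, inside N2/N3
epochs of a supplied hypnogram. The cohort generator draws participant
tables whose clinical marginals are anchored to a mild-to-moderate AD
polysomnography cohort (age ~75, high AHI, CSF Aβ42 median ~516 pg/mL,
pTau181 ~82 pg/mL, MMSE ~23 declining ~4 points over 36 months) and whose
exposure→mediator→outcome structure is planted with configurable direct,
indirect and interaction effects — the ground truth every statistics test
is scored against.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .recording import EPOCH_LEN_S, EEGRecording, Hypnogram

CENTRAL = ("C3", "C4")
FRONTAL = ("F3", "F4")


@dataclass
class GroundTruthEvent:
    """One injected event, recorded exactly as rendered."""

    kind: str                 # "spindle" | "SO"
    channel: str
    start_s: float
    duration_s: float
    amplitude_uv: float       # peak-to-peak (spindle) / trough-to-peak (SO)
    freq_hz: float            # carrier frequency

    def __post_init__(self) -> None:
        if self.kind not in ("spindle", "SO"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_s <= 0 or self.start_s < 0:
            raise ValueError("events need start_s >= 0 and duration_s > 0")
        if self.kind == "spindle" and not 9 <= self.freq_hz <= 16:
            raise ValueError("spindle carrier must lie in 9-16 Hz")
        if self.kind == "SO" and not 0 < self.freq_hz <= 1.25:
            raise ValueError("SO carrier must lie in (0, 1.25] Hz")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def spindle_event(channel: str, start_s: float, duration_s: float = 1.0,
                  amplitude_uv: float = 40.0, freq_hz: float = 12.0) -> GroundTruthEvent:
    return GroundTruthEvent("spindle", channel, start_s, duration_s,
                            amplitude_uv, freq_hz)


def so_event(channel: str, start_s: float, freq_hz: float = 0.8,
             amplitude_uv: float = 150.0) -> GroundTruthEvent:
    """A slow oscillation rendered as one full cycle at ``freq_hz``."""
    return GroundTruthEvent("SO", channel, start_s, 1.0 / freq_hz,
                            amplitude_uv, freq_hz)


@dataclass
class ArtifactSpec:
    """Planned signal aberration: flatline (zeroed) or broadband burst."""

    kind: str                 # "flatline" | "burst"
    channel: str
    start_s: float
    duration_s: float
    amplitude_uv: float = 400.0

    def __post_init__(self) -> None:
        if self.kind not in ("flatline", "burst"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def pink_noise(n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """1/f-amplitude (pink) Gaussian noise, standardized to ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spectrum * scale, n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def _render_spindle(fs: float, duration_s: float, amplitude_uv: float,
                    freq_hz: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    hann = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    return (amplitude_uv / 2.0) * hann * np.sin(2 * np.pi * freq_hz * t)


def _render_so(fs: float, duration_s: float, amplitude_uv: float) -> np.ndarray:
    # one biphasic cycle: down phase (trough) then up phase (peak), so the
    # event spans successive positive-to-negative zero crossings
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return -(amplitude_uv / 2.0) * np.sin(2 * np.pi * t / duration_s)


def generate_eeg(duration_s: float, sampling_rate_hz: float,
                 channels: Sequence[str],
                 event_plan: Sequence[GroundTruthEvent] = (),
                 artifact_plan: Sequence[ArtifactSpec] = (),
                 background_noise_sd: float = 5.0,
                 stages: Sequence[str] | None = None,
                 seed: int = 0) -> tuple[EEGRecording, Hypnogram, list[GroundTruthEvent]]:
    """Render a synthetic recording with ground-truth events.

    Parameters
    ----------
    duration_s : float
        Must be a multiple of 30 s (whole epochs).
    channels : sequence of str
        Must include at least one central (C3/C4) and one frontal (F3/F4)
        label, so both detectors have a target.
    stages : sequence of str, optional
        Per-epoch stages; defaults to all N2. Events may only be planned
        inside N2/N3 epochs.

    Returns
    -------
    (EEGRecording, Hypnogram, list[GroundTruthEvent])
        The ground-truth list is exactly the rendered plan.
    """
    if duration_s % EPOCH_LEN_S != 0:
        raise ValueError("duration_s must be a multiple of 30 s")
    if sampling_rate_hz < 128:
        raise ValueError("sampling_rate_hz must be >= 128")
    channels = list(channels)
    if not any(c in CENTRAL for c in channels):
        raise ValueError(f"channels must include a central channel {CENTRAL}")
    if not any(c in FRONTAL for c in channels):
        raise ValueError(f"channels must include a frontal channel {FRONTAL}")
    n_epochs = int(duration_s // EPOCH_LEN_S)
    if stages is None:
        stages = ["N2"] * n_epochs
    stages = list(stages)
    if len(stages) != n_epochs:
        raise ValueError(f"expected {n_epochs} stages, got {len(stages)}")
    hyp = Hypnogram(stages=stages)

    fs = float(sampling_rate_hz)
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    data = np.stack([pink_noise(n, rng, background_noise_sd) for _ in channels])

    for ev in event_plan:
        if ev.channel not in channels:
            raise ValueError(f"event channel {ev.channel!r} not in {channels}")
        if ev.end_s > duration_s + 1e-9:
            raise ValueError(
                f"event at {ev.start_s:.2f}s ends at {ev.end_s:.2f}s, outside "
                f"the {duration_s:.0f}s recording"
            )
        e0 = int(ev.start_s // EPOCH_LEN_S)
        e1 = int(np.ceil(ev.end_s / EPOCH_LEN_S))
        bad = [stages[e] for e in range(e0, min(e1, n_epochs)) if stages[e] not in ("N2", "N3")]
        if bad:
            raise ValueError(
                f"event at {ev.start_s:.2f}s overlaps {bad[0]} epoch(s); events "
                "are only injectable into N2/N3 sleep"
            )
        if ev.kind == "spindle":
            wave = _render_spindle(fs, ev.duration_s, ev.amplitude_uv, ev.freq_hz)
        else:
            wave = _render_so(fs, ev.duration_s, ev.amplitude_uv)
        i0 = int(round(ev.start_s * fs))
        data[channels.index(ev.channel), i0 : i0 + len(wave)] += wave

    for art in artifact_plan:
        i0 = int(round(art.start_s * fs))
        i1 = min(int(round((art.start_s + art.duration_s) * fs)), n)
        ci = channels.index(art.channel)
        if art.kind == "flatline":
            data[ci, i0:i1] = 0.0
        else:
            data[ci, i0:i1] += rng.standard_normal(i1 - i0) * art.amplitude_uv / 2.0

    rec = EEGRecording(channels=channels, sampling_rate_hz=fs, data=data)
    return rec, hyp, list(event_plan)


def random_event_plan(kind: str, channel: str, n_events: int,
                      stages: Sequence[str], rng: np.random.Generator,
                      freq_hz: float, amplitude_uv: float,
                      duration_s: float | None = None,
                      min_gap_s: float = 1.0,
                      edge_margin_s: float = 1.0) -> list[GroundTruthEvent]:
    """Place ``n_events`` non-overlapping events uniformly inside N2/N3 epochs."""
    if kind == "SO":
        duration_s = 1.0 / freq_hz
    elif duration_s is None:
        duration_s = 1.0
    ok_epochs = [i for i, s in enumerate(stages) if s in ("N2", "N3")]
    if not ok_epochs:
        raise ValueError("no N2/N3 epochs to place events in")
    placed: list[tuple[float, float]] = []
    out: list[GroundTruthEvent] = []
    attempts = 0
    while len(out) < n_events:
        attempts += 1
        if attempts > 200 * n_events + 1000:
            raise RuntimeError(
                f"could not place {n_events} events of {duration_s:.2f}s "
                "without overlap; reduce the count or density"
            )
        e = ok_epochs[rng.integers(len(ok_epochs))]
        lo = e * EPOCH_LEN_S + edge_margin_s
        hi = (e + 1) * EPOCH_LEN_S - duration_s - edge_margin_s
        if hi <= lo:
            continue
        start = float(rng.uniform(lo, hi))
        if any(start < pe + min_gap_s and ps - min_gap_s < start + duration_s
               for ps, pe in placed):
            continue
        placed.append((start, start + duration_s))
        out.append(GroundTruthEvent(kind, channel, start, duration_s,
                                    amplitude_uv, freq_hz))
    out.sort(key=lambda ev: ev.start_s)
    return out


def ground_truth_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortConfig:
    """Planted-effect configuration for synthetic cohorts.

    The structural core is
    ``mediator = a_path·exposure + ε`` and
    ``outcome = c_prime·exposure + b_path·mediator + gamma·exposure·moderator + ε``
    with ε ~ N(0, noise_sd²). The latent ``exposure`` drives the CSF
    biomarkers (higher exposure: lower Aβ42, higher tau), the latent
    ``mediator`` drives the spindle metrics, and the latent ``outcome``
    drives cognitive follow-up scores; the raw latents are also exported so
    path estimates can be checked against the configuration directly.

    skew > 0 switches the biomarker marginals from normal to right-skewed
    lognormal shapes (larger skew, heavier right tail).

    decline_beta, when set, makes the 36-month MMSE decline indicator follow
    logit P(decline) = decline_intercept + decline_beta·sp_density instead
    of the planted outcome path.
    """

    n: int
    a_path: float = 0.0
    b_path: float = 0.0
    c_prime: float = 0.0
    gamma: float = 0.0
    noise_sd: float = 1.0
    skew: float = 0.0
    seed: int = 0
    decline_beta: float | None = None
    decline_intercept: float = -0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _biomarker(median: float, sd: float, skew: float, z: np.ndarray) -> np.ndarray:
    if skew > 0:
        return median * np.exp(0.2 * skew * z)
    return np.clip(median + sd * z, median * 0.05, None)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table with the configured planted structure."""
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n

    X = rng.standard_normal(n)                    # exposure latent
    W = rng.standard_normal(n)                    # moderator latent
    M = c.a_path * X + rng.normal(0, c.noise_sd, n)
    Y = (c.c_prime * X + c.b_path * M + c.gamma * X * W
         + rng.normal(0, c.noise_sd, n))
    sd_m = float(np.sqrt(c.a_path**2 + c.noise_sd**2))
    sd_y = float(np.sqrt(c.c_prime**2 + (c.b_path * sd_m) ** 2
                         + c.gamma**2 + c.noise_sd**2))
    Mstd, Ystd = M / sd_m, Y / sd_y

    age = 74.7 + 5.0 * rng.standard_normal(n)
    sex = rng.permuted(np.arange(n) % 2)          # balanced 0/1
    ahi = np.clip(33.7 + 23.1 * rng.standard_normal(n), 0.0, None)

    za = -0.6 * X + 0.8 * rng.standard_normal(n)
    zp = 0.6 * X + 0.8 * rng.standard_normal(n)
    zt = 0.5 * X + np.sqrt(0.75) * rng.standard_normal(n)
    abeta42 = _biomarker(516.0, 140.0, c.skew, za)
    ptau181 = _biomarker(82.0, 30.0, c.skew, zp)
    ttau = _biomarker(543.0, 280.0, c.skew, zt)

    sp_density = np.clip(2.0 + 0.8 * Mstd, 0.05, None)
    sp_duration = np.clip(1.0 + 0.15 * (0.5 * Mstd + np.sqrt(0.75) * rng.standard_normal(n)), 0.3, None)
    sp_power = np.clip(150.0 + 60.0 * (0.5 * Mstd + np.sqrt(0.75) * rng.standard_normal(n)), 5.0, None)
    so_density = np.clip(2.7 + 0.9 * rng.standard_normal(n), 0.05, None)
    so_duration = np.clip(1.2 + 0.25 * rng.standard_normal(n), 0.8, 2.0)
    so_ptp = 108.0 * np.exp(0.25 * rng.standard_normal(n))

    mmse_0 = np.clip(23.2 + 2.4 * rng.standard_normal(n), 0.0, 30.0)
    drifts = {"12": -0.8, "24": -2.5, "36": -4.1}
    mmse = {"0": mmse_0}
    for k, d in drifts.items():
        mmse[k] = np.clip(mmse_0 + d + 1.5 * Ystd
                          + 1.5 * rng.standard_normal(n), 0.0, 30.0)
    if c.decline_beta is not None:
        logit = c.decline_intercept + c.decline_beta * sp_density
        declined = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))
        drop = 2.0 + 3.0 * np.abs(rng.standard_normal(n))
        gain = 0.5 + np.abs(rng.standard_normal(n))
        mmse["36"] = np.where(declined, mmse_0 - drop, mmse_0 + gain)

    adas_0 = np.clip(28.5 + 8.0 * (0.8 * rng.standard_normal(n) - 0.6 * Ystd), 0.0, 70.0)
    adas_12 = np.clip(adas_0 + 0.5 + 2.0 * rng.standard_normal(n) - 1.0 * Ystd, 0.0, 70.0)

    df = pd.DataFrame({
        "id": [f"P{i + 1:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "ahi": ahi,
        "sp_density": sp_density,
        "sp_duration_s": sp_duration,
        "sp_power_uv2": sp_power,
        "so_density": so_density,
        "so_duration_s": so_duration,
        "so_ptp_uv": so_ptp,
        "abeta42": abeta42,
        "ptau181": ptau181,
        "ttau": ttau,
        "ratio_ptau_abeta42": ptau181 / abeta42,
        "ratio_ttau_abeta42": ttau / abeta42,
        "mmse_0": mmse["0"],
        "mmse_12": mmse["12"],
        "mmse_24": mmse["24"],
        "mmse_36": mmse["36"],
        "adascog_0": adas_0,
        "adascog_12": adas_12,
        "exposure": X,
        "moderator": W,
        "mediator": M,
        "outcome": Y,
    })
    df["mmse_decline"] = (df["mmse_36"] < df["mmse_0"]).astype(int)
    return df
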