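"""Sleep-cycle segmentation, rule-based artifact tagging, and sleep architecture.

Sleep cycles follow the classic criterion: a period of NREM sleep of at
least 15 min followed by a REM period of at least 5 min, relaxed to 1 min
of REM for the first cycle of the night. Artifact tagging covers the two
aberration classes routinely excluded from microarchitecture analyses:
poor/dysfunctional signal lasting more than 1 s (flatlining, signal
popping / high-amplitude muscle bursts) and, optionally, micro-arousal-like
abrupt spectral shifts sustained for more than 3 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import (
    EPOCH_LEN_S,
    ArtifactMask,
    EEGRecording,
    Hypnogram,
    SLEEP_STAGES,
)


@dataclass
class SleepCycle:
    """One NREM→REM cycle; ``end_epoch`` is exclusive."""

    index: int
    start_epoch: int
    end_epoch: int
    nrem_min: float
    rem_min: float


@dataclass
class SleepArchitecture:
    """Whole-night staging summary (all durations in minutes)."""

    tst_min: float
    time_in_bed_min: float
    sleep_efficiency_pct: float
    sol_min: float              # sleep-onset latency; NaN if no sleep
    waso_min: float
    stage_min: dict = field(default_factory=dict)      # N1/N2/N3/REM minutes
    stage_pct_tst: dict = field(default_factory=dict)  # NaN when TST == 0
    n2n3_pct_tst: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "tst_min": self.tst_min,
            "time_in_bed_min": self.time_in_bed_min,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
            "sol_min": self.sol_min,
            "waso_min": self.waso_min,
            "n2n3_pct_tst": self.n2n3_pct_tst,
        }
        for s in ("N1", "N2", "N3", "REM"):
            d[f"{s.lower()}_min"] = self.stage_min.get(s, 0.0)
            d[f"{s.lower()}_pct_tst"] = self.stage_pct_tst.get(s, float("nan"))
        return d


def identify_sleep_cycles(hypnogram: Hypnogram,
                          nrem_min_required: float = 15.0,
                          rem_min_required: float = 5.0,
                          first_cycle_rem_min: float = 1.0) -> list[SleepCycle]:
    """Segment the hypnogram into qualifying NREM→REM cycles.

    Cycles are taken greedily from the start of the night. A candidate is a
    run of NREM epochs (interleaved W/N1 tolerated but not counted toward
    the NREM requirement) followed by a run of REM epochs ending at the
    next N2/N3 epoch. Candidates failing the minute thresholds contribute
    their epochs to no cycle.
    """
    stages = hypnogram.stages
    n = len(stages)
    epm = EPOCH_LEN_S / 60.0  # minutes per epoch
    cycles: list[SleepCycle] = []
    i = 0
    while i < n:
        # find start of NREM phase
        while i < n and stages[i] not in ("N2", "N3"):
            i += 1
        if i >= n:
            break
        start = i
        nrem_count = 0
        while i < n and stages[i] != "REM":
            if stages[i] in ("N2", "N3"):
                nrem_count += 1
            i += 1
        if i >= n:
            break  # night ends without REM: no qualifying cycle
        rem_count = 0
        while i < n and stages[i] not in ("N2", "N3"):
            if stages[i] == "REM":
                rem_count += 1
            i += 1
        end = i  # exclusive; first epoch of the next NREM phase (or n)
        rem_needed = first_cycle_rem_min if not cycles else rem_min_required
        if nrem_count * epm >= nrem_min_required and rem_count * epm >= rem_needed:
            cycles.append(
                SleepCycle(
                    index=len(cycles) + 1,
                    start_epoch=start,
                    end_epoch=end,
                    nrem_min=nrem_count * epm,
                    rem_min=rem_count * epm,
                )
            )
    return cycles


@dataclass
class ArtifactParams:
    """Thresholds for rule-based artifact tagging.

    flatline: |x| < ``flatline_eps_uv`` sustained strictly longer than
    ``flatline_min_s``. Popping/muscle: the 0.2-s local peak amplitude
    exceeds ``popping_cap_uv`` for longer than ``popping_min_s``.
    The spectral-shift (micro-arousal) rule compares high-band (8-30 Hz) to
    low-band (0.5-8 Hz) power in a sliding window against a multiple of its
    NREM median; it approximates what sleep scorers tag visually and is off
    by default.
    """

    flatline_eps_uv: float = 1.0
    flatline_min_s: float = 1.0
    popping_cap_uv: float = 300.0
    popping_min_s: float = 1.0
    popping_window_s: float = 0.2
    freq_shift_enabled: bool = False
    freq_shift_ratio: float = 4.0
    freq_shift_min_s: float = 3.0
    freq_shift_window_s: float = 3.0
    freq_shift_step_s: float = 0.5


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as (start, end-exclusive)."""
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


def _rolling_max_abs(x: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling maximum of |x| (edges use shrunken windows)."""
    from scipy.ndimage import maximum_filter1d

    return maximum_filter1d(np.abs(x), size=max(w, 1), mode="nearest")


def tag_artifacts(recording: EEGRecording, hypnogram: Hypnogram,
                  params: ArtifactParams | None = None,
                  channels: list[str] | None = None) -> ArtifactMask:
    """Tag flatline, popping, and (optionally) spectral-shift intervals."""
    params = params or ArtifactParams()
    channels = channels or recording.channels
    fs = recording.sampling_rate_hz
    mask = ArtifactMask()
    for ch in channels:
        x = recording.get(ch)
        n = len(x)
        # flatline: |x| < eps sustained > flatline_min_s
        flat = np.abs(x) < params.flatline_eps_uv
        for i0, i1 in _runs(flat):
            if (i1 - i0) / fs > params.flatline_min_s:
                mask.add(ch, i0 / fs, i1 / fs)
        # popping / muscle: local peak amplitude above cap sustained > min_s
        w = int(round(params.popping_window_s * fs))
        pop = _rolling_max_abs(x, w) > params.popping_cap_uv
        for i0, i1 in _runs(pop):
            if (i1 - i0) / fs > params.popping_min_s:
                mask.add(ch, i0 / fs, i1 / fs)
        if params.freq_shift_enabled:
            for s, e in _freq_shift_intervals(x, fs, hypnogram, params):
                mask.add(ch, s, e)
    return mask.merged()


def _freq_shift_intervals(x: np.ndarray, fs: float, hypnogram: Hypnogram,
                          params: ArtifactParams) -> list[tuple[float, float]]:
    win = int(round(params.freq_shift_window_s * fs))
    step = int(round(params.freq_shift_step_s * fs))
    n = len(x)
    if n < win:
        return []
    starts = np.arange(0, n - win + 1, step)
    ratios = np.full(len(starts), np.nan)
    for j, i0 in enumerate(starts):
        seg = x[i0 : i0 + win]
        f, p = sps.periodogram(seg, fs)
        low = p[(f >= 0.5) & (f < 8.0)].sum()
        high = p[(f >= 8.0) & (f <= 30.0)].sum()
        ratios[j] = high / low if low > 0 else np.inf
    centers = (starts + win / 2) / fs
    in_nrem = np.array([hypnogram.stage_at(t) in ("N2", "N3") for t in centers])
    if not in_nrem.any():
        return []
    ref = np.nanmedian(ratios[in_nrem])
    hot = ratios > params.freq_shift_ratio * ref
    out = []
    for j0, j1 in _runs(hot):
        s = starts[j0] / fs
        e = (starts[j1 - 1] + win) / fs
        if e - s > params.freq_shift_min_s:
            out.append((s, min(e, n / fs)))
    return out


def compute_sleep_architecture(hypnogram: Hypnogram,
                               lights_off_s: float = 0.0,
                               lights_on_s: float | None = None) -> SleepArchitecture:
    """Standard staging summary: TST, efficiency, SOL, WASO, stage minutes/%."""
    if lights_on_s is None:
        lights_on_s = hypnogram.duration_s
    if lights_on_s <= lights_off_s:
        raise ValueError("lights_on_s must exceed lights_off_s")
    tib_min = (lights_on_s - lights_off_s) / 60.0
    epm = EPOCH_LEN_S / 60.0
    stages = hypnogram.stages
    stage_min = {s: 0.0 for s in ("N1", "N2", "N3", "REM")}
    first_sleep: int | None = None
    waso = 0.0
    for i, s in enumerate(stages):
        t0 = i * EPOCH_LEN_S
        if t0 < lights_off_s or t0 >= lights_on_s:
            continue
        if s in SLEEP_STAGES:
            stage_min[s] += epm
            if first_sleep is None:
                first_sleep = i
        elif s == "W" and first_sleep is not None:
            waso += epm
    tst = sum(stage_min.values())
    eff = 100.0 * tst / tib_min if tib_min > 0 and tst > 0 else 0.0
    if first_sleep is None:
        sol = float("nan")
        warnings.warn("no sleep epochs: SOL and stage percentages undefined")
    else:
        sol = (first_sleep * EPOCH_LEN_S - lights_off_s) / 60.0
    if tst > 0:
        pct = {s: 100.0 * m / tst for s, m in stage_min.items()}
        n2n3 = pct["N2"] + pct["N3"]
    else:
        pct = {s: float("nan") for s in stage_min}
        n2n3 = float("nan")
    return SleepArchitecture(
        tst_min=tst,
        time_in_bed_min=tib_min,
        sleep_efficiency_pct=eff,
        sol_min=sol,
        waso_min=waso,
        stage_min=stage_min,
        stage_pct_tst=pct,
        n2n3_pct_tst=n2n3,
    )
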