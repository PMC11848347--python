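import numpy as np
import pytest

import sleepmicro as sm


@pytest.fixture(scope="session")
def mixed_night():
    """15-min recording with mixed stages, injected events, and artifacts.

    Stages: 10 N2, 4 N3, 4 REM, 4 N2, 4 W, 4 N2 (30 epochs, 900 s).
    Spindles on C3, SOs on F3, one flatline and one burst artifact on each.
    """
    stages = (["N2"] * 10 + ["N3"] * 4 + ["REM"] * 4 + ["N2"] * 4
              + ["W"] * 4 + ["N2"] * 4)
    rng = np.random.default_rng(11)
    plan = sm.random_event_plan("spindle", "C3", 20, stages, rng,
                                freq_hz=12.0, amplitude_uv=40.0, duration_s=1.0)
    plan += sm.random_event_plan("SO", "F3", 25, stages, rng,
                                 freq_hz=0.8, amplitude_uv=150.0)
    artifacts = [
        sm.ArtifactSpec("flatline", "C3", 95.0, 2.5),
        sm.ArtifactSpec("burst", "C3", 210.0, 4.0, amplitude_uv=800.0),
        sm.ArtifactSpec("flatline", "F3", 155.0, 2.0),
        sm.ArtifactSpec("burst", "F3", 310.0, 5.0, amplitude_uv=800.0),
    ]
    # drop planned events colliding with an artifact window
    def clear(ev):
        return not any(a.channel == ev.channel
                       and ev.start_s < a.start_s + a.duration_s + 1.0
                       and a.start_s - 1.0 < ev.end_s
                       for a in artifacts)
    plan = [ev for ev in plan if clear(ev)]
    rec, hyp, truth = sm.generate_eeg(
        900.0, 256.0, ["F3", "C3"], plan, artifacts,
        background_noise_sd=5.0, stages=stages, seed=11,
    )
    return {"recording": rec, "hypnogram": hyp, "truth": truth,
            "artifacts": artifacts}


@pytest.fixture(scope="session")
def mixed_night_detection(mixed_night):
    return sm.run_detection(
        mixed_night["recording"], mixed_night["hypnogram"],
        spindle_channels=["C3"], so_channels=["F3"],
    )
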