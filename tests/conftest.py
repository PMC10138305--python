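import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from mimil.preprocess import ConditionSpan, DetectionWindow, RawRecording
from mimil.synthdata import SynthConfig, generate_cohort


def make_recording(
    duration_s=60.0,
    fs=1250.0,
    participant_id="p0",
    group="CWNS",
    dataset="free_speech",
    events=(),
    spans=None,
    seed=0,
):
    """Small synthetic-noise recording for structural tests."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    channels = {c: rng.normal(0, 1, n) for c in ("ecg", "eda", "rsp")}
    if spans is None:
        spans = [ConditionSpan("baseline", 0.0, duration_s)]
    return RawRecording(
        participant_id=participant_id,
        group=group,
        dataset=dataset,
        sample_rate=fs,
        channels=channels,
        events=list(events),
        condition_spans=spans,
    )


def make_window(channels=None, fs=1250.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    n = int(20 * fs)
    if channels is None:
        channels = {c: rng.normal(0, 1, n) for c in ("ecg", "eda", "rsp")}
    defaults = dict(
        participant_id="p0", group="CWNS", window_kind="baseline", start_s=0.0
    )
    defaults.update(kw)
    return DetectionWindow(sample_rate=fs, channels=channels, **defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2 subjects with short spans: fast, full-structure cohort."""
    cfg = SynthConfig(
        n_subjects_per_group=2, seed=42, baseline_duration_s=60.0, task_duration_s=65.0
    )
    return cfg, *generate_cohort(cfg)
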