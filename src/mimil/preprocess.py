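"""Ingestion-side preprocessing: filtering, detection windows, segment grids.

A recording is one participant's synchronized ECG / EDA / respiratory-effort
session sampled at 1250 Hz, annotated with condition spans (baseline vs. task)
and, for the scripted protocol, picture-onset event markers.  The unit the
downstream classifier consumes is a 20 s *detection window*, decomposed into
nineteen 2 s segments with 1 s overlap (the instances of a MIL bag).

All window and segment coordinates are half-open ``[start, end)`` in seconds,
0-based within the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

TARGET_RATE_HZ = 1250.0
WINDOW_DURATION_S = 20.0
SEGMENT_DURATION_S = 2.0
SEGMENT_HOP_S = 1.0
#: segments per 20 s window: floor((20 - 2) / 1) + 1
N_SEGMENTS = 19

CHANNELS = ("ecg", "eda", "rsp")

# scripted-protocol anchoring: the picture onset lands at window time-step 13
# of window 1, and window 2 starts 18 s after window 1.
W1_PRE_ONSET_S = 13.0
W2_OFFSET_FROM_W1_S = 18.0


class FormatError(ValueError):
    """Raised when an input file violates the documented signal format."""


@dataclass(frozen=True)
class EventMarker:
    kind: str  # currently only "picture_onset"
    onset_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")


@dataclass(frozen=True)
class ConditionSpan:
    condition: str  # "baseline" | "task"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("condition span must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RawRecording:
    """One participant's multichannel session plus annotations."""

    participant_id: str
    group: str  # "CWS" | "CWNS"
    dataset: str  # "scripted" | "free_speech"
    sample_rate: float
    channels: Dict[str, np.ndarray]
    events: List[EventMarker] = field(default_factory=list)
    condition_spans: List[ConditionSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.group not in ("CWS", "CWNS"):
            raise ValueError(f"unknown group {self.group!r}")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"channel lengths differ: {lengths}")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing channels: {missing}")
        dur = self.duration_s
        for ev in self.events:
            if ev.onset_s > dur:
                raise ValueError(f"event at {ev.onset_s}s beyond recording end {dur}s")
        spans = sorted(self.condition_spans, key=lambda s: s.start_s)
        for a, b in zip(spans, spans[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"overlapping condition spans {a} / {b}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def spans_for(self, condition: str) -> List[ConditionSpan]:
        return [s for s in self.condition_spans if s.condition == condition]


@dataclass
class DetectionWindow:
    """A 20 s multichannel slice, the MIL bag skeleton."""

    participant_id: str
    group: str
    window_kind: str  # "baseline" | "scripted_w1" | "scripted_w2" | "free_speech"
    start_s: float
    sample_rate: float
    channels: Dict[str, np.ndarray]
    duration_s: float = WINDOW_DURATION_S

    def __post_init__(self) -> None:
        n_expected = int(round(self.duration_s * self.sample_rate))
        for name, series in self.channels.items():
            if len(series) != n_expected:
                raise ValueError(
                    f"channel {name!r} has {len(series)} samples, "
                    f"expected {n_expected} for a {self.duration_s}s window"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))


@dataclass
class SegmentGrid:
    """A window cut into 19 overlapping 2 s multichannel segments."""

    window: DetectionWindow
    #: per segment, per channel slice; segment i covers seconds [i, i+2)
    segments: List[Dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise ValueError(f"expected {N_SEGMENTS} segments, got {len(self.segments)}")

    @property
    def segment_starts_s(self) -> np.ndarray:
        return np.arange(N_SEGMENTS) * SEGMENT_HOP_S


def highpass_filter(
    x: np.ndarray, sample_rate: float, cutoff_hz: float = 0.05, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes DC and baseline drift.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the squared Butterworth response and the phase is zero.
    """
    nyq = sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq})")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def filter_recording(
    rec: RawRecording, cutoff_hz: float = 0.05, order: int = 2
) -> RawRecording:
    """Return a copy of ``rec`` with every channel high-pass filtered."""
    channels = {
        name: highpass_filter(series, rec.sample_rate, cutoff_hz, order)
        for name, series in rec.channels.items()
    }
    return RawRecording(
        participant_id=rec.participant_id,
        group=rec.group,
        dataset=rec.dataset,
        sample_rate=rec.sample_rate,
        channels=channels,
        events=list(rec.events),
        condition_spans=list(rec.condition_spans),
    )


def _slice_window(rec: RawRecording, start_s: float, kind: str) -> DetectionWindow:
    fs = rec.sample_rate
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(WINDOW_DURATION_S * fs))
    channels = {name: series[i0:i1].copy() for name, series in rec.channels.items()}
    return DetectionWindow(
        participant_id=rec.participant_id,
        group=rec.group,
        window_kind=kind,
        start_s=start_s,
        sample_rate=fs,
        channels=channels,
    )


def extract_session_windows(
    rec: RawRecording,
    condition: str,
    hop_s: float = 15.0,
    duration_s: float = WINDOW_DURATION_S,
) -> List[DetectionWindow]:
    """Cut hop-strided 20 s windows out of every span of ``condition``.

    Window i of a span starts at ``span.start_s + i * hop_s``; only windows
    lying fully inside the span are kept, so a span of length T yields
    ``floor((T - duration) / hop) + 1`` windows.
    """
    kind = "baseline" if condition == "baseline" else "free_speech"
    out: List[DetectionWindow] = []
    for span in rec.spans_for(condition):
        if span.duration_s < duration_s - 1e-9:
            warnings.warn(
                f"{rec.participant_id}: {condition} span of {span.duration_s:.1f}s "
                f"is shorter than {duration_s}s; no windows extracted"
            )
            continue
        n = int(np.floor((span.duration_s - duration_s) / hop_s + 1e-9)) + 1
        for i in range(n):
            out.append(_slice_window(rec, span.start_s + i * hop_s, kind))
    return out


def extract_scripted_windows(
    rec: RawRecording,
) -> List[Tuple[DetectionWindow, DetectionWindow]]:
    """Per picture onset t_p, the (window-1, window-2) pair of the scripted task.

    Window 1 covers ``[t_p - 13, t_p + 7)`` so the onset lands at window
    time-step 13; window 2 covers ``[t_p + 5, t_p + 25)`` (speaking after the
    prompt).  Onsets too close to the recording edges are skipped.
    """
    onsets = sorted(ev.onset_s for ev in rec.events if ev.kind == "picture_onset")
    pairs = []
    for t_p in onsets:
        w1_start = t_p - W1_PRE_ONSET_S
        w2_start = w1_start + W2_OFFSET_FROM_W1_S
        if w1_start < 0 or w2_start + WINDOW_DURATION_S > rec.duration_s + 1e-9:
            warnings.warn(
                f"{rec.participant_id}: picture onset at {t_p}s too close to the "
                "recording edge; window pair skipped"
            )
            continue
        pairs.append(
            (
                _slice_window(rec, w1_start, "scripted_w1"),
                _slice_window(rec, w2_start, "scripted_w2"),
            )
        )
    return pairs


def segment_window(window: DetectionWindow) -> SegmentGrid:
    """Cut a 20 s window into 19 ordered 2 s segments with 1 s hop."""
    if abs(window.duration_s - WINDOW_DURATION_S) > 1e-9:
        raise ValueError(f"expected a {WINDOW_DURATION_S}s window")
    fs = window.sample_rate
    seg_len = int(round(SEGMENT_DURATION_S * fs))
    hop = int(round(SEGMENT_HOP_S * fs))
    segments = []
    for i in range(N_SEGMENTS):
        i0 = i * hop
        segments.append(
            {name: series[i0 : i0 + seg_len] for name, series in window.channels.items()}
        )
    return SegmentGrid(window=window, segments=segments)
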