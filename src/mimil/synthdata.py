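"""Synthetic weakly-labeled physiological cohorts with known ground truth.

The generator emulates the statistical structure the classification problem
poses, not physiological morphology: per-subject baseline offsets in heart
rate, tonic EDA and breathing rate; a baseline span followed by a speaking
task span; and, for subjects of the stuttering group (CWS), sparse 2-5 s
class-indicative patterns injected at uniformly random onsets of each task
window — independently per modality (each modality carries the pattern with
``modality_presence_prob``; at least one always does), hence asynchronous and
modality-disjoint.  Only the bag (window) label is observable downstream; the
injected onsets and the derived instance labels are emitted as ground truth
for testing.

Pattern motifs:

* EDA — a smooth compact-support ramp-up bump (arousal transition),
* HR — a biphasic dip-then-rise of the instantaneous rate (freezing response
  followed by recovery), applied to the beat-interval process,
* RSP — an elevation of the instantaneous breathing rate.

Pattern amplitudes are expressed as multiples of a per-modality *effect unit*
chosen to approximate background segment-level variability, so one knob scales
the difficulty of the whole problem; amplitude 0 yields statistically
indistinguishable groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocess import (
    N_SEGMENTS,
    SEGMENT_DURATION_S,
    WINDOW_DURATION_S,
    ConditionSpan,
    EventMarker,
    RawRecording,
)

PATTERN_KINDS = {
    "eda": "eda_ramp",
    "hr": "hr_freeze_rise",
    "rsp_rate": "rsp_rate_up",
    "rsp_amp": "rsp_amp_up",
}

#: physical scale of one unit of pattern amplitude, per modality.  Chosen to
#: approximate the background segment-to-segment variability of each LLD.
EFFECT_UNITS = {
    "eda": 0.10,  # microsiemens
    "hr": 4.0,  # beats/min
    "rsp_rate": 2.0,  # breaths/min
    "rsp_amp": 0.15,  # relative amplitude (fraction of breath depth)
}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic cohort."""

    n_subjects_per_group: int = 20
    seed: int = 0
    baseline_duration_s: float = 240.0
    task_duration_s: Optional[float] = None  # default 300 (free speech) / per-trial (scripted)
    dataset_style: str = "free_speech"  # or "scripted"
    pattern_duration_range_s: Tuple[float, float] = (2.0, 5.0)
    #: per-modality effect sizes, multiples of EFFECT_UNITS
    pattern_amplitude: Dict[str, float] = field(
        default_factory=lambda: {m: 4.0 for m in PATTERN_KINDS}
    )
    modality_presence_prob: float = 0.6
    n_pictures: int = 10  # scripted style only
    #: additive measurement-noise sd per channel (ecg in a.u., eda in uS, rsp relative)
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.05, "eda": 0.03, "rsp": 0.05}
    )
    #: sd of stable per-subject baseline offsets (hr bpm, eda uS, rsp_rate brpm)
    per_subject_offset_sd: Dict[str, float] = field(
        default_factory=lambda: {"hr": 8.0, "eda": 1.5, "rsp_rate": 3.0}
    )
    #: optional distinct low-amplitude freezing-first HR motif in CWNS windows
    cwns_motif_amplitude: float = 0.0
    #: class-neutral spontaneous transients (NS-SCR-like bumps, sighs, HR
    #: accelerations) occur in every subject of both groups, in baseline and
    #: task spans alike; rates in events/min
    spontaneous_rate_per_min: Dict[str, float] = field(
        default_factory=lambda: {"eda": 3.0, "hr": 3.0, "rsp_rate": 2.0, "rsp_amp": 1.5}
    )
    #: lognormal amplitude of spontaneous transients, in EFFECT_UNITS multiples
    spontaneous_amp_median: float = 1.2
    spontaneous_amp_sigma: float = 0.5
    #: trait arousal lability: stable per-subject lognormal multipliers on the
    #: transient-event rate and on response magnitude (labile vs. stabile
    #: responders).  The magnitude trait scales spontaneous *and* class-motif
    #: amplitudes alike, as individual reactivity does; absolute response size
    #: is therefore subject-confounded and only within-window contrast is
    #: class-informative.
    trait_rate_sigma: float = 0.6
    trait_amp_sigma: float = 0.25
    sample_rate: float = 1250.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modality_presence_prob <= 1.0:
            raise ValueError("modality_presence_prob must lie in [0, 1]")
        lo, hi = self.pattern_duration_range_s
        if not 0 < lo <= hi <= WINDOW_DURATION_S:
            raise ValueError("pattern durations must be positive and fit in a window")
        if self.baseline_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.dataset_style not in ("free_speech", "scripted"):
            raise ValueError(f"unknown dataset_style {self.dataset_style!r}")
        if any(v < 0 for v in self.pattern_amplitude.values()):
            raise ValueError("pattern amplitudes must be >= 0")

    @property
    def effective_task_duration_s(self) -> float:
        if self.task_duration_s is not None:
            return self.task_duration_s
        if self.dataset_style == "scripted":
            # onsets every 40 s, first at 15 s into the task, + tail for window 2
            return 15.0 + 40.0 * (self.n_pictures - 1) + 30.0
        # ten 20 s windows at 15 s hop per child — the same per-child window
        # count a ten-trial picture-viewing protocol yields
        return 160.0


@dataclass
class PatternEvent:
    modality: str
    kind: str
    onset_s: float  # within the window
    duration_s: float


@dataclass
class WindowTruth:
    participant_id: str
    group: str
    window_kind: str
    window_start_s: float
    patterns: List[PatternEvent]
    #: class-neutral spontaneous transients overlapping the window (diagnostics
    #: only; instance labels y_i refer to class-indicative patterns alone)
    distractors: List[PatternEvent] = field(default_factory=list)

    def instance_labels(self) -> Dict[str, np.ndarray]:
        """Per modality, y_i = 1 for segments overlapping a pattern (19-vector)."""
        out = {m: np.zeros(N_SEGMENTS, dtype=int) for m in PATTERN_KINDS}
        starts = np.arange(N_SEGMENTS, dtype=float)
        for p in self.patterns:
            overlap = (starts < p.onset_s + p.duration_s) & (starts + SEGMENT_DURATION_S > p.onset_s)
            out[p.modality][overlap] = 1
        return out

    def bag_label(self) -> int:
        """MIL assumption Y = max_i y_i over modalities and instances."""
        labels = self.instance_labels()
        return int(max(arr.max() for arr in labels.values()))


@dataclass
class GroundTruth:
    windows: List[WindowTruth]

    def for_participant(self, pid: str) -> List[WindowTruth]:
        return [w for w in self.windows if w.participant_id == pid]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "participant_id": w.participant_id,
                    "group": w.group,
                    "window_kind": w.window_kind,
                    "window_start_s": w.window_start_s,
                    "patterns": [
                        {
                            "modality": p.modality,
                            "kind": p.kind,
                            "onset_s": p.onset_s,
                            "duration_s": p.duration_s,
                        }
                        for p in w.patterns
                    ],
                }
                for w in self.windows
            ],
            indent=1,
        )


# ---------------------------------------------------------------------------
# pattern shapes
# ---------------------------------------------------------------------------

_RAMP_S = 0.25  # rise/fall time of the compact-support plateau bump


def _bump(t: np.ndarray, onset_s: float, duration_s: float) -> np.ndarray:
    """Smooth plateau bump: cosine rise over 0.25 s, plateau at 1, cosine fall.

    Compact support: exactly zero outside [onset, onset + duration].
    """
    ramp = min(_RAMP_S, duration_s / 4.0)
    u = t - onset_s
    out = np.zeros_like(t)
    rising = (u >= 0) & (u < ramp)
    out[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / ramp))
    flat = (u >= ramp) & (u <= duration_s - ramp)
    out[flat] = 1.0
    falling = (u > duration_s - ramp) & (u <= duration_s)
    out[falling] = 0.5 * (1 - np.cos(np.pi * (duration_s - u[falling]) / ramp))
    return out


def _biphasic(t: np.ndarray, onset_s: float, duration_s: float) -> np.ndarray:
    """Dip-then-rise: -1 plateau over the first half, +1 over the second."""
    half = duration_s / 2.0
    return -_bump(t, onset_s, half) + _bump(t, onset_s + half, half)


def inject_pattern(
    series: np.ndarray,
    kind: str,
    onset_s: float,
    duration_s: float,
    amplitude: float,
    sample_rate: float,
) -> np.ndarray:
    """Additively inject one pattern motif; unchanged outside its support.

    ``series`` is the signal the motif modulates: the EDA trace itself for
    ``eda_ramp``, or an instantaneous-rate/amplitude series for the HR and RSP
    motifs (the generator integrates those into beat/breath trains afterwards).
    """
    n = len(series)
    if onset_s < 0 or onset_s + duration_s > n / sample_rate + 1e-9:
        raise ValueError("pattern does not fit inside the series")
    t = np.arange(n) / sample_rate
    if kind in ("eda_ramp", "rsp_rate_up", "rsp_amp_up"):
        shape = _bump(t, onset_s, duration_s)
    elif kind == "hr_freeze_rise":
        shape = _biphasic(t, onset_s, duration_s)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return series + amplitude * shape


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _ecg_from_rate(rate_bpm: np.ndarray, fs: float, rng: np.random.Generator,
                   noise_sd: float) -> np.ndarray:
    """Spike-train ECG whose beat times integrate the instantaneous rate."""
    phase = np.cumsum(rate_bpm / 60.0) / fs  # beats elapsed
    beat_idx = np.searchsorted(phase, np.arange(1, int(phase[-1]) + 1))
    ecg = rng.normal(0.0, noise_sd, size=len(rate_bpm))
    # triangular R spike, ~40 ms wide, amplitude 1
    half = max(1, int(0.02 * fs))
    spike = 1.0 - np.abs(np.arange(-half, half + 1)) / half
    for b in beat_idx:
        lo = max(0, b - half)
        hi = min(len(ecg), b + half + 1)
        ecg[lo:hi] += spike[lo - (b - half) : hi - (b - half)]
    return ecg


def _rsp_from_rate(rate_brpm: np.ndarray, amp_rel: np.ndarray, fs: float,
                   rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    phase = 2 * np.pi * np.cumsum(rate_brpm / 60.0) / fs
    return amp_rel * np.sin(phase) + rng.normal(0.0, noise_sd, size=len(rate_brpm))


def _slow_wander(n: int, fs: float, sd: float, rng: np.random.Generator,
                 corr_s: float = 30.0) -> np.ndarray:
    """Stationary slow drift: smoothed noise at a coarse grid, sd ``sd``."""
    step = max(1, int(corr_s * fs / 8))
    coarse = rng.normal(0.0, 1.0, size=n // step + 3)
    # cosine-interpolate the coarse grid for a smooth wander
    idx = np.arange(n) / step
    k = idx.astype(int)
    frac = idx - k
    w = 0.5 * (1 - np.cos(np.pi * frac))
    out = coarse[k] * (1 - w) + coarse[k + 1] * w
    return sd * out


def _task_window_starts(cfg: SynthConfig, task_start: float) -> List[Tuple[str, float]]:
    """(window_kind, start_s) of every task window that will be extracted."""
    out = []
    if cfg.dataset_style == "free_speech":
        task_len = cfg.effective_task_duration_s
        n = int(np.floor((task_len - WINDOW_DURATION_S) / 15.0 + 1e-9)) + 1
        for i in range(n):
            out.append(("free_speech", task_start + 15.0 * i))
    else:
        for k in range(cfg.n_pictures):
            t_p = task_start + 15.0 + 40.0 * k
            out.append(("scripted_w1", t_p - 13.0))
            out.append(("scripted_w2", t_p + 5.0))
    return out


def _generate_subject(
    cfg: SynthConfig, pid: str, group: str, rng: np.random.Generator
) -> Tuple[RawRecording, List[WindowTruth]]:
    fs = cfg.sample_rate
    base_len = cfg.baseline_duration_s
    task_len = cfg.effective_task_duration_s
    total_s = base_len + task_len
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # stable per-subject physiology (offsets persist across baseline and task)
    hr_base = 100.0 + rng.normal(0.0, cfg.per_subject_offset_sd["hr"])
    eda_base = 5.0 + rng.normal(0.0, cfg.per_subject_offset_sd["eda"])
    rsp_base = 25.0 + rng.normal(0.0, cfg.per_subject_offset_sd["rsp_rate"])

    hr_rate = hr_base + _slow_wander(n, fs, EFFECT_UNITS["hr"], rng, corr_s=20.0)
    rsp_rate = np.clip(
        rsp_base + _slow_wander(n, fs, EFFECT_UNITS["rsp_rate"], rng, corr_s=25.0), 6.0, 60.0
    )
    rsp_amp = np.clip(
        1.0 + _slow_wander(n, fs, EFFECT_UNITS["rsp_amp"], rng, corr_s=25.0), 0.2, None
    )
    eda = (
        eda_base
        + _slow_wander(n, fs, EFFECT_UNITS["eda"], rng, corr_s=40.0)
        + rng.normal(0.0, cfg.noise_sd["eda"], size=n)
    )

    # class-neutral spontaneous transients, both groups, whole recording;
    # signed for HR (accelerations and decelerations), positive bumps otherwise
    spont: List[Tuple[str, str, float, float]] = []
    lo, hi = cfg.pattern_duration_range_s
    trait_rate = np.exp(rng.normal(0.0, cfg.trait_rate_sigma))
    trait_amp = np.exp(rng.normal(0.0, cfg.trait_amp_sigma))
    for m, per_min in cfg.spontaneous_rate_per_min.items():
        n_ev = rng.poisson(trait_rate * per_min * total_s / 60.0)
        for _ in range(n_ev):
            dur = rng.uniform(lo, hi)
            onset = rng.uniform(0.0, total_s - dur)
            amp = (
                trait_amp
                * cfg.spontaneous_amp_median
                * np.exp(rng.normal(0.0, cfg.spontaneous_amp_sigma))
                * EFFECT_UNITS[m]
            )
            if m == "hr" and rng.random() < 0.5:
                amp = -amp
            spont.append((m, "spontaneous", onset, dur))
            if m == "eda":
                eda = inject_pattern(eda, "eda_ramp", onset, dur, amp, fs)
            elif m == "hr":
                hr_rate = inject_pattern(hr_rate, "rsp_rate_up", onset, dur, amp, fs)
            elif m == "rsp_rate":
                rsp_rate = inject_pattern(rsp_rate, "rsp_rate_up", onset, dur, amp, fs)
            else:
                rsp_amp = inject_pattern(rsp_amp, "rsp_amp_up", onset, dur, amp, fs)

    # task windows and pattern injection
    task_start = base_len
    modalities = list(PATTERN_KINDS)
    window_starts = _task_window_starts(cfg, task_start)
    injected: List[Tuple[str, str, float, float]] = []  # modality, kind, abs onset, dur
    for kind, w_start in window_starts:
        patterns: List[PatternEvent] = []
        if group == "CWS":
            present = rng.random(len(modalities)) < cfg.modality_presence_prob
            if not present.any():
                present[rng.integers(len(modalities))] = True
            for m, on in zip(modalities, present):
                if not on:
                    continue
                dur = rng.uniform(lo, hi)
                onset = rng.uniform(0.0, WINDOW_DURATION_S - dur)
                patterns.append(PatternEvent(m, PATTERN_KINDS[m], onset, dur))
        elif cfg.cwns_motif_amplitude > 0:
            # optional distinct low-amplitude freezing-first HR motif
            dur = rng.uniform(lo, hi)
            onset = rng.uniform(0.0, WINDOW_DURATION_S - dur)
            patterns.append(PatternEvent("hr", "hr_freeze_rise", onset, dur))
        for p in patterns:
            amp_mult = (
                cfg.pattern_amplitude[p.modality]
                if group == "CWS"
                else cfg.cwns_motif_amplitude
            )
            amp = trait_amp * amp_mult * EFFECT_UNITS[p.modality]
            abs_onset = w_start + p.onset_s
            if p.modality == "eda":
                eda = inject_pattern(eda, p.kind, abs_onset, p.duration_s, amp, fs)
            elif p.modality == "hr":
                hr_rate = inject_pattern(hr_rate, p.kind, abs_onset, p.duration_s, amp, fs)
            elif p.modality == "rsp_rate":
                rsp_rate = inject_pattern(rsp_rate, p.kind, abs_onset, p.duration_s, amp, fs)
            else:
                rsp_amp = inject_pattern(rsp_amp, p.kind, abs_onset, p.duration_s, amp, fs)
            injected.append((p.modality, p.kind, abs_onset, p.duration_s))

    # ground truth reflects actual signal content: overlapping windows also
    # contain their neighbours' injected patterns, clipped to the window
    def _clip_to_window(events, w_start):
        clipped = []
        for m, pkind, abs_onset, dur in events:
            a = max(abs_onset, w_start)
            b = min(abs_onset + dur, w_start + WINDOW_DURATION_S)
            if b - a > 1e-9:
                clipped.append(PatternEvent(m, pkind, a - w_start, b - a))
        return clipped

    truths: List[WindowTruth] = []
    for kind, w_start in window_starts:
        truths.append(
            WindowTruth(
                pid,
                group,
                kind,
                w_start,
                _clip_to_window(injected, w_start),
                distractors=_clip_to_window(spont, w_start),
            )
        )

    ecg = _ecg_from_rate(hr_rate, fs, rng, cfg.noise_sd["ecg"])
    rsp = _rsp_from_rate(rsp_rate, rsp_amp, fs, rng, cfg.noise_sd["rsp"])

    events = []
    if cfg.dataset_style == "scripted":
        events = [
            EventMarker("picture_onset", task_start + 15.0 + 40.0 * k)
            for k in range(cfg.n_pictures)
        ]
    rec = RawRecording(
        participant_id=pid,
        group=group,
        dataset=cfg.dataset_style,
        sample_rate=fs,
        channels={"ecg": ecg, "eda": eda, "rsp": rsp},
        events=events,
        condition_spans=[
            ConditionSpan("baseline", 0.0, base_len),
            ConditionSpan("task", base_len, total_s),
        ],
    )
    return rec, truths


def generate_cohort(cfg: SynthConfig) -> Tuple[List[RawRecording], GroundTruth]:
    """Generate the full cohort; deterministic under ``cfg.seed``.

    Per-subject random streams are derived from the master seed by fixed
    offsets, so a subject's data does not change when the cohort grows.
    """
    recs: List[RawRecording] = []
    truths: List[WindowTruth] = []
    for g_idx, group in enumerate(("CWS", "CWNS")):
        for s in range(cfg.n_subjects_per_group):
            pid = f"{group}_{s:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(g_idx, s))
            )
            rec, wt = _generate_subject(cfg, pid, group, rng)
            recs.append(rec)
            truths.extend(wt)
    return recs, GroundTruth(truths)
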