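"""End-to-end extraction: recordings -> filtered signals -> windows -> bags.

One participant is processed as: high-pass filter every channel, derive the
four LLD series once over the whole recording (so HR/RSP event detection sees
context beyond window edges), cut baseline and task detection windows, reduce
each window to its 19x6 HLD matrices per modality, form the participant's
baseline-score from all baseline segments, and emit raw and change-score
feature bags for every task window.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from .features import (
    FeatureBag,
    baseline_score,
    change_score_bag,
    compute_llds,
    raw_feature_bag,
    window_hlds,
)
from .preprocess import (
    DetectionWindow,
    RawRecording,
    extract_scripted_windows,
    extract_session_windows,
    filter_recording,
)


def task_windows(rec: RawRecording, hop_s: float = 15.0) -> List[DetectionWindow]:
    """The task-condition detection windows of one recording."""
    if rec.dataset == "scripted":
        out = []
        for w1, w2 in extract_scripted_windows(rec):
            out += [w1, w2]
        return out
    return extract_session_windows(rec, "task", hop_s=hop_s)


def extract_participant_bags(
    rec: RawRecording,
    cutoff_hz: float = 0.05,
    filter_order: int = 2,
    hop_s: float = 15.0,
    include_baseline_bags: bool = False,
    apply_filter: bool = True,
) -> Dict[str, List[FeatureBag]]:
    """Raw and change-score bags for every task window of one participant."""
    if apply_filter:
        rec = filter_recording(rec, cutoff_hz=cutoff_hz, order=filter_order)
    llds = compute_llds(rec)
    base_windows = extract_session_windows(rec, "baseline", hop_s=hop_s)
    base_hlds = [window_hlds(w, llds) for w in base_windows]
    y_b = baseline_score(base_hlds)
    out: Dict[str, List[FeatureBag]] = {"raw": [], "change_score": []}
    for w in task_windows(rec, hop_s=hop_s):
        hlds = window_hlds(w, llds)
        out["raw"].append(
            FeatureBag(
                participant_id=w.participant_id,
                group=w.group,
                window_kind=w.window_kind,
                representation="raw",
                matrices=hlds,
                window_start_s=w.start_s,
            )
        )
        out["change_score"].append(change_score_bag(w, y_b, hlds=hlds))
    if include_baseline_bags:
        out["baseline_raw"] = [
            raw_feature_bag(w, llds) for w in base_windows
        ]
    return out


def extract_cohort_bags(
    recs: Sequence[RawRecording], **kwargs
) -> Dict[str, List[FeatureBag]]:
    """Concatenate per-participant bags over a whole cohort."""
    out: Dict[str, List[FeatureBag]] = {}
    for rec in recs:
        bags = extract_participant_bags(rec, **kwargs)
        for key, lst in bags.items():
            out.setdefault(key, []).extend(lst)
    return out
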