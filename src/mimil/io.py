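"""File formats for cohorts of physiological recordings.

Signal files are delimited text with a header ``time_s,ecg,eda,rsp`` (comma or
tab separated), one row per sample.  Events files are CSV ``kind,onset_s``;
conditions files are CSV ``condition,start_s,end_s``.  A cohort manifest lists
one participant per row:
``participant_id,group,dataset,signal_path,events_path,conditions_path``
with paths interpreted relative to the manifest location.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .preprocess import (
    CHANNELS,
    TARGET_RATE_HZ,
    ConditionSpan,
    EventMarker,
    FormatError,
    RawRecording,
)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_signal(path, target_rate: float = TARGET_RATE_HZ):
    """Read a signal file; returns (channels dict, sample_rate).

    Recordings whose native rate differs from ``target_rate`` are linearly
    resampled; a mismatch above 1% logs a warning.
    """
    path = Path(path)
    df = _read_table(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time_s" not in cols:
        raise FormatError(f"{path}: missing 'time_s' column")
    missing = [c for c in CHANNELS if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing channel columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    native_rate = 1.0 / np.median(dt)
    channels = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
    if abs(native_rate - target_rate) / target_rate > 1e-6:
        if abs(native_rate - target_rate) / target_rate > 0.01:
            warnings.warn(
                f"{path}: native rate {native_rate:.2f} Hz differs from "
                f"{target_rate} Hz by more than 1%; resampling"
            )
        n_out = int(round(len(t) * target_rate / native_rate))
        t_new = t[0] + np.arange(n_out) / target_rate
        channels = {c: np.interp(t_new, t, v) for c, v in channels.items()}
    return channels, target_rate


def read_events(path) -> List[EventMarker]:
    df = pd.read_csv(path)
    return [EventMarker(kind=str(r.kind), onset_s=float(r.onset_s)) for r in df.itertuples()]


def read_conditions(path) -> List[ConditionSpan]:
    df = pd.read_csv(path)
    return [
        ConditionSpan(condition=str(r.condition), start_s=float(r.start_s), end_s=float(r.end_s))
        for r in df.itertuples()
    ]


def read_recording(
    signal_path,
    participant_id: str,
    group: str,
    dataset: str,
    events_path=None,
    conditions_path=None,
) -> RawRecording:
    """Load and validate one participant's recording from disk."""
    channels, rate = read_signal(signal_path)
    events = read_events(events_path) if events_path else []
    spans = read_conditions(conditions_path) if conditions_path else []
    if dataset == "scripted" and not events:
        warnings.warn(f"{participant_id}: scripted recording without picture-onset events")
    return RawRecording(
        participant_id=participant_id,
        group=group,
        dataset=dataset,
        sample_rate=rate,
        channels=channels,
        events=events,
        condition_spans=spans,
    )


def write_recording(rec: RawRecording, out_dir, stem: Optional[str] = None) -> dict:
    """Write one recording as signal/events/conditions text files.

    Returns the manifest row (paths relative to ``out_dir``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.participant_id
    t = np.arange(rec.n_samples) / rec.sample_rate
    sig = pd.DataFrame({"time_s": t, **{c: rec.channels[c] for c in CHANNELS}})
    signal_path = f"{stem}_signal.csv"
    sig.to_csv(out_dir / signal_path, index=False, float_format="%.6f")
    events_path = ""
    if rec.events:
        events_path = f"{stem}_events.csv"
        pd.DataFrame(
            {"kind": [e.kind for e in rec.events], "onset_s": [e.onset_s for e in rec.events]}
        ).to_csv(out_dir / events_path, index=False)
    conditions_path = f"{stem}_conditions.csv"
    pd.DataFrame(
        {
            "condition": [s.condition for s in rec.condition_spans],
            "start_s": [s.start_s for s in rec.condition_spans],
            "end_s": [s.end_s for s in rec.condition_spans],
        }
    ).to_csv(out_dir / conditions_path, index=False)
    return {
        "participant_id": rec.participant_id,
        "group": rec.group,
        "dataset": rec.dataset,
        "signal_path": signal_path,
        "events_path": events_path,
        "conditions_path": conditions_path,
    }


def write_manifest(rows: Iterable[dict], path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def save_bags(bags, path) -> None:
    """Serialize feature bags to an .npz container with a JSON metadata entry."""
    import json

    from .features import MODALITIES

    meta = [
        {
            "participant_id": b.participant_id,
            "group": b.group,
            "window_kind": b.window_kind,
            "representation": b.representation,
            "window_start_s": b.window_start_s,
        }
        for b in bags
    ]
    arrays = {
        m: np.stack([b.matrices[m] for b in bags]) for m in MODALITIES
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_bags(path):
    import json

    from .features import MODALITIES, FeatureBag

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = {m: data[m] for m in MODALITIES}
    return [
        FeatureBag(
            participant_id=row["participant_id"],
            group=row["group"],
            window_kind=row["window_kind"],
            representation=row["representation"],
            matrices={m: arrays[m][i] for m in MODALITIES},
            window_start_s=row["window_start_s"],
        )
        for i, row in enumerate(meta)
    ]


def export_bags_csv(bags, path) -> None:
    """Flat CSV export: one row per window, 456 (raw) or 152 (change) columns."""
    from .features import feature_names
    from .preprocess import N_SEGMENTS

    names = feature_names(bags[0].representation)
    cols = [f"t{t:02d}_{n}" for t in range(N_SEGMENTS) for n in names]
    X = np.stack([b.flatten().ravel() for b in bags])
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "participant_id", [b.participant_id for b in bags])
    df.insert(1, "group", [b.group for b in bags])
    df.insert(2, "window_kind", [b.window_kind for b in bags])
    df.to_csv(path, index=False)


def read_manifest(path) -> List[RawRecording]:
    """Load every participant listed in a cohort manifest."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    base = path.parent
    recs = []
    for r in df.itertuples():
        recs.append(
            read_recording(
                base / r.signal_path,
                participant_id=str(r.participant_id),
                group=str(r.group),
                dataset=str(r.dataset),
                events_path=(base / r.events_path) if r.events_path else None,
                conditions_path=(base / r.conditions_path) if r.conditions_path else None,
            )
        )
    return recs
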