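"""Feature engineering: low/high-level descriptors and change-score bags.

Four low-level descriptors (LLDs) are derived from the three raw channels —
instantaneous heart rate (HR, from ECG R-peaks), electrodermal activity (EDA,
the filtered channel itself), respiratory rate and respiratory amplitude
(RSP-rate / RSP-amp, from breath peaks of the effort signal).  Each LLD is a
1250 Hz series, so every 2 s segment holds 2500 values.  Six high-level
descriptor (HLD) functionals — min, max, std, var, mean, median — summarize
each segment, giving a 19x6 instance matrix per modality and 19x24 per window.

Change-score bags replace each segment's 6-dim HLD vector (the *post-score*
Y_t) by its Euclidean distance to and cosine similarity with the participant's
*baseline-score* Y_b, the mean HLD vector over all baseline-condition
segments.  This referencing removes stable between-subject offsets: the bag
carries how far a child's response moved from their own neutral state rather
than its absolute level.

HR and RSP instantaneous series are sample-and-hold step functions between
detected events, which defines an LLD value at every 0.8 ms tick without
inventing interpolation dynamics.  Variance and std use the population
convention (divide by n), so var == std**2 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .preprocess import (
    N_SEGMENTS,
    SEGMENT_DURATION_S,
    SEGMENT_HOP_S,
    DetectionWindow,
    RawRecording,
    SegmentGrid,
)

#: fixed modality order used everywhere a bag is flattened
MODALITIES = ("eda", "hr", "rsp_amp", "rsp_rate")
FUNCTIONALS = ("min", "max", "std", "var", "mean", "median")
N_RAW_FEATURES = len(MODALITIES) * len(FUNCTIONALS)  # 24
N_CHANGE_FEATURES = len(MODALITIES) * 2  # 8
CHANGE_COLUMNS = ("euclidean", "cosine")


# ---------------------------------------------------------------------------
# low-level descriptors
# ---------------------------------------------------------------------------


def detect_r_peaks(ecg: np.ndarray, sample_rate: float) -> np.ndarray:
    """R-peak sample indices via band-pass + amplitude threshold.

    The ECG is band-passed to the QRS band, candidate peaks must exceed
    mean + 2*std of the band-passed trace, and a 250 ms refractory period
    suppresses double detections.  Simple but adequate for clean and
    synthetic ECG; swap in a dedicated detector for ambulatory data.
    """
    ecg = np.asarray(ecg, dtype=float)
    high = min(30.0, 0.45 * sample_rate)
    sos = sps.butter(2, [5.0, high], btype="bandpass", fs=sample_rate, output="sos")
    band = sps.sosfiltfilt(sos, ecg)
    thresh = band.mean() + 2.0 * band.std()
    peaks, _ = sps.find_peaks(band, height=thresh, distance=int(0.25 * sample_rate))
    return peaks


def _sample_and_hold(
    n: int, event_idx: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Step function over n samples: value[k] holds on [event_idx[k], event_idx[k+1])."""
    out = np.empty(n, dtype=float)
    if len(values) == 0:
        out.fill(np.nan)
        return out
    edges = np.concatenate(([0], event_idx[1:], [n])) if len(event_idx) else [0, n]
    # hold value k between event k and event k+1; extend first/last to the edges
    pos = 0
    for k, v in enumerate(values):
        end = int(edges[k + 1]) if k + 1 < len(edges) else n
        out[pos:end] = v
        pos = end
    if pos < n:
        out[pos:] = values[-1]
    return out


def instantaneous_hr(
    ecg: np.ndarray, sample_rate: float, fallback_bpm: Optional[float] = None
) -> Tuple[np.ndarray, bool]:
    """Full-length instantaneous HR (beats/min) from an ECG trace.

    HR on ``[r_k, r_{k+1})`` is ``60 / RR_k``; the first/last values are held
    to the edges.  Returns ``(series, ok)`` — when fewer than two R-peaks are
    found the series is filled with ``fallback_bpm`` (or NaN) and ok=False.
    """
    ecg = np.asarray(ecg, dtype=float)
    peaks = detect_r_peaks(ecg, sample_rate)
    if len(peaks) < 2:
        fill = np.nan if fallback_bpm is None else fallback_bpm
        return np.full(len(ecg), fill), False
    rr_s = np.diff(peaks) / sample_rate
    hr = 60.0 / rr_s
    return _sample_and_hold(len(ecg), peaks[:-1], hr), True


def detect_breaths(rsp: np.ndarray, sample_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    """(peak indices, trough indices) of the smoothed respiratory effort."""
    rsp = np.asarray(rsp, dtype=float)
    sos = sps.butter(2, 1.5, btype="lowpass", fs=sample_rate, output="sos")
    smooth = sps.sosfiltfilt(sos, rsp)
    min_dist = int(0.8 * sample_rate)  # breaths faster than 75/min are implausible
    prom = 0.25 * smooth.std()
    peaks, _ = sps.find_peaks(smooth, distance=min_dist, prominence=prom)
    troughs, _ = sps.find_peaks(-smooth, distance=min_dist, prominence=prom)
    return peaks, troughs


def instantaneous_rsp(
    rsp: np.ndarray,
    sample_rate: float,
    fallback: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """(RSP-rate breaths/min, RSP-amp peak-to-trough) step series from effort.

    The rate over a breath interval ``[p_k, p_{k+1})`` is ``60 / T_k``; the
    amplitude is the peak value minus the minimum of the effort between the
    two peaks (the enclosing breath's trough).
    """
    rsp = np.asarray(rsp, dtype=float)
    n = len(rsp)
    peaks, _troughs = detect_breaths(rsp, sample_rate)
    if len(peaks) < 2:
        fill = (np.nan, np.nan) if fallback is None else fallback
        return np.full(n, fill[0]), np.full(n, fill[1]), False
    periods_s = np.diff(peaks) / sample_rate
    rate = 60.0 / periods_s
    amp = np.empty(len(peaks) - 1)
    for k in range(len(peaks) - 1):
        trough = rsp[peaks[k] : peaks[k + 1] + 1].min()
        amp[k] = rsp[peaks[k]] - trough
    return (
        _sample_and_hold(n, peaks[:-1], rate),
        _sample_and_hold(n, peaks[:-1], amp),
        True,
    )


def compute_hr_lld(
    ecg: np.ndarray,
    sample_rate: float,
    segment: Optional[slice] = None,
    fallback_bpm: Optional[float] = None,
) -> np.ndarray:
    """HR LLD for one 2 s segment, computed with whatever context ``ecg`` carries."""
    series, ok = instantaneous_hr(ecg, sample_rate, fallback_bpm)
    if not ok:
        warnings.warn("no detectable R-peaks; HR filled with fallback")
    return series[segment] if segment is not None else series


def compute_eda_lld(eda: np.ndarray) -> np.ndarray:
    """EDA LLD is the (filtered) channel itself."""
    return np.asarray(eda, dtype=float)


def compute_rsp_llds(
    rsp: np.ndarray,
    sample_rate: float,
    segment: Optional[slice] = None,
    fallback: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """(RSP-rate, RSP-amp) LLDs for one segment with context."""
    rate, amp, ok = instantaneous_rsp(rsp, sample_rate, fallback)
    if not ok:
        warnings.warn("fewer than 2 breath peaks; RSP LLDs filled with fallback")
    if segment is not None:
        return rate[segment], amp[segment]
    return rate, amp


@dataclass
class LLDCache:
    """Full-recording LLD series, computed once per participant."""

    sample_rate: float
    series: Dict[str, np.ndarray]  # modality -> full-length array

    def window_segments(self, window: DetectionWindow) -> Dict[str, np.ndarray]:
        """Per modality, the (19, seg_len) matrix of segment slices of a window."""
        fs = self.sample_rate
        seg_len = int(round(SEGMENT_DURATION_S * fs))
        hop = int(round(SEGMENT_HOP_S * fs))
        w0 = int(round(window.start_s * fs))
        out = {}
        for m in MODALITIES:
            s = self.series[m]
            idx = w0 + np.arange(N_SEGMENTS)[:, None] * hop + np.arange(seg_len)[None, :]
            out[m] = s[idx]
        return out


def compute_llds(rec: RawRecording, fallback_bpm: float = 90.0) -> LLDCache:
    """Derive the four LLD series over an entire recording."""
    fs = rec.sample_rate
    hr, ok = instantaneous_hr(rec.channels["ecg"], fs, fallback_bpm)
    if not ok:
        warnings.warn(f"{rec.participant_id}: HR fallback used for whole recording")
    rate, amp, ok = instantaneous_rsp(rec.channels["rsp"], fs, fallback=(20.0, 0.0))
    if not ok:
        warnings.warn(f"{rec.participant_id}: RSP fallback used for whole recording")
    return LLDCache(
        sample_rate=fs,
        series={
            "eda": compute_eda_lld(rec.channels["eda"]),
            "hr": hr,
            "rsp_rate": rate,
            "rsp_amp": amp,
        },
    )


# ---------------------------------------------------------------------------
# high-level descriptors and bags
# ---------------------------------------------------------------------------


def hld_functionals(lld: np.ndarray) -> np.ndarray:
    """(min, max, std, var, mean, median) of one segment's LLD values."""
    x = np.asarray(lld, dtype=float)
    if x.size == 0:
        raise ValueError("empty LLD series")
    std = x.std()  # population convention
    return np.array([x.min(), x.max(), std, std**2, x.mean(), np.median(x)])


def _hld_matrix(segments: np.ndarray) -> np.ndarray:
    """HLD functionals row-wise over a (n_seg, seg_len) matrix -> (n_seg, 6)."""
    std = segments.std(axis=1)
    return np.column_stack(
        [
            segments.min(axis=1),
            segments.max(axis=1),
            std,
            std**2,
            segments.mean(axis=1),
            np.median(segments, axis=1),
        ]
    )


@dataclass
class FeatureBag:
    """The MIL input: one window's per-modality instance matrices + bag label.

    ``matrices[m]`` has shape (19, 6) for the raw representation or (19, 2)
    (Euclidean, cosine) for change-scores.  Labels are semantic:
    CWS = 1 (positive class), CWNS = 0.
    """

    participant_id: str
    group: str
    window_kind: str
    representation: str  # "raw" | "change_score"
    matrices: Dict[str, np.ndarray]
    window_start_s: float = 0.0

    def __post_init__(self) -> None:
        width = 6 if self.representation == "raw" else 2
        for m in MODALITIES:
            if m not in self.matrices:
                raise ValueError(f"bag missing modality {m!r}")
            if self.matrices[m].shape != (N_SEGMENTS, width):
                raise ValueError(
                    f"modality {m!r} matrix has shape {self.matrices[m].shape}, "
                    f"expected {(N_SEGMENTS, width)}"
                )

    @property
    def label(self) -> int:
        return 1 if self.group == "CWS" else 0

    def flatten(self) -> np.ndarray:
        """Modality-major, functional-minor row per segment; shape (19, 24) or (19, 8)."""
        return np.concatenate([self.matrices[m] for m in MODALITIES], axis=1)


def feature_names(representation: str = "raw") -> List[str]:
    """Column names of the flattened bag, matching :meth:`FeatureBag.flatten`."""
    cols = FUNCTIONALS if representation == "raw" else CHANGE_COLUMNS
    return [f"{m}_{c}" for m in MODALITIES for c in cols]


def window_hlds(
    grid_or_window, llds: Optional[LLDCache] = None
) -> Dict[str, np.ndarray]:
    """Per modality, the (19, 6) HLD matrix of one window.

    With an :class:`LLDCache` the segments are sliced out of full-recording
    LLD series (so HR/RSP event detection sees context beyond the window);
    otherwise LLDs are computed from the window's own 20 s of signal.
    """
    window = grid_or_window.window if isinstance(grid_or_window, SegmentGrid) else grid_or_window
    if llds is not None:
        seg = llds.window_segments(window)
    else:
        fs = window.sample_rate
        hr = compute_hr_lld(window.channels["ecg"], fs)
        rate, amp = compute_rsp_llds(window.channels["rsp"], fs)
        cache = LLDCache(
            sample_rate=fs,
            series={
                "eda": compute_eda_lld(window.channels["eda"]),
                "hr": hr,
                "rsp_rate": rate,
                "rsp_amp": amp,
            },
        )
        shifted = DetectionWindow(
            participant_id=window.participant_id,
            group=window.group,
            window_kind=window.window_kind,
            start_s=0.0,
            sample_rate=fs,
            channels=window.channels,
        )
        seg = cache.window_segments(shifted)
    return {m: _hld_matrix(seg[m]) for m in MODALITIES}


def raw_feature_bag(
    grid_or_window, llds: Optional[LLDCache] = None
) -> FeatureBag:
    """The 19x6-per-modality raw HLD bag of one window (19x24 flattened)."""
    window = grid_or_window.window if isinstance(grid_or_window, SegmentGrid) else grid_or_window
    return FeatureBag(
        participant_id=window.participant_id,
        group=window.group,
        window_kind=window.window_kind,
        representation="raw",
        matrices=window_hlds(grid_or_window, llds),
        window_start_s=window.start_s,
    )


def baseline_score(
    baseline_hlds: Sequence[Dict[str, np.ndarray]]
) -> Dict[str, np.ndarray]:
    """Per-modality mean HLD vector over all baseline segments (Y_b).

    ``baseline_hlds`` is a list of per-window (19, 6) HLD matrices, one dict
    per baseline window of the participant.
    """
    if not baseline_hlds:
        raise ValueError("baseline score needs at least one baseline window")
    out = {}
    for m in MODALITIES:
        stacked = np.concatenate([h[m] for h in baseline_hlds], axis=0)
        out[m] = stacked.mean(axis=0)
    return out


def change_scores(post: np.ndarray, base: np.ndarray) -> Tuple[float, float]:
    """(Euclidean distance, cosine similarity) between post- and baseline-score."""
    post = np.asarray(post, dtype=float)
    base = np.asarray(base, dtype=float)
    eucl = float(np.linalg.norm(post - base))
    np_ = np.linalg.norm(post)
    nb = np.linalg.norm(base)
    if np_ == 0.0 or nb == 0.0:
        warnings.warn("zero-norm vector in cosine similarity; set to 0")
        cos = 0.0
    else:
        cos = float(np.dot(post, base) / (np_ * nb))
    return eucl, cos


def change_score_bag(
    grid_or_window,
    baseline: Dict[str, np.ndarray],
    llds: Optional[LLDCache] = None,
    hlds: Optional[Dict[str, np.ndarray]] = None,
) -> FeatureBag:
    """The 19x2-per-modality change-score bag (19x8 flattened) of one window."""
    window = grid_or_window.window if isinstance(grid_or_window, SegmentGrid) else grid_or_window
    if hlds is None:
        hlds = window_hlds(grid_or_window, llds)
    matrices = {}
    for m in MODALITIES:
        mat = np.empty((N_SEGMENTS, 2))
        for i in range(N_SEGMENTS):
            mat[i] = change_scores(hlds[m][i], baseline[m])
        matrices[m] = mat
    return FeatureBag(
        participant_id=window.participant_id,
        group=window.group,
        window_kind=window.window_kind,
        representation="change_score",
        matrices=matrices,
        window_start_s=window.start_s,
    )
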