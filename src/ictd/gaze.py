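"""Raw eye-tracking preprocessing, event detection and trial-level features.

The pipeline is: linear interpolation of short invalid gaps and moving-average
smoothing (:func:`preprocess`), velocity-threshold (I-VT) segmentation into
fixations/saccades with invalid runs reported as blinks
(:func:`detect_events`), and two trial-level feature dialects:

* ``seed``  — per-event mean/std statistics plus event-rate summaries
  (fixation/saccade frequency, maxima, total dispersion, saccade latency);
* ``eseed`` — distributional moments (mean, variance, coefficient of
  variation, kurtosis, skewness) of pupil diameter, fixation duration and
  saccade duration/speed/distance.

Feature screening keeps features whose one-way ANOVA across emotion labels
is significant at ``alpha`` (default 0.05). ``map_to_russell`` converts the
five discrete emotions of the eSEE-d protocol to the arousal/valence classes
of Russell's circumplex model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GazeRecording", "OcularEvent", "FeatureTable",
    "preprocess", "detect_events",
    "extract_seed_features", "extract_esee_features",
    "anova_screen", "map_to_russell",
    "SEED_FEATURES", "ESEE_FEATURES", "RUSSELL_MAP",
]


# ----------------------------------------------------------------------
@dataclass
class GazeRecording:
    """A uniformly sampled gaze stream.

    Positions x, y are in one consistent unit (pixels or degrees, the
    caller's choice); pupil diameters in mm; `valid` flags usable samples.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid: np.ndarray
    sample_rate: float

    def __post_init__(self):
        arrays = [self.t_ms, self.x, self.y, self.pupil_left,
                  self.pupil_right, self.valid]
        n = len(self.t_ms)
        if any(len(a) != n for a in arrays):
            raise ValueError("all recording channels must have equal length")
        if n == 0:
            raise ValueError("empty recording")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self):
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return float(len(self) * 1000.0 / self.sample_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms, "x": self.x, "y": self.y,
            "pupil_l": self.pupil_left, "pupil_r": self.pupil_right,
            "valid": self.valid.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float) -> "GazeRecording":
        required = ["t_ms", "x", "y", "pupil_l", "pupil_r", "valid"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing column: {missing[0]}")
        return cls(
            t_ms=df["t_ms"].to_numpy(float), x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float), pupil_left=df["pupil_l"].to_numpy(float),
            pupil_right=df["pupil_r"].to_numpy(float),
            valid=df["valid"].to_numpy().astype(bool), sample_rate=sample_rate)


@dataclass
class OcularEvent:
    kind: str                       # fixation | saccade | blink
    onset_ms: float
    offset_ms: float
    dispersion_x: float = np.nan    # fixations: coordinate range
    dispersion_y: float = np.nan
    amplitude: float = np.nan       # saccades: start-to-end displacement
    distance: float = np.nan        # saccades: path length
    mean_velocity: float = np.nan   # units/s
    peak_velocity: float = np.nan

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("event offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def dispersion(self) -> float:
        return self.dispersion_x + self.dispersion_y


@dataclass
class FeatureTable:
    """Trial-by-feature matrix with labels and subject identifiers."""

    data: pd.DataFrame
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if len(self.data) != len(self.labels) or len(self.data) != len(self.subject_ids):
            raise ValueError("row count of data, labels and subject_ids must agree")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        all_nan = self.data.columns[self.data.isna().all()]
        if len(all_nan):
            raise ValueError(f"feature is entirely missing: {all_nan[0]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self):
        return len(self.data)


# ----------------------------------------------------------------------
def preprocess(rec: GazeRecording, max_gap_ms: float = 75.0,
               smooth_window: int = 3) -> GazeRecording:
    """Interpolate short invalid gaps and smooth the continuous channels.

    Invalid runs no longer than `max_gap_ms` are linearly interpolated from
    the bracketing valid samples and marked valid; longer runs are left
    invalid (blink candidates). A centred moving average of width
    `smooth_window` is then applied to x, y and both pupil channels within
    each contiguous valid run, with shrinking windows at run edges so a
    linear ramp is preserved away from the edges.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    valid = rec.valid.copy()
    if not valid.any():
        raise ValueError("recording contains no valid samples")
    channels = [rec.x.astype(float).copy(), rec.y.astype(float).copy(),
                rec.pupil_left.astype(float).copy(),
                rec.pupil_right.astype(float).copy()]
    dt = 1000.0 / rec.sample_rate
    for a, b in _runs(~valid):
        gap_ms = (b - a) * dt
        if gap_ms > max_gap_ms or a == 0 or b == len(valid):
            continue  # unbounded or long gap stays invalid
        t0, t1 = rec.t_ms[a - 1], rec.t_ms[b]
        w = (rec.t_ms[a:b] - t0) / (t1 - t0)
        for ch in channels:
            ch[a:b] = ch[a - 1] + w * (ch[b] - ch[a - 1])
        valid[a:b] = True
    if smooth_window > 1:
        half = smooth_window // 2
        for a, b in _runs(valid):
            for ch in channels:
                seg = ch[a:b]
                c = np.cumsum(np.concatenate(([0.0], seg)))
                n = len(seg)
                lo = np.maximum(np.arange(n) - half, 0)
                hi = np.minimum(np.arange(n) + half + 1, n)
                ch[a:b] = (c[hi] - c[lo]) / (hi - lo)
    x, y, pl, pr = channels
    return GazeRecording(rec.t_ms.copy(), x, y, pl, pr, valid, rec.sample_rate)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where the boolean array is True."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(len(flags))
    return list(zip(starts, ends))


def detect_events(rec: GazeRecording, velocity_threshold: float = 30.0,
                  min_fixation_ms: float = 60.0,
                  min_saccade_ms: float = 10.0) -> list[OcularEvent]:
    """I-VT segmentation of a (preprocessed) recording.

    Point-to-point velocity above `velocity_threshold` marks saccadic
    samples, below marks fixational samples; segments shorter than the
    respective minimum duration are merged into their neighbour. Contiguous
    invalid runs are emitted as blink events, and fixations (or saccades)
    split only by a blink are merged back into a single event spanning it.
    """
    if len(rec) == 0:
        raise ValueError("empty recording")
    if np.any(np.diff(rec.t_ms) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = 1000.0 / rec.sample_rate
    events: list[OcularEvent] = []
    for a, b in _runs(~rec.valid):
        events.append(OcularEvent("blink", rec.t_ms[a], rec.t_ms[b - 1] + dt))

    for a, b in _runs(rec.valid):
        if b - a < 2:
            continue
        seg_t = rec.t_ms[a:b]
        seg_x, seg_y = rec.x[a:b], rec.y[a:b]
        step = np.hypot(np.diff(seg_x), np.diff(seg_y))
        vel = step / (np.diff(seg_t) / 1000.0)
        vel = np.append(vel, vel[-1])  # last sample inherits final velocity
        is_sacc = vel > velocity_threshold
        segments = _segment(is_sacc, seg_t, dt, min_fixation_ms, min_saccade_ms)
        for kind, i, j in segments:
            onset, offset = seg_t[i], seg_t[j - 1] + dt
            if kind == "fixation":
                events.append(OcularEvent(
                    "fixation", onset, offset,
                    dispersion_x=float(seg_x[i:j].max() - seg_x[i:j].min()),
                    dispersion_y=float(seg_y[i:j].max() - seg_y[i:j].min())))
            else:
                path = float(step[i:max(i, j - 1)].sum())
                dur_s = (offset - onset) / 1000.0
                events.append(OcularEvent(
                    "saccade", onset, offset,
                    amplitude=float(np.hypot(seg_x[j - 1] - seg_x[i],
                                             seg_y[j - 1] - seg_y[i])),
                    distance=path,
                    mean_velocity=path / dur_s,
                    peak_velocity=float(vel[i:j].max())))
    events.sort(key=lambda e: (e.onset_ms, e.kind))
    return _merge_across_blinks(events)


def _segment(is_sacc: np.ndarray, t: np.ndarray, dt: float,
             min_fix_ms: float, min_sacc_ms: float) -> list[tuple[str, int, int]]:
    segs: list[list] = []
    for i, s in enumerate(is_sacc):
        kind = "saccade" if s else "fixation"
        if segs and segs[-1][0] == kind:
            segs[-1][2] = i + 1
        else:
            segs.append([kind, i, i + 1])
    # merge under-length segments into their (preceding, else following) run
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for idx, (kind, i, j) in enumerate(segs):
            dur = t[j - 1] + dt - t[i]
            floor = min_fix_ms if kind == "fixation" else min_sacc_ms
            if dur < floor:
                tgt = idx - 1 if idx > 0 else idx + 1
                segs[tgt][1] = min(segs[tgt][1], i)
                segs[tgt][2] = max(segs[tgt][2], j)
                del segs[idx]
                # coalesce equal-kind neighbours
                k = 1
                while k < len(segs):
                    if segs[k][0] == segs[k - 1][0]:
                        segs[k - 1][2] = segs[k][2]
                        del segs[k]
                    else:
                        k += 1
                changed = True
                break
    return [(k, i, j) for k, i, j in segs]


def _merge_across_blinks(events: list[OcularEvent]) -> list[OcularEvent]:
    out: list[OcularEvent] = []
    for ev in events:
        if (len(out) >= 2 and out[-1].kind == "blink"
                and out[-2].kind == ev.kind and ev.kind in ("fixation", "saccade")
                and abs(out[-1].onset_ms - out[-2].offset_ms) < 1e-9
                and abs(ev.onset_ms - out[-1].offset_ms) < 1e-9):
            prev = out[-2]
            if ev.kind == "fixation":
                merged = OcularEvent(
                    "fixation", prev.onset_ms, ev.offset_ms,
                    dispersion_x=max(prev.dispersion_x, ev.dispersion_x),
                    dispersion_y=max(prev.dispersion_y, ev.dispersion_y))
            else:
                merged = OcularEvent(
                    "saccade", prev.onset_ms, ev.offset_ms,
                    amplitude=prev.amplitude + ev.amplitude,
                    distance=prev.distance + ev.distance,
                    mean_velocity=(prev.mean_velocity + ev.mean_velocity) / 2,
                    peak_velocity=max(prev.peak_velocity, ev.peak_velocity))
            out[-2] = merged  # blink stays in the list, overlapping the event
        else:
            out.append(ev)
    return out


# ----------------------------------------------------------------------
# feature dialects

SEED_FEATURES = [
    "pupil_left_mean", "pupil_left_std", "pupil_right_mean", "pupil_right_std",
    "fixation_duration_mean", "fixation_duration_std",
    "dispersion_x_mean", "dispersion_x_std",
    "dispersion_y_mean", "dispersion_y_std",
    "saccade_duration_mean", "saccade_duration_std",
    "saccade_amplitude_mean", "saccade_amplitude_std",
    "blink_duration_mean", "blink_duration_std",
    "fixation_frequency", "max_fixation_duration", "max_fixation_dispersion",
    "total_fixation_dispersion", "saccade_frequency", "avg_saccade_duration",
    "avg_saccade_amplitude", "avg_saccade_latency",
]

ESEE_FEATURES = [
    "pupil_diameter_mean", "pupil_diameter_var", "pupil_diameter_cv",
    "fixation_duration_mean", "fixation_duration_var", "fixation_duration_cv",
    "saccade_duration_kurt", "saccade_duration_skew", "saccade_duration_cv",
    "saccade_speed_kurt", "saccade_speed_skew",
    "saccade_distance_kurt", "saccade_distance_skew",
]


def _mean(v):  # population conventions throughout (ddof=0)
    return float(np.mean(v)) if len(v) else np.nan


def _std(v):
    return float(np.std(v)) if len(v) else np.nan


def extract_seed_features(events: Sequence[OcularEvent],
                          rec: GazeRecording) -> dict[str, float]:
    """Per-trial statistics in the SEED-style dialect.

    Frequencies are events per second of recording; "total fixation
    dispersion" sums per-fixation dispersion; "average saccade latency" is
    the mean gap between consecutive saccade onsets. Features whose source
    events are absent are emitted as NaN, never fabricated.
    """
    fix = [e for e in events if e.kind == "fixation"]
    sac = [e for e in events if e.kind == "saccade"]
    bli = [e for e in events if e.kind == "blink"]
    dur_s = rec.duration_ms / 1000.0
    pl = rec.pupil_left[rec.valid]
    pr = rec.pupil_right[rec.valid]
    fd = [e.duration_ms for e in fix]
    dx = [e.dispersion_x for e in fix]
    dy = [e.dispersion_y for e in fix]
    sd = [e.duration_ms for e in sac]
    sa = [e.amplitude for e in sac]
    bd = [e.duration_ms for e in bli]
    onsets = sorted(e.onset_ms for e in sac)
    latency = _mean(np.diff(onsets)) if len(onsets) >= 2 else np.nan
    disp = [e.dispersion for e in fix]
    return {
        "pupil_left_mean": _mean(pl), "pupil_left_std": _std(pl),
        "pupil_right_mean": _mean(pr), "pupil_right_std": _std(pr),
        "fixation_duration_mean": _mean(fd), "fixation_duration_std": _std(fd),
        "dispersion_x_mean": _mean(dx), "dispersion_x_std": _std(dx),
        "dispersion_y_mean": _mean(dy), "dispersion_y_std": _std(dy),
        "saccade_duration_mean": _mean(sd), "saccade_duration_std": _std(sd),
        "saccade_amplitude_mean": _mean(sa), "saccade_amplitude_std": _std(sa),
        "blink_duration_mean": _mean(bd), "blink_duration_std": _std(bd),
        "fixation_frequency": len(fix) / dur_s,
        "max_fixation_duration": float(np.max(fd)) if fd else np.nan,
        "max_fixation_dispersion": float(np.max(disp)) if disp else np.nan,
        "total_fixation_dispersion": float(np.sum(disp)) if disp else np.nan,
        "saccade_frequency": len(sac) / dur_s,
        "avg_saccade_duration": _mean(sd),
        "avg_saccade_amplitude": _mean(sa),
        "avg_saccade_latency": latency,
    }


def extract_esee_features(events: Sequence[OcularEvent], rec: GazeRecording,
                          bias: bool = False) -> dict[str, float]:
    """Per-trial moment features in the eSEE-d dialect.

    Variance is population variance (ddof=0); CV = std/mean and is missing
    when the mean is zero. Kurtosis is Fisher (excess) and skewness the
    adjusted Fisher-Pearson coefficient; pass ``bias=True`` for the raw
    (uncorrected) moment versions. Pupil diameter is the mean of the left
    and right channels where both are valid.
    """
    fix = [e for e in events if e.kind == "fixation"]
    sac = [e for e in events if e.kind == "saccade"]
    pupil = (rec.pupil_left[rec.valid] + rec.pupil_right[rec.valid]) / 2.0
    fd = np.array([e.duration_ms for e in fix])
    sd = np.array([e.duration_ms for e in sac])
    sp = np.array([e.mean_velocity for e in sac])
    dist = np.array([e.distance for e in sac])

    def cv(v):
        if len(v) == 0:
            return np.nan
        m = np.mean(v)
        return float(np.std(v) / m) if m != 0 else np.nan

    def kurt(v):
        return float(stats.kurtosis(v, fisher=True, bias=bias)) if len(v) >= 4 else np.nan

    def skew(v):
        return float(stats.skew(v, bias=bias)) if len(v) >= 3 else np.nan

    def var(v):
        return float(np.var(v)) if len(v) else np.nan

    return {
        "pupil_diameter_mean": _mean(pupil),
        "pupil_diameter_var": var(pupil),
        "pupil_diameter_cv": cv(pupil),
        "fixation_duration_mean": _mean(fd),
        "fixation_duration_var": var(fd),
        "fixation_duration_cv": cv(fd),
        "saccade_duration_kurt": kurt(sd),
        "saccade_duration_skew": skew(sd),
        "saccade_duration_cv": cv(sd),
        "saccade_speed_kurt": kurt(sp),
        "saccade_speed_skew": skew(sp),
        "saccade_distance_kurt": kurt(dist),
        "saccade_distance_skew": skew(dist),
    }


# ----------------------------------------------------------------------
def anova_screen(table: FeatureTable, alpha: float = 0.05
                 ) -> tuple[FeatureTable, pd.DataFrame]:
    """One-way ANOVA of every feature across the label groups.

    Features with p < alpha are retained. Features that are constant across
    all samples have an undefined F statistic and are dropped with the
    reason recorded in the report.
    """
    labels = table.labels
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ANOVA screening needs at least two classes")
    rows = []
    keep = []
    for name in table.feature_names:
        col = table.data[name].to_numpy(float)
        groups = [col[labels == c] for c in classes]
        groups = [g[~np.isnan(g)] for g in groups]
        if any(len(g) < 2 for g in groups):
            rows.append((name, np.nan, np.nan, False, "insufficient samples"))
            continue
        pooled = np.concatenate(groups)
        if np.allclose(pooled, pooled[0]):
            rows.append((name, np.nan, np.nan, False, "constant feature"))
            continue
        f, p = stats.f_oneway(*groups)
        retained = bool(p < alpha)
        rows.append((name, float(f), float(p), retained, ""))
        if retained:
            keep.append(name)
    report = pd.DataFrame(rows, columns=["feature", "F", "p", "retained", "reason"])
    retained_table = FeatureTable(table.data[keep].copy(), table.labels.copy(),
                                  table.subject_ids.copy())
    return retained_table, report


# ----------------------------------------------------------------------
RUSSELL_MAP = {
    # emotion -> (arousal, valence) per the circumplex placement used for
    # the five eSEE-d emotions
    "anger": ("HA", "NV"),
    "disgust": ("HA", "NV"),
    "sadness": ("LA", "NV"),
    "tenderness": ("LA", "PV"),
    "neutral": ("MA", "MV"),
}


def map_to_russell(emotion_labels: Sequence[str]
                   ) -> tuple[list[str], list[str]]:
    """Map discrete emotions to (arousal, valence) class labels."""
    arousal, valence = [], []
    for lab in emotion_labels:
        if lab not in RUSSELL_MAP:
            raise ValueError(f"unknown emotion label: {lab!r}")
        a, v = RUSSELL_MAP[lab]
        arousal.append(a)
        valence.append(v)
    return arousal, valence
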