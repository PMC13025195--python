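"""Synthetic dual-view datasets and gaze streams with known ground truth.

Two generators:

* :func:`generate_dual_modality` draws trials from a shared latent class
  structure and maps them into a gaze-feature view and a pupil-feature view
  through fixed random loading matrices, with per-view noise and per-subject
  offsets. Class means sit on a regular simplex whose edge length is
  ``class_separation``, so separability is controlled exactly, and the
  cross-view correlation of the 1-D case has the closed form 1/(1+sigma^2).

* :func:`generate_gaze_stream` realises a fixation/saccade/blink plan as a
  uniformly sampled recording whose event intervals are known exactly,
  providing the oracle for the I-VT detector and the feature formulas.

All randomness flows from the spec's seed; identical spec -> identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze import GazeRecording

__all__ = [
    "SyntheticSpec", "DualModalityDataset",
    "GazeStreamSpec", "EventGroundTruth",
    "generate_dual_modality", "generate_gaze_stream",
    "simplex_means", "save_dataset", "load_dataset",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the dual-view latent-class generator."""

    n_classes: int = 4
    n_subjects: int = 10
    trials_per_subject: int = 200
    latent_dim: int = 8
    view_dims: tuple[int, int] = (16, 6)     # (gaze view, pupil view)
    class_separation: float = 8.0
    loading_seed_scale: float = 1.0
    noise_sd: tuple[float, float] = (0.5, 0.5)
    subject_shift_sd: float = 0.5
    unit_loadings: bool = False              # loadings all 1 (closed-form case)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_classes", "n_subjects", "trials_per_subject", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(d < 1 for d in self.view_dims):
            raise ValueError("view_dims components must be >= 1")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd components must be >= 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.loading_seed_scale <= 0:
            raise ValueError("loading_seed_scale must be > 0")
        if self.subject_shift_sd < 0:
            raise ValueError("subject_shift_sd must be >= 0")
        if self.class_separation > 0 and self.latent_dim < self.n_classes - 1:
            raise ValueError(
                "latent_dim must be >= n_classes - 1 to place class means on "
                "a regular simplex")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["view_dims"] = list(self.view_dims)
        d["noise_sd"] = list(self.noise_sd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["view_dims"] = tuple(d["view_dims"])
        d["noise_sd"] = tuple(d["noise_sd"])
        return cls(**d)


@dataclass
class DualModalityDataset:
    """Paired gaze-view/pupil-view feature matrices with labels and subjects."""

    gaze_view: np.ndarray
    pupil_view: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self):
        n = len(self.labels)
        if not (self.gaze_view.shape[0] == self.pupil_view.shape[0]
                == n == len(self.subject_ids)):
            raise ValueError("views, labels and subject_ids must share row count")
        c = int(self.labels.max()) + 1
        present = np.unique(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if len(present) != c:
            raise ValueError("every class in [0, C) must be present")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def __len__(self):
        return len(self.labels)


def simplex_means(n_classes: int, dim: int, separation: float) -> np.ndarray:
    """Centered regular-simplex vertices with pairwise distance `separation`."""
    if separation == 0:
        return np.zeros((n_classes, dim))
    e = np.eye(n_classes) - 1.0 / n_classes     # centered, pairwise dist sqrt(2)
    # orthonormal basis of the (C-1)-dim affine span
    u, s, _ = np.linalg.svd(e, full_matrices=False)
    pts = (u[:, :n_classes - 1] * s[:n_classes - 1]) * (separation / np.sqrt(2.0))
    out = np.zeros((n_classes, dim))
    out[:, :n_classes - 1] = pts
    return out


def generate_dual_modality(spec: SyntheticSpec) -> DualModalityDataset:
    """Draw a dual-view dataset per the latent-class model.

    Sample i of class c and subject s is, in view v:
    ``A_v (mu_c + z_i) + o_{s,v} + eps_{i,v}`` with z standard normal,
    per-subject offset o drawn once per subject, and iid noise eps.
    Labels cycle over classes so counts are balanced to within one trial;
    subjects own contiguous trial blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    d1, d2 = spec.view_dims
    n = spec.n_subjects * spec.trials_per_subject
    if n < spec.n_classes:
        raise ValueError("not enough trials to include every class")
    means = simplex_means(spec.n_classes, spec.latent_dim, spec.class_separation)
    if spec.unit_loadings:
        A1 = np.ones((d1, spec.latent_dim))
        A2 = np.ones((d2, spec.latent_dim))
    else:
        A1 = rng.normal(scale=spec.loading_seed_scale, size=(d1, spec.latent_dim))
        A2 = rng.normal(scale=spec.loading_seed_scale, size=(d2, spec.latent_dim))
    subj_off1 = rng.normal(scale=spec.subject_shift_sd, size=(spec.n_subjects, d1))
    subj_off2 = rng.normal(scale=spec.subject_shift_sd, size=(spec.n_subjects, d2))

    labels = np.arange(n) % spec.n_classes
    subject_ids = np.repeat(np.arange(spec.n_subjects), spec.trials_per_subject)
    z = rng.normal(size=(n, spec.latent_dim))
    latent = means[labels] + z
    gaze = latent @ A1.T + subj_off1[subject_ids]
    pupil = latent @ A2.T + subj_off2[subject_ids]
    if spec.noise_sd[0] > 0:
        gaze = gaze + rng.normal(scale=spec.noise_sd[0], size=gaze.shape)
    if spec.noise_sd[1] > 0:
        pupil = pupil + rng.normal(scale=spec.noise_sd[1], size=pupil.shape)
    return DualModalityDataset(gaze, pupil, labels, subject_ids)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GazeStreamSpec:
    """A fixation/saccade/blink plan realised as a sampled stream.

    `fixation_plan` entries are (duration_ms, cx, cy, dispersion_sd);
    `saccade_plan` entries are (duration_ms, amplitude) — k fixations imply
    k-1 interleaved saccades; `blink_plan` entries are (onset_ms,
    duration_ms). Time intervals are half-open [onset, offset).
    """

    fixation_plan: tuple = ((500.0, 0.0, 0.0, 0.0),)
    saccade_plan: tuple = ()
    blink_plan: tuple = ()
    pupil_baseline: float = 3.0
    pupil_noise_sd: float = 0.0
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if len(self.fixation_plan) == 0:
            raise ValueError("plan must contain at least one fixation")
        if len(self.saccade_plan) != len(self.fixation_plan) - 1:
            raise ValueError("k fixations require exactly k-1 saccades")
        for f in self.fixation_plan:
            if f[0] <= 0:
                raise ValueError("fixation durations must be > 0")
        for s in self.saccade_plan:
            if s[0] <= 0:
                raise ValueError("saccade durations must be > 0")
        for b in self.blink_plan:
            if b[1] <= 0:
                raise ValueError("blink durations must be > 0")
        if self.total_duration_ms <= 0:
            raise ValueError("plan has zero total duration")

    @property
    def total_duration_ms(self) -> float:
        return (sum(f[0] for f in self.fixation_plan)
                + sum(s[0] for s in self.saccade_plan))


@dataclass
class EventGroundTruth:
    """Planned (kind, onset_ms, offset_ms) intervals, half-open."""

    events: list[tuple[str, float, float]]

    def __post_init__(self):
        by_kind: dict[str, list[tuple[float, float]]] = {}
        for kind, a, b in self.events:
            if b <= a:
                raise ValueError("event offset must exceed onset")
            by_kind.setdefault(kind, []).append((a, b))
        for kind, iv in by_kind.items():
            iv.sort()
            for (a1, b1), (a2, _) in zip(iv, iv[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping {kind} intervals")

    def count(self, kind: str) -> int:
        return sum(1 for k, *_ in self.events if k == kind)


def generate_gaze_stream(spec: GazeStreamSpec
                         ) -> tuple[GazeRecording, EventGroundTruth]:
    """Sample the planned stream uniformly at `sample_rate`.

    Fixations scatter around their centre with the planned dispersion sd;
    saccades are linear position ramps between consecutive fixation centres
    (constant velocity, so an I-VT detector sees them as uniformly fast);
    blink intervals get validity False. A sample belongs to the half-open
    interval containing its timestamp.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    total = spec.total_duration_ms
    dt = 1000.0 / spec.sample_rate
    n = int(round(total / dt))
    t = np.arange(n) * dt

    events: list[tuple[str, float, float]] = []
    x = np.zeros(n)
    y = np.zeros(n)
    cursor = 0.0
    centers = [(f[1], f[2]) for f in spec.fixation_plan]
    for i, (dur, cx, cy, disp) in enumerate(spec.fixation_plan):
        a, b = cursor, cursor + dur
        sel = (t >= a) & (t < b)
        x[sel] = cx + (rng.normal(scale=disp, size=sel.sum()) if disp > 0 else 0.0)
        y[sel] = cy + (rng.normal(scale=disp, size=sel.sum()) if disp > 0 else 0.0)
        events.append(("fixation", a, b))
        cursor = b
        if i < len(spec.saccade_plan):
            sdur = spec.saccade_plan[i][0]
            a, b = cursor, cursor + sdur
            sel = (t >= a) & (t < b)
            frac = (t[sel] - a) / sdur
            nx, ny = centers[i + 1]
            x[sel] = cx + frac * (nx - cx)
            y[sel] = cy + frac * (ny - cy)
            events.append(("saccade", a, b))
            cursor = b

    pupil = np.full(n, spec.pupil_baseline)
    if spec.pupil_noise_sd > 0:
        pupil = pupil + rng.normal(scale=spec.pupil_noise_sd, size=n)
    valid = np.ones(n, dtype=bool)
    for onset, dur in spec.blink_plan:
        sel = (t >= onset) & (t < onset + dur)
        valid[sel] = False
        events.append(("blink", float(onset), float(onset + dur)))

    rec = GazeRecording(t, x, y, pupil.copy(), pupil.copy(), valid,
                        spec.sample_rate)
    return rec, EventGroundTruth(events)


# ----------------------------------------------------------------------
# dataset persistence: compressed array bundle + JSON spec sidecar

def save_dataset(ds: DualModalityDataset, path: str | Path,
                 spec: SyntheticSpec | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "dataset.npz", gaze_view=ds.gaze_view,
                        pupil_view=ds.pupil_view, labels=ds.labels,
                        subject_ids=ds.subject_ids)
    sidecar = {"class_names": ds.class_names,
               "spec": spec.to_dict() if spec is not None else None}
    (path / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(path: str | Path) -> DualModalityDataset:
    path = Path(path)
    with np.load(path / "dataset.npz") as z:
        arrays = {k: z[k] for k in z.files}
    class_names = None
    sidecar = path / "dataset.json"
    if sidecar.exists():
        class_names = json.loads(sidecar.read_text()).get("class_names")
    return DualModalityDataset(arrays["gaze_view"], arrays["pupil_view"],
                               arrays["labels"], arrays["subject_ids"],
                               class_names=class_names)


def dataset_to_csv(ds: DualModalityDataset, path: str | Path) -> None:
    """Flat CSV export with a view prefix on every feature column."""
    cols = {f"gaze_f{i}": ds.gaze_view[:, i] for i in range(ds.gaze_view.shape[1])}
    cols.update({f"pupil_f{i}": ds.pupil_view[:, i]
                 for i in range(ds.pupil_view.shape[1])})
    cols["label"] = ds.labels
    cols["subject"] = ds.subject_ids
    # %.17g preserves float64 exactly across a write/read round trip
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
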