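"""Joint-loss training, subject-independent cross-validation and evaluation.

The total loss is ``L = w1 * L_CE + w2 * L_align`` where L_CE is categorical
cross-entropy over the classifier output and L_align is the negated matrix
cosine of the centered per-view projections (computed per minibatch, as is
standard for stochastic DCCA training). Defaults w1 = 0.1, w2 = 0.9 reflect
the roughly tenfold scale difference between the two terms.

Cross-validation folds partition *subjects*, never trials, so no individual
contributes to both the training and test side of any fold; with five folds
each fold trains on 80% of subjects. The ablation harness retrains the
network with the IFFN swapped for a plain FFN and/or the alignment weight
forced to zero, under identical folds and seeds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from .autodiff import Tensor, no_grad
from .cosdcca import cos_dcca_loss, cos_dcca_loss_t
from .layers import Adam, cross_entropy
from .model import ICTDModel, ModelConfig
from .synthetic import DualModalityDataset

__all__ = [
    "TrainConfig", "FoldAssignment", "EvalReport", "TrainedICTD",
    "joint_loss", "subject_kfold_split", "train_ictd", "evaluate",
    "cross_validate", "run_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    momentum: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 128
    epochs: int = 50
    decay_rate: float = 0.1              # one LR step at ceil(epochs/2)
    weight_decay: float = 0.01
    omega1: float = 0.1                  # cross-entropy weight
    omega2: float = 0.9                  # alignment weight
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if abs(self.omega1 + self.omega2 - 1.0) > 1e-9:
            raise ValueError("loss weights must satisfy omega1 + omega2 = 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and counts must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["momentum"] = list(self.momentum)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "momentum" in d:
            d["momentum"] = tuple(d["momentum"])
        return cls(**d)


@dataclass
class FoldAssignment:
    """Per-fold train/test subject id lists (disjoint within every fold)."""

    train_subjects: list[np.ndarray]
    test_subjects: list[np.ndarray]

    def __post_init__(self):
        covered = []
        for tr, te in zip(self.train_subjects, self.test_subjects):
            if np.intersect1d(tr, te).size:
                raise ValueError("train and test subjects overlap in a fold")
            covered.append(te)
        self.covered = np.unique(np.concatenate(covered))

    @property
    def n_folds(self) -> int:
        return len(self.test_subjects)

    def hash(self) -> int:
        import zlib
        payload = b"|".join(np.sort(t).tobytes() for t in self.test_subjects)
        return zlib.crc32(payload)


@dataclass
class EvalReport:
    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    per_fold: list[tuple[float, float]] = field(default_factory=list)
    ci95: tuple[float, float] | None = None
    ablation_tag: str | None = None
    fold_hash: int | None = None

    def __post_init__(self):
        total = self.confusion.sum()
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")

    @property
    def confusion_normalized(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1, keepdims=True)
        return np.divide(self.confusion, np.maximum(rows, 1), dtype=float)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "per_fold": [list(pf) for pf in self.per_fold],
            "ci95": list(self.ci95) if self.ci95 else None,
            "ablation_tag": self.ablation_tag,
            "fold_hash": self.fold_hash,
        }


# ----------------------------------------------------------------------
def joint_loss(probs: np.ndarray, labels: np.ndarray, h1p: np.ndarray,
               h2p: np.ndarray, omega1: float = 0.1, omega2: float = 0.9,
               eps: float = 1e-12) -> float:
    """L = w1 * L_CE + w2 * L_align from predicted probabilities."""
    if abs(omega1 + omega2 - 1.0) > 1e-9:
        raise ValueError("omega1 + omega2 must equal 1")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    p_true = np.clip(probs[np.arange(n), labels], eps, None)
    l_ce = float(-np.mean(np.log(p_true)))
    l_align = cos_dcca_loss(h1p, h2p)
    return omega1 * l_ce + omega2 * l_align


def subject_kfold_split(dataset: DualModalityDataset, folds: int = 5,
                        seed: int = 0) -> FoldAssignment:
    """Seeded shuffled partition of subjects into `folds` test groups."""
    subjects = np.unique(dataset.subject_ids)
    if len(subjects) < folds:
        raise ValueError(
            f"{len(subjects)} subjects cannot form {folds} subject-disjoint folds")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(subjects)
    groups = np.array_split(order, folds)
    train, test = [], []
    for g in groups:
        test.append(np.sort(g))
        train.append(np.sort(np.setdiff1d(subjects, g)))
    return FoldAssignment(train, test)


# ----------------------------------------------------------------------
@dataclass
class TrainedICTD:
    """A fitted network with the feature scaler of its training split."""

    model: ICTDModel
    scaler: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    train_cfg: TrainConfig
    log: list[dict] = field(default_factory=list)

    def _scale(self, x1, x2):
        m1, s1, m2, s2 = self.scaler
        return (np.asarray(x1, float) - m1) / s1, (np.asarray(x2, float) - m2) / s2

    def predict(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.model.predict(*self._scale(x1, x2))

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(*self._scale(x1, x2))


def _fit_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(x, axis=0)
    x = np.where(np.isnan(x), med, x)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _impute(x: np.ndarray) -> np.ndarray:
    if not np.isnan(x).any():
        return x
    med = np.nanmedian(x, axis=0)
    return np.where(np.isnan(x), med, x)


def train_ictd(dataset: DualModalityDataset,
               model_cfg: ModelConfig | None = None,
               train_cfg: TrainConfig | None = None,
               fold: tuple[np.ndarray, np.ndarray] | None = None,
               log_every_epoch: bool = True) -> TrainedICTD:
    """Fit the network on one subject-disjoint fold (or the whole dataset).

    Features are imputed by the training-split median and z-scored with
    training-split statistics. Adam uses the configured momentum pair and
    decoupled weight decay; the learning rate is multiplied by
    ``decay_rate`` once at epoch ceil(epochs/2). The per-epoch log records
    the total loss and both components, plus held-out accuracy when a test
    split exists.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if fold is not None:
        train_subj, test_subj = fold
        tr = np.isin(dataset.subject_ids, train_subj)
        te = np.isin(dataset.subject_ids, test_subj)
    else:
        tr = np.ones(len(dataset), dtype=bool)
        te = np.zeros(len(dataset), dtype=bool)
    x1_tr = _impute(dataset.gaze_view[tr])
    x2_tr = _impute(dataset.pupil_view[tr])
    y_tr = dataset.labels[tr]
    m1, s1 = _fit_scaler(x1_tr)
    m2, s2 = _fit_scaler(x2_tr)
    x1_tr = (x1_tr - m1) / s1
    x2_tr = (x2_tr - m2) / s2

    n_classes = dataset.n_classes
    ss = np.random.SeedSequence(train_cfg.seed)
    s_init, s_shuffle = ss.spawn(2)
    model = ICTDModel((x1_tr.shape[1], x2_tr.shape[1]), n_classes,
                      cfg=model_cfg, seed=s_init.generate_state(1)[0] % (2**31))
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               betas=train_cfg.momentum, weight_decay=train_cfg.weight_decay)
    shuffle_rng = np.random.default_rng(s_shuffle)
    trained = TrainedICTD(model, (m1, s1, m2, s2), train_cfg)
    decay_epoch = math.ceil(train_cfg.epochs / 2)
    n = len(y_tr)
    for epoch in range(train_cfg.epochs):
        if epoch == decay_epoch:
            opt.lr *= train_cfg.decay_rate
        model.train()
        order = shuffle_rng.permutation(n)
        ep_loss = ep_ce = ep_align = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            if len(idx) < 2:
                continue
            logits, h1p, h2p = model.forward(x1_tr[idx], x2_tr[idx])
            ce = cross_entropy(logits, y_tr[idx])
            if train_cfg.omega2 != 0.0:
                align = cos_dcca_loss_t(h1p, h2p)
                loss = train_cfg.omega1 * ce + train_cfg.omega2 * align
                align_val = float(align.data)
            else:
                # alignment still logged, but outside the gradient path
                with no_grad():
                    align_val = cos_dcca_loss(h1p.data, h2p.data, eps=1e-12)
                loss = train_cfg.omega1 * ce
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: ce={float(ce.data)} "
                    f"align={align_val} (projection norms "
                    f"{np.linalg.norm(h1p.data):.3g}/{np.linalg.norm(h2p.data):.3g})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            full = train_cfg.omega1 * float(ce.data) + train_cfg.omega2 * align_val
            ep_loss += full
            ep_ce += float(ce.data)
            ep_align += align_val
            n_batches += 1
        entry = {"epoch": epoch, "loss": ep_loss / n_batches,
                 "loss_ce": ep_ce / n_batches, "loss_align": ep_align / n_batches,
                 "lr": opt.lr}
        if te.any() and log_every_epoch:
            pred = trained.predict(dataset.gaze_view[te], dataset.pupil_view[te])
            entry["val_accuracy"] = float(np.mean(pred == dataset.labels[te]))
        trained.log.append(entry)
    model.eval()
    return trained


# ----------------------------------------------------------------------
def evaluate(trained: TrainedICTD, x1: np.ndarray, x2: np.ndarray,
             labels: np.ndarray, n_classes: int | None = None) -> EvalReport:
    """Accuracy, macro-F1 and the class confusion matrix on a test split."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) == 0:
        raise ValueError("empty test split")
    pred = trained.predict(_impute(np.asarray(x1, float)),
                           _impute(np.asarray(x2, float)))
    c = n_classes or max(int(labels.max()), int(pred.max())) + 1
    conf = confusion_matrix(labels, pred, labels=np.arange(c))
    acc = float(np.trace(conf) / conf.sum())
    f1 = float(f1_score(labels, pred, average="macro", zero_division=0))
    return EvalReport(acc, f1, conf)


def cross_validate(dataset: DualModalityDataset,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   assignment: FoldAssignment | None = None,
                   ablation_tag: str | None = None) -> EvalReport:
    """Subject-independent k-fold CV; the 95% CI on accuracy is the normal
    approximation mean +/- 1.96 * sd / sqrt(folds) over fold accuracies."""
    train_cfg = train_cfg or TrainConfig()
    if assignment is None:
        assignment = subject_kfold_split(dataset, train_cfg.folds,
                                         seed=train_cfg.seed)
    per_fold = []
    conf_total = np.zeros((dataset.n_classes, dataset.n_classes), dtype=int)
    for tr_subj, te_subj in zip(assignment.train_subjects,
                                assignment.test_subjects):
        trained = train_ictd(dataset, model_cfg, train_cfg,
                             fold=(tr_subj, te_subj), log_every_epoch=False)
        te = np.isin(dataset.subject_ids, te_subj)
        rep = evaluate(trained, dataset.gaze_view[te], dataset.pupil_view[te],
                       dataset.labels[te], n_classes=dataset.n_classes)
        per_fold.append((rep.accuracy, rep.macro_f1))
        conf_total += rep.confusion
    accs = np.array([a for a, _ in per_fold])
    f1s = np.array([f for _, f in per_fold])
    half = 1.96 * accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
    return EvalReport(
        accuracy=float(np.trace(conf_total) / conf_total.sum()),
        macro_f1=float(f1s.mean()),
        confusion=conf_total, per_fold=per_fold,
        ci95=(float(accs.mean() - half), float(accs.mean() + half)),
        ablation_tag=ablation_tag, fold_hash=assignment.hash())


ABLATION_VARIANTS = ("full", "no_iffn", "no_dcca", "no_iffn_no_dcca")


def run_ablation(dataset: DualModalityDataset,
                 model_cfg: ModelConfig | None = None,
                 train_cfg: TrainConfig | None = None,
                 variants: Sequence[str] = ABLATION_VARIANTS
                 ) -> list[EvalReport]:
    """Retrain under identical folds/seeds with components removed.

    `no_iffn` swaps the IFFN for the width-matched plain FFN; `no_dcca`
    forces the alignment weight to zero (pure cross-entropy); the combined
    variant removes both.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    assignment = subject_kfold_split(dataset, train_cfg.folds,
                                     seed=train_cfg.seed)
    reports = []
    for tag in variants:
        if tag not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant: {tag!r}")
        mc = dataclasses.replace(model_cfg,
                                 use_iffn=("no_iffn" not in tag))
        tc = train_cfg
        if "no_dcca" in tag or tag == "no_iffn_no_dcca":
            tc = dataclasses.replace(train_cfg, omega1=1.0, omega2=0.0)
        reports.append(cross_validate(dataset, mc, tc, assignment=assignment,
                                      ablation_tag=tag))
    return reports
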