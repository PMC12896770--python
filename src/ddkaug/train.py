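"""Training loop and the four evaluation/model-selection strategies.

All partitioning is subject-independent: every segment of a subject
falls in the same partition, and augmented items are derived only from
training-partition subjects.  Both properties are asserted on every run
and violations raise :class:`LeakageError`.

Strategies (each evaluated on a disjoint independent test cohort):

* ``train100`` — train on the whole development cohort for a fixed
  epoch budget (no validation signal exists to select from);
* ``holdout`` — subject-stratified 70/30 split, model selected by
  validation accuracy (best epoch);
* ``cv`` with ``selection='best'`` — stratified 5-fold CV, keep the
  fold model with the highest validation accuracy;
* ``cv`` with ``selection='mean'`` — keep the fold model whose
  validation accuracy is closest to the across-fold mean (ties go to
  the lowest fold index).

Validation performance is subject-level accuracy (mean segment PD
probability per subject, thresholded at 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentationConfig, expand_training_set
from .errors import DataError, LeakageError, ParameterError
from .melspec import MelSpectrogram, batch_melspec
from .metrics import (ConfusionMatrix, EvalResult, aggregate_to_subject,
                      confusion_to_metrics, summarize_folds)
from .model import CNNClassifier, ModelConfig, build_model, predict_proba, \
    softmax, spectrograms_to_array
from .preprocess import Segment, preprocess_recording
from .synthetic import AudioRecording

logger = logging.getLogger(__name__)

# named RNG sub-streams, combined with the run seed
_STREAM_INIT = 1
_STREAM_SHUFFLE = 2
_STREAM_FOLDS = 3
_STREAM_SPLIT = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (cross-entropy loss, Adam optimizer)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    train100_epochs: int | None = None   # default: max_epochs
    select_by_validation: bool = True    # keep best-val-epoch weights
    augmentations: tuple[AugmentationConfig, ...] = ()
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ParameterError("max_epochs and batch_size must be >= 1")
        if not 0 <= self.patience < self.max_epochs:
            raise ParameterError("patience must be in [0, max_epochs)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


@dataclass(frozen=True)
class FoldAssignment:
    """Subject -> fold index, subject-disjoint and class-stratified."""

    folds: dict[str, int]
    labels: dict[str, str]
    k: int

    def subjects_in(self, fold: int) -> set[str]:
        return {s for s, f in self.folds.items() if f == fold}

    def subjects_not_in(self, fold: int) -> set[str]:
        return {s for s, f in self.folds.items() if f != fold}


def make_folds(subject_labels: dict[str, str], k: int = 5,
               seed: int = 0) -> FoldAssignment:
    """Stratified subject-level fold assignment.

    Subjects of each class are shuffled and dealt round-robin, so
    per-fold class counts differ by at most one from perfect balance.
    """
    by_class: dict[str, list[str]] = {}
    for subject, label in subject_labels.items():
        by_class.setdefault(label, []).append(subject)
    for label, members in by_class.items():
        if len(members) < k:
            raise ParameterError(
                f"class {label} has {len(members)} subjects, need >= {k}")
    rng = _rng(seed, _STREAM_FOLDS)
    folds: dict[str, int] = {}
    for label in sorted(by_class):
        members = sorted(by_class[label])
        rng.shuffle(members)
        for i, subject in enumerate(members):
            folds[subject] = i % k
    return FoldAssignment(folds=folds, labels=dict(subject_labels), k=k)


# ------------------------------------------------------------------ data prep

def cohort_segments(cohort: list[AudioRecording]) -> list[Segment]:
    """Standardize and segment every recording of a cohort."""
    segments: list[Segment] = []
    for rec in cohort:
        segments.extend(preprocess_recording(rec))
    if not segments:
        raise DataError("cohort produced no segments")
    return segments


def subject_labels_of(cohort: list[AudioRecording]) -> dict[str, str]:
    labels: dict[str, str] = {}
    for rec in cohort:
        if labels.setdefault(rec.subject_id, rec.label) != rec.label:
            raise DataError(f"subject {rec.subject_id} has conflicting labels")
    return labels


def _items_for(segments: list[Segment], subjects: set[str],
               cfgs: tuple[AugmentationConfig, ...]) -> list[MelSpectrogram]:
    """Spectrograms of the given subjects' segments, augmented if requested."""
    part = [s for s in segments if s.subject_id in subjects]
    if not part:
        raise DataError("empty partition")
    if cfgs:
        items = expand_training_set(part, list(cfgs))
    else:
        items = batch_melspec(part)
    bad = {s.subject_id for s in items} - subjects
    if bad:
        raise LeakageError(f"augmented items from non-training subjects: {bad}")
    return items


def _assert_disjoint(**partitions: set[str]) -> None:
    names = list(partitions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = partitions[a] & partitions[b]
            if overlap:
                raise LeakageError(f"subjects shared between {a} and {b}: {overlap}")


# ------------------------------------------------------------------ training

class _Adam:
    def __init__(self, layers, lr: float):
        self.layers, self.lr, self.t = layers, lr, 0
        self.m = [np.zeros_like(p) for layer in layers for p in (layer.w, layer.b)]
        self.v = [np.zeros_like(p) for layer in layers for p in (layer.w, layer.b)]

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        i = 0
        for layer in self.layers:
            for name in ("w", "b"):
                g = getattr(layer, "d" + name)
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1 ** self.t)
                vhat = self.v[i] / (1 - b2 ** self.t)
                p = getattr(layer, name)
                setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + eps))
                i += 1


def _subject_accuracy(model: CNNClassifier, items: list[MelSpectrogram],
                      labels: dict[str, str]) -> float:
    probs = predict_proba(model, items)
    by_subject: dict[str, list[float]] = {}
    for item, p in zip(items, probs):
        by_subject.setdefault(item.subject_id, []).append(p[1])
    decisions = aggregate_to_subject(by_subject)
    correct = sum(decisions[s][1] == labels[s] for s in decisions)
    return correct / len(decisions)


def train_model(train_items: list[MelSpectrogram],
                val_items: list[MelSpectrogram] | None,
                cfg: TrainConfig) -> tuple[CNNClassifier, dict]:
    """Train the CNN; return the model and a per-epoch history.

    With validation items and ``select_by_validation`` the returned
    weights are those of the best validation-accuracy epoch (early
    stopping after ``patience`` epochs without improvement); otherwise
    the final epoch's weights after a fixed budget.  Disabling
    selection matters when the validation fold itself is the quantity
    being estimated (e.g. chance-level calibration), where best-epoch
    selection would bias it upward.
    """
    if not train_items:
        raise DataError("empty training set")
    x = spectrograms_to_array(train_items)
    y = np.array([1 if it.label == "PD" else 0 for it in train_items])
    model = build_model(cfg.model, seed=int(_rng(cfg.seed, _STREAM_INIT)
                                            .integers(0, 2 ** 31)))
    opt = _Adam(model.parameters(), cfg.learning_rate)
    shuffle_rng = _rng(cfg.seed, _STREAM_SHUFFLE)
    val_labels = ({it.subject_id: it.label for it in val_items}
                  if val_items else None)
    n_epochs = cfg.max_epochs if val_items else (cfg.train100_epochs
                                                 or cfg.max_epochs)
    history: dict = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_acc, best_weights, best_epoch, since_best = -1.0, None, -1, 0
    n = len(x)
    for epoch in range(n_epochs):
        order = shuffle_rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            caches: list = []
            scores = model.forward(xb, caches)
            p = softmax(scores)
            losses.append(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-12)))
            hits += int(np.sum(p.argmax(axis=1) == yb))
            grad = p.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model.backward(grad / len(yb), caches)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / n)
        if val_items:
            acc = _subject_accuracy(model, val_items, val_labels)
            history["val_acc"].append(acc)
            if not cfg.select_by_validation:
                continue
            if acc > best_acc:
                best_acc, best_weights, best_epoch = acc, model.get_weights(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best > cfg.patience:
                    break
    if val_items and cfg.select_by_validation and best_weights is not None:
        model.set_weights(best_weights)
        history["best_epoch"], history["best_val_acc"] = best_epoch, best_acc
    return model, history


# ------------------------------------------------------------------ evaluation

def evaluate_on_cohort(model: CNNClassifier,
                       test_segments: list[Segment],
                       test_labels: dict[str, str]) -> tuple[ConfusionMatrix, dict]:
    """Subject-level confusion matrix of a trained model on a test cohort."""
    items = batch_melspec(test_segments)
    probs = predict_proba(model, items)
    by_subject: dict[str, list[float]] = {}
    for item, p in zip(items, probs):
        by_subject.setdefault(item.subject_id, []).append(p[1])
    decisions = aggregate_to_subject(by_subject)
    subjects = sorted(decisions)
    cm = ConfusionMatrix.from_predictions(
        [test_labels[s] for s in subjects],
        [decisions[s][1] for s in subjects])
    return cm, {s: decisions[s][0] for s in subjects}


def _result(strategy: str, method: str, cm: ConfusionMatrix,
            fold_summary=None, **extra) -> EvalResult:
    acc, sens, spec, f1 = confusion_to_metrics(cm)
    return EvalResult(strategy=strategy, method=method, accuracy=acc,
                      sensitivity=sens, specificity=spec, f1=f1,
                      confusion=cm, fold_summary=fold_summary, extra=extra)


def _setup(cohort, test_cohort):
    dev_labels = subject_labels_of(cohort)
    test_labels = subject_labels_of(test_cohort)
    _assert_disjoint(development=set(dev_labels), test=set(test_labels))
    return (cohort_segments(cohort), dev_labels,
            cohort_segments(test_cohort), test_labels)


def _method_name(cfg: TrainConfig) -> str:
    return " + ".join(c.technique for c in cfg.augmentations) or "baseline"


def strategy_train100(cohort: list[AudioRecording],
                      test_cohort: list[AudioRecording],
                      cfg: TrainConfig) -> EvalResult:
    """Train on the entire development cohort, evaluate on the test cohort."""
    dev_seg, dev_labels, test_seg, test_labels = _setup(cohort, test_cohort)
    items = _items_for(dev_seg, set(dev_labels), cfg.augmentations)
    model, history = train_model(items, None, cfg)
    cm, probs = evaluate_on_cohort(model, test_seg, test_labels)
    return _result("train100", _method_name(cfg), cm,
                   history=history, subject_probs=probs)


def strategy_holdout(cohort: list[AudioRecording],
                     test_cohort: list[AudioRecording],
                     cfg: TrainConfig,
                     train_fraction: float = 0.7) -> EvalResult:
    """Subject-stratified 70/30 split; best-validation-epoch model on test."""
    dev_seg, dev_labels, test_seg, test_labels = _setup(cohort, test_cohort)
    rng = _rng(cfg.seed, _STREAM_SPLIT)
    train_subjects: set[str] = set()
    val_subjects: set[str] = set()
    by_class: dict[str, list[str]] = {}
    for s, lab in dev_labels.items():
        by_class.setdefault(lab, []).append(s)
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        rng.shuffle(members)
        n_train = int(round(train_fraction * len(members)))
        train_subjects.update(members[:n_train])
        val_subjects.update(members[n_train:])
    _assert_disjoint(train=train_subjects, validation=val_subjects,
                     test=set(test_labels))
    train_items = _items_for(dev_seg, train_subjects, cfg.augmentations)
    val_items = [s for s in batch_melspec(dev_seg)
                 if s.subject_id in val_subjects]
    model, history = train_model(train_items, val_items, cfg)
    cm, probs = evaluate_on_cohort(model, test_seg, test_labels)
    return _result("holdout", _method_name(cfg), cm,
                   history=history, subject_probs=probs,
                   train_subjects=sorted(train_subjects),
                   val_subjects=sorted(val_subjects))


def cross_validate(cohort: list[AudioRecording], cfg: TrainConfig,
                   k: int = 5) -> tuple[list[CNNClassifier], list[dict], FoldAssignment]:
    """Train one model per fold; returns models, per-fold records, folds.

    Each record holds the fold's subject-level validation accuracy and
    full metric set.
    """
    dev_labels = subject_labels_of(cohort)
    segments = cohort_segments(cohort)
    assignment = make_folds(dev_labels, k=k, seed=cfg.seed)
    models, records = [], []
    for fold in range(k):
        train_subjects = assignment.subjects_not_in(fold)
        val_subjects = assignment.subjects_in(fold)
        _assert_disjoint(train=train_subjects, validation=val_subjects)
        train_items = _items_for(segments, train_subjects, cfg.augmentations)
        val_items = [s for s in batch_melspec(
            [seg for seg in segments if seg.subject_id in val_subjects])]
        # independent init/shuffle streams per fold: one unlucky
        # initialization must not sink every fold identically
        fold_seed = int(np.random.SeedSequence((cfg.seed, 100 + fold))
                        .generate_state(1)[0] % (2 ** 31))
        model, history = train_model(train_items, val_items,
                                     replace(cfg, seed=fold_seed))
        val_seg = [seg for seg in segments if seg.subject_id in val_subjects]
        cm, _ = evaluate_on_cohort(model, val_seg, dev_labels)
        acc, sens, spec, f1 = confusion_to_metrics(cm)
        records.append({"fold": fold, "val_acc": acc,
                        "metrics": {"accuracy": acc, "sensitivity": sens,
                                    "specificity": spec, "f1": f1},
                        "history": history})
        models.append(model)
    return models, records, assignment


def select_fold(val_accuracies: list[float], selection: str) -> int:
    """'best': argmax accuracy; 'mean': closest to the across-fold mean.

    Ties resolve to the lowest fold index in both rules.
    """
    accs = np.asarray(val_accuracies, dtype=float)
    if selection == "best":
        return int(np.argmax(accs))
    if selection == "mean":
        return int(np.argmin(np.abs(accs - accs.mean())))
    raise ParameterError(f"selection must be 'best' or 'mean', got {selection!r}")


def strategy_cv(cohort: list[AudioRecording],
                test_cohort: list[AudioRecording],
                cfg: TrainConfig, selection: str = "mean",
                k: int = 5) -> EvalResult:
    """5-fold CV; the selected single fold model is evaluated on test."""
    dev_labels = subject_labels_of(cohort)
    test_labels = subject_labels_of(test_cohort)
    _assert_disjoint(development=set(dev_labels), test=set(test_labels))
    models, records, assignment = cross_validate(cohort, cfg, k=k)
    chosen = select_fold([r["val_acc"] for r in records], selection)
    fold_summary = summarize_folds([r["metrics"] for r in records])
    test_seg = cohort_segments(test_cohort)
    cm, probs = evaluate_on_cohort(models[chosen], test_seg, test_labels)
    return _result(f"cv_{selection}", _method_name(cfg), cm,
                   fold_summary=fold_summary, chosen_fold=chosen,
                   fold_val_accuracies=[r["val_acc"] for r in records],
                   subject_probs=probs)


STRATEGIES = ("train100", "holdout", "cv_best", "cv_mean")


def run_strategy(name: str, cohort, test_cohort, cfg: TrainConfig) -> EvalResult:
    """Dispatch by strategy name."""
    if name == "train100":
        return strategy_train100(cohort, test_cohort, cfg)
    if name == "holdout":
        return strategy_holdout(cohort, test_cohort, cfg)
    if name in ("cv_best", "cv_mean"):
        return strategy_cv(cohort, test_cohort, cfg,
                           selection=name.removeprefix("cv_"))
    raise ParameterError(f"unknown strategy {name!r}")
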