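"""Training-set assembly, multilayer-perceptron training, prediction and
evaluation.

Training data follows the family-discovery protocol: candidates whose
self-normalized alignment similarity to the family consensus falls below a
gate (default 0.2) are excluded outright; remaining candidates that carry
the conserved-domain pattern become the positive class, and an equal-sized
set of the least-similar candidates without the domain becomes the negative
class.

The classifier is a single-hidden-layer feed-forward network trained by
back-propagation with learning rate 0.3, momentum 0.2 and 500 epochs, the
hidden layer sized to ⌊(n_features + n_classes)/2⌋ — i.e. the standard
"-L 0.3 -M 0.2 -N 500 -H a" configuration.  Features are standardized on
the training data and the scaling constants stored with the model, which is
serializable to a self-contained JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .align import DEFAULT_SCORING, ScoringConfig, selfalign
from .features import FEATURE_NAMES, extract_features, feature_matrix
from .io import ProteinRecord
from .motif import PrositePattern, has_domain

SELFALIGN_GATE = 0.2

HYPERPARAMS = {
    "learning_rate": 0.3,
    "momentum": 0.2,
    "epochs": 500,
}


@dataclass(frozen=True)
class TrainingSet:
    matrix: np.ndarray                 # n x 39
    labels: np.ndarray                 # n integer labels
    label_semantics: dict[int, str]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix rows and labels length differ")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix columns do not match the feature schema")


def build_training_set(
    positives_source: Sequence[ProteinRecord],
    pattern: PrositePattern,
    consensus: str,
    scoring: ScoringConfig = DEFAULT_SCORING,
    gate: float = SELFALIGN_GATE,
) -> TrainingSet:
    """Label a candidate pool by conserved-domain presence (balanced classes).

    Candidates with selfalign(candidate, consensus) < ``gate`` are dropped.
    Pattern matchers are labeled 1; the n_pos lowest-selfalign non-matchers
    are labeled 0.  Raises ``ValueError`` when either class is empty.
    """
    scored = [
        (rec, selfalign(rec.sequence, consensus, scoring))
        for rec in positives_source
    ]
    retained = [(rec, s) for rec, s in scored if s >= gate]
    positives = [rec for rec, _ in retained if has_domain(pattern, rec.sequence)]
    non_matchers = sorted(
        ((rec, s) for rec, s in retained if not has_domain(pattern, rec.sequence)),
        key=lambda rs: rs[1],
    )
    negatives = [rec for rec, _ in non_matchers[: len(positives)]]
    if not positives or not negatives:
        raise ValueError(
            f"degenerate training set: {len(positives)} positives, "
            f"{len(negatives)} negatives after the {gate} similarity gate"
        )
    records = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    X = feature_matrix(records, consensus, scoring).to_numpy()
    return TrainingSet(X, labels, {0: "negative", 1: "positive"},
                       ids=tuple(r.id for r in records))


def training_set_from_labels(
    records: Sequence[ProteinRecord],
    truth: dict[str, int],
    consensus: str,
    label_semantics: dict[int, str] | None = None,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> TrainingSet:
    """Training set from externally supplied integer labels (e.g. curated or
    synthetic ground truth), for binary or multiclass modes."""
    labels = np.array([truth[r.id] for r in records])
    X = feature_matrix(records, consensus, scoring).to_numpy()
    if label_semantics is None:
        label_semantics = {int(v): f"class_{v}" for v in np.unique(labels)}
    return TrainingSet(X, labels, label_semantics, ids=tuple(r.id for r in records))


@dataclass
class MLPModel:
    """A trained feed-forward network plus its feature standardization.

    Prediction is a pure forward pass over the stored weights: logistic
    hidden units, softmax (multiclass) or logistic (binary) output.
    """

    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    classes: np.ndarray
    out_activation: str               # "softmax" | "logistic"
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    label_semantics: dict[int, str]
    feature_names: tuple[str, ...]
    hyperparams: dict
    seed: int

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.coefs[0].shape[0], self.coefs[0].shape[1],
                self.coefs[1].shape[1])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature schema mismatch: expected {len(self.feature_names)} "
                f"columns, got {X.shape}"
            )
        Z = (X - self.scaler_mean) / self.scaler_scale
        H = _sigmoid(Z @ self.coefs[0] + self.intercepts[0])
        out = H @ self.coefs[1] + self.intercepts[1]
        if self.out_activation == "softmax":
            out = out - out.max(axis=1, keepdims=True)
            e = np.exp(out)
            return e / e.sum(axis=1, keepdims=True)
        p = _sigmoid(out).ravel()
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": 1,
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "classes": self.classes.tolist(),
            "out_activation": self.out_activation,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "label_semantics": {str(k): v for k, v in self.label_semantics.items()},
            "feature_names": list(self.feature_names),
            "hyperparams": self.hyperparams,
            "seed": self.seed,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        doc = json.loads(text)
        if doc.get("schema_version") != 1:
            raise ValueError("unsupported model schema version")
        return cls(
            coefs=[np.array(w) for w in doc["coefs"]],
            intercepts=[np.array(b) for b in doc["intercepts"]],
            classes=np.array(doc["classes"]),
            out_activation=doc["out_activation"],
            scaler_mean=np.array(doc["scaler_mean"]),
            scaler_scale=np.array(doc["scaler_scale"]),
            label_semantics={int(k): v for k, v in doc["label_semantics"].items()},
            feature_names=tuple(doc["feature_names"]),
            hyperparams=doc["hyperparams"],
            seed=doc["seed"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_json(Path(path).read_text())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def hidden_layer_size(n_features: int, n_classes: int) -> int:
    return (n_features + n_classes) // 2


def train_mlp(ts: TrainingSet, seed: int = 0) -> MLPModel:
    """Back-propagation training, deterministic for a given seed."""
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if ts.matrix.shape[0] < 10:
        raise ValueError("training requires at least 10 examples")
    scaler = StandardScaler().fit(ts.matrix)
    X = scaler.transform(ts.matrix)
    hidden = hidden_layer_size(ts.matrix.shape[1], len(classes))
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=HYPERPARAMS["learning_rate"],
        momentum=HYPERPARAMS["momentum"],
        nesterovs_momentum=False,
        max_iter=HYPERPARAMS["epochs"],
        alpha=0.0,
        tol=1e-8,
        n_iter_no_change=HYPERPARAMS["epochs"],
        early_stopping=False,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, ts.labels)
    return MLPModel(
        coefs=[np.array(w) for w in clf.coefs_],
        intercepts=[np.array(b) for b in clf.intercepts_],
        classes=clf.classes_.copy(),
        out_activation=clf.out_activation_,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        label_semantics=dict(ts.label_semantics),
        feature_names=tuple(ts.feature_names),
        hyperparams=dict(HYPERPARAMS, hidden=hidden),
        seed=seed,
    )


@dataclass(frozen=True)
class Prediction:
    id: str
    status: str                 # "classified" | "not-candidate"
    label: int | None
    class_name: str | None
    score: float | None


def predict(
    model: MLPModel,
    records: Sequence[ProteinRecord],
    consensus: str,
    scoring: ScoringConfig = DEFAULT_SCORING,
    gate: float = SELFALIGN_GATE,
) -> list[Prediction]:
    """Classify records; those failing the similarity gate are reported as
    not-candidate without a class."""
    results: list[Prediction] = []
    for rec in records:
        if selfalign(rec.sequence, consensus, scoring) < gate:
            results.append(Prediction(rec.id, "not-candidate", None, None, None))
            continue
        x = extract_features(rec, consensus, scoring).to_array()[None, :]
        proba = model.predict_proba(x)[0]
        k = int(np.argmax(proba))
        label = int(model.classes[k])
        results.append(Prediction(
            rec.id, "classified", label,
            model.label_semantics.get(label, str(label)), float(proba[k]),
        ))
    return results


# ---------------------------------------------------------------------------
# Evaluation


def round_percent(fraction: float, digits: int = 2) -> float:
    """Percentage rounded half-up (the convention of the reported tables)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(repr(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def metrics_percent(self) -> dict[str, float]:
        """Sensitivity/specificity/accuracy as percentages, 2 decimals."""
        return {
            "sensitivity": round_percent(self.sensitivity),
            "specificity": round_percent(self.specificity),
            "accuracy": round_percent(self.accuracy),
        }


def evaluate(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionMatrix:
    """Binary confusion matrix (positive class = 1)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth label lists differ in length")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def per_class_accuracy(
    predicted: Sequence[int], truth: Sequence[int]
) -> dict[int, float]:
    """Per-class accuracy = hits / curated members of the class (percent)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth label lists differ in length")
    out: dict[int, float] = {}
    truth_arr = np.asarray(truth)
    pred_arr = np.asarray(predicted)
    for c in np.unique(truth_arr):
        mask = truth_arr == c
        out[int(c)] = round_percent(float((pred_arr[mask] == c).mean()))
    return out


def mean_class_accuracy(per_class: dict[int, float]) -> float:
    vals = list(per_class.values())
    return float(
        (Decimal(repr(sum(vals) / len(vals)))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Rule-based baselines


def baseline_classifiers(
    records: Sequence[ProteinRecord],
    truth: dict[str, int],
    pattern: PrositePattern,
    consensus: str,
    scoring: ScoringConfig = DEFAULT_SCORING,
    identity_cutoff: float = 0.30,
    positive_cutoff: float = 0.50,
) -> dict[str, ConfusionMatrix]:
    """Three rule-based reference methods evaluated against truth labels:

    - ``cutoff_score``: local identity > identity_cutoff AND local positive
      fraction > positive_cutoff against the consensus;
    - ``conserved_domain``: the pattern matches;
    - ``domain_with_cutoff``: both.
    """
    from .align import local_align  # local import to keep module load light

    calls: dict[str, list[int]] = {
        "cutoff_score": [], "conserved_domain": [], "domain_with_cutoff": []
    }
    truth_list: list[int] = []
    for rec in records:
        l = local_align(rec.sequence, consensus, scoring)
        score_ok = l.identity > identity_cutoff and l.positive > positive_cutoff
        domain_ok = has_domain(pattern, rec.sequence)
        calls["cutoff_score"].append(int(score_ok))
        calls["conserved_domain"].append(int(domain_ok))
        calls["domain_with_cutoff"].append(int(score_ok and domain_ok))
        truth_list.append(1 if truth[rec.id] == 1 else 0)
    return {name: evaluate(pred, truth_list) for name, pred in calls.items()}
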