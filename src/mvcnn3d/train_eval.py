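"""Patient-level cross-validated training and the evaluation suite.

Cross-validation assigns whole patients to folds, so the rotated copies of a
lesion can never straddle the train/validation boundary.  Per-fold results
are combined by an average weighted by each fold's validation-sample
proportion, and the whole k-fold procedure can be repeated with fresh fold
plans, the final figure being the mean over repeats.

Binary metrics follow the usual confusion-count definitions

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    error rate  = (FP + FN) / (TP + TN + FP + FN)

with the malignant class as positive; the ternary task reports the error
rate only.  The ROC curve is a threshold sweep over the positive-class
softmax probability and its trapezoidal area equals the Mann-Whitney
pairwise-win probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .dataprep import samples_to_arrays
from .layers import SGD, Sequential, softmax

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "ConfusionCounts",
    "MetricsReport",
    "make_patient_folds",
    "train_model",
    "evaluate",
    "confusion_metrics",
    "roc_auc",
    "weighted_average",
    "run_cv",
]


@dataclass
class TrainConfig:
    """SGD hyperparameters (defaults are the study's settings)."""

    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 16
    momentum: float = 0.9
    weight_decay: float = 5e-4
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs + 1, self.batch_size) <= 0:
            raise ValueError("learning rate and batch size must be positive")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")


@dataclass
class FoldPlan:
    """Patient-disjoint assignment of patients to k folds."""

    k: int
    assignment: dict[str, int]
    repeat_id: int = 0
    seed: int = 0

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def sample_folds(self, patient_ids) -> np.ndarray:
        return np.array([self.assignment[p] for p in patient_ids])


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    error_rate: float
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    roc_points: list = field(default_factory=list)
    confusion: ConfusionCounts | None = None
    per_fold: list = field(default_factory=list)
    weights: list = field(default_factory=list)
    per_repeat: list = field(default_factory=list)


def make_patient_folds(
    patient_ids, k: int = 10, seed: int = 0, repeat_id: int = 0
) -> FoldPlan:
    """Random seeded patient-disjoint partition with fold sizes differing by
    at most one (96 patients at k = 10 gives six folds of 10 and four of 9)."""
    patients = sorted(set(patient_ids))
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment = {}
    for pos, idx in enumerate(order):
        # first (n % k) folds get the extra patient
        assignment[patients[idx]] = _fold_of(pos, len(patients), k)
    return FoldPlan(k=k, assignment=assignment, repeat_id=repeat_id, seed=seed)


def _fold_of(pos: int, n: int, k: int) -> int:
    base, extra = divmod(n, k)
    cut = (base + 1) * extra
    if pos < cut:
        return pos // (base + 1)
    return extra + (pos - cut) // base


def train_model(
    network,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> list[dict]:
    """Mini-batch SGD with momentum and weight decay; deterministic given
    ``config.seed``.  Returns one history entry per epoch with the mean
    cross-entropy loss and the training error rate."""
    config = config or TrainConfig()
    params = list(network.parameters()) if hasattr(network, "parameters") else []
    history: list[dict] = []
    if not params or config.epochs == 0:
        return history
    if x.shape[0] != y.shape[0]:
        raise ValueError("sample/label count mismatch")
    opt = SGD(
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    n_classes = int(y.max()) + 1 if y.size else 2
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, errors, counts = [], [], []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = network.forward(xb, training=True)
            probs = softmax(logits)
            eps = 1e-12
            losses.append(-np.log(probs[np.arange(len(yb)), yb] + eps).mean())
            errors.append((probs.argmax(axis=1) != yb).sum())
            counts.append(len(yb))
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            network.backward((grad / len(yb)).astype(np.float32))
            opt.step(network.parameters())
        history.append(
            {
                "loss": float(np.mean(losses)),
                "error_rate": float(np.sum(errors) / np.sum(counts)),
            }
        )
    return history


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(error_rate, sensitivity, specificity) from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty sample set")
    err = (counts.fp + counts.fn) / counts.total
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return err, sens, spec


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and the trapezoidal AUC,
    which equals the probability that a random positive outscores a random
    negative (ties counting one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skm.auc(fpr, tpr))


def evaluate(
    network,
    x: np.ndarray,
    y: np.ndarray,
    task: str = "binary",
    positive_class: int = 1,
) -> MetricsReport:
    """Confusion counts and metrics on labeled samples.

    For the binary task the positive class is malignant (index 1 by
    default) and the report carries sensitivity, specificity and ROC/AUC;
    the ternary task reports the error rate only.
    """
    if x.shape[0] == 0:
        raise ValueError("empty sample set")
    probs = network.predict_proba(x)
    pred = probs.argmax(axis=1)
    if task == "ternary":
        return MetricsReport(error_rate=float((pred != y).mean()))
    pos = positive_class
    counts = ConfusionCounts(
        tp=int(((pred == pos) & (y == pos)).sum()),
        tn=int(((pred != pos) & (y != pos)).sum()),
        fp=int(((pred == pos) & (y != pos)).sum()),
        fn=int(((pred != pos) & (y == pos)).sum()),
    )
    err, sens, spec = confusion_metrics(counts)
    scores = probs[:, pos]
    try:
        roc_points, auc = roc_auc(scores, (y == pos).astype(int))
    except ValueError:
        roc_points, auc = [], None
    return MetricsReport(
        error_rate=err,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        roc_points=roc_points,
        confusion=counts,
    )


def weighted_average(values, weights) -> float:
    """Sum of w_i * v_i with weights normalized to 1."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same length")
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.sum(values * weights / weights.sum()))


def run_cv(
    model_factory,
    samples,
    config: TrainConfig | None = None,
    task: str = "binary",
    k: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Repeated patient-level k-fold cross-validation.

    ``model_factory(seed) -> network`` builds a fresh model per fold.  Every
    repeat draws a new fold plan; fold results are averaged weighted by the
    validation-set proportion (augmented copies included in validation, each
    inheriting its lesion's patient so no patient straddles folds); repeats
    are averaged uniformly.
    """
    config = config or TrainConfig()
    x, y, pids = samples_to_arrays(samples)
    root = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_repeats)]
    per_repeat = []
    for r, rseed in enumerate(repeat_seeds):
        plan = make_patient_folds(pids, k=k, seed=rseed, repeat_id=r)
        fold_of_sample = plan.sample_folds(pids)
        fold_reports, weights = [], []
        for fold in range(k):
            val = fold_of_sample == fold
            train = ~val
            if val.sum() == 0:
                continue
            net = model_factory(rseed + fold)
            train_model(net, x[train], y[train], config)
            rep = evaluate(net, x[val], y[val], task=task)
            fold_reports.append(rep)
            weights.append(int(val.sum()))
        agg = {
            "error_rate": weighted_average(
                [f.error_rate for f in fold_reports], weights
            )
        }
        if task == "binary":
            for name in ("sensitivity", "specificity", "auc"):
                vals = [getattr(f, name) for f in fold_reports]
                if all(v is not None and np.isfinite(v) for v in vals):
                    agg[name] = weighted_average(vals, weights)
        per_repeat.append({"aggregate": agg, "folds": fold_reports, "weights": weights})
    final = MetricsReport(
        error_rate=float(
            np.mean([r["aggregate"]["error_rate"] for r in per_repeat])
        ),
        per_repeat=per_repeat,
    )
    if task == "binary":
        for name in ("sensitivity", "specificity", "auc"):
            vals = [r["aggregate"].get(name) for r in per_repeat]
            if all(v is not None for v in vals):
                setattr(final, name, float(np.mean(vals)))
    final.per_fold = per_repeat[-1]["folds"] if per_repeat else []
    final.weights = per_repeat[-1]["weights"] if per_repeat else []
    return final
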