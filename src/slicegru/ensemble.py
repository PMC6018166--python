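"""Group pruning, multi-view score fusion and cross-validated evaluation.

After pre-training, group networks with weak slice-level validation
accuracy are pruned.  Each anatomical view yields one subject-level
probability score; the three views are fused by a weighted average whose
weights are grid-searched on the validation set over the probability
simplex.  Evaluation follows a stratified 10-fold protocol in which one
fold tests, one validates and eight train, with ACC / SEN / SPE and a
threshold-sweep ROC whose area equals the Mann-Whitney pair statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

VIEW_ORDER = ("axial", "sagittal", "coronal")


class UndefinedMetricError(ValueError):
    """Raised when a rate has an empty denominator (single-class input)."""


@dataclass
class PredictionScore:
    """Per-class probabilities for one subject from one view or after fusion."""

    subject_id: str
    source: str  # a view name or "fused"
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


@dataclass
class FusionWeights:
    w_axial: float
    w_sagittal: float
    w_coronal: float

    def __post_init__(self):
        w = np.array([self.w_axial, self.w_sagittal, self.w_coronal], dtype=np.float64)
        if (w < 0).any():
            raise ValueError("fusion weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"axial": self.w_axial, "sagittal": self.w_sagittal, "coronal": self.w_coronal}


def prune_cnns(group_val_accuracies: dict[int, float], threshold: float = 0.55) -> list[int]:
    """Group ids whose validation accuracy reaches ``threshold``.

    If every group falls below the threshold the single best one (lowest id
    on ties) is kept, so downstream stages always have at least one group.
    """
    if not group_val_accuracies:
        raise ValueError("no group accuracies given")
    for gid, acc in group_val_accuracies.items():
        if not (0.0 <= acc <= 1.0):
            raise ValueError(f"accuracy of group {gid} outside [0, 1]")
    retained = sorted(g for g, a in group_val_accuracies.items() if a >= threshold)
    if not retained:
        best = max(group_val_accuracies.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        retained = [best]
    return retained


def fuse(scores: dict[str, PredictionScore], w: FusionWeights) -> PredictionScore:
    """Weighted average of the three per-view probability vectors."""
    missing = [v for v in VIEW_ORDER if v not in scores]
    if missing:
        raise ValueError(f"missing view scores: {missing}")
    subject = scores[VIEW_ORDER[0]].subject_id
    probs = sum(w.as_dict()[v] * scores[v].probs for v in VIEW_ORDER)
    return PredictionScore(subject_id=subject, source="fused", probs=probs)


def simplex_grid(step: float = 0.1) -> list[tuple[float, float, float]]:
    """All weight triples with components in {0, step, ..., 1} summing to 1."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    triples = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k = n - i - j
            triples.append((i / n, j / n, k / n))
    return triples


def fused_accuracy(view_scores: dict[str, np.ndarray], labels: np.ndarray, weights: tuple[float, float, float]) -> float:
    fusedp = sum(wv * view_scores[v] for wv, v in zip(weights, VIEW_ORDER))
    return float((fusedp.argmax(axis=1) == labels).mean())


def grid_search_weights(
    view_scores: dict[str, np.ndarray], labels: np.ndarray, step: float = 0.1
) -> tuple[FusionWeights, float]:
    """Exhaustive simplex search for the fusion weights.

    ``view_scores`` maps each view to an (N, n_classes) probability array
    aligned with ``labels``.  Returns the maximising weights and their
    fused validation accuracy.  Ties are broken toward the most uniform
    triple, then lexicographically in (axial, sagittal, coronal) order.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty validation set")
    best = None
    for triple in simplex_grid(step):
        acc = fused_accuracy(view_scores, labels, triple)
        nonuniformity = sum((t - 1.0 / 3.0) ** 2 for t in triple)
        key = (-acc, nonuniformity, triple)
        if best is None or key < best[0]:
            best = (key, triple, acc)
    _, triple, acc = best
    return FusionWeights(*triple), acc


@dataclass
class CVSplit:
    """Stratified fold assignment with rotating test/validation roles."""

    fold_of: np.ndarray  # subject index -> fold id in {0..k-1}
    k: int

    def rotation(self, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices of (train, validation, test) subjects for rotation ``r``.

        Fold r tests, fold (r+1) mod k validates, the remaining k-2 train.
        """
        if not (0 <= r < self.k):
            raise ValueError(f"rotation must be in [0, {self.k})")
        test = np.flatnonzero(self.fold_of == r)
        val = np.flatnonzero(self.fold_of == (r + 1) % self.k)
        train = np.flatnonzero((self.fold_of != r) & (self.fold_of != (r + 1) % self.k))
        return train, val, test


def make_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> CVSplit:
    """Stratified partition of subjects into ``k`` folds (deterministic)."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < k).any():
        small = classes[counts < k]
        raise ValueError(f"classes {small.tolist()} have fewer than {k} members; cannot stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold_id
    return CVSplit(fold_of=fold_of, k=k)


@dataclass
class MetricsReport:
    acc: float
    sen: float | None  # None when no positive subjects (undefined)
    spe: float | None  # None when no negative subjects (undefined)
    roc: np.ndarray | None = None  # ordered (FPR, TPR) points
    auc: float | None = None
    n_pos: int = 0
    n_neg: int = 0
    per_fold: list[dict] = field(default_factory=list)


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """ACC, SEN, SPE under the argmax decision rule (class 1 = positive).

    The identity ACC * (P + N) = SEN * P + SPE * N holds exactly whenever
    both rates are defined.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must align")
    pred = scores.argmax(axis=1) if scores.ndim == 2 else (scores >= 0.5).astype(int)
    pos = labels == 1
    neg = labels == 0
    acc = float((pred == labels).mean())
    sen = float((pred[pos] == 1).mean()) if pos.any() else None
    spe = float((pred[neg] == 0).mean()) if neg.any() else None
    return MetricsReport(acc=acc, sen=sen, spe=spe, n_pos=int(pos.sum()), n_neg=int(neg.sum()))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC and its area.

    ``scores`` are positive-class scores; higher means more positive.  The
    trapezoidal area over the sweep equals the Mann-Whitney statistic (the
    proportion of positive/negative pairs ordered correctly, ties counted
    half), and is invariant under strictly increasing score transforms.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 2:
        scores = scores[:, 1]
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(np.float64)
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(1.0 - sorted_pos)
    distinct = np.flatnonzero(np.diff(sorted_scores, append=np.nan))  # last index of each tie block
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Full report: ACC/SEN/SPE plus ROC curve and AUC."""
    report = compute_metrics(scores, labels)
    roc, auc = roc_auc(scores, labels)
    report.roc = roc
    report.auc = auc
    return report


def null_auc_band(n_pos: int, n_neg: int, n_draws: int = 2000, seed: int = 0, coverage: float = 0.95) -> tuple[float, float]:
    """Monte-Carlo central band of the AUC under label-score independence."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    draws = np.empty(n_draws)
    for i in range(n_draws):
        s = rng.random(n_pos + n_neg)
        _, draws[i] = roc_auc(s, labels)
    alpha = (1.0 - coverage) / 2.0
    return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))
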