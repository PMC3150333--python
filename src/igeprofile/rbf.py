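"""Normalized radial-basis-function (NRBF) asthma classifier.

Three-layer network: the input layer takes a subject's class-score
profile over the filtered allergen panel; the hidden layer holds h
Gaussian units whose activations are normalized to sum to one (the
"normalized RBF" variant, making the hidden layer a partition of unity);
the output layer is linear with one unit per class, solved in closed
form by least squares on one-hot labels.

Training protocol mirrors a repeated randomized-split evaluation:
stratified 60/10/30 train/test/holdout partition, h chosen on the 10%
test split, performance reported on the untouched 30% holdout, the whole
procedure repeated 10 times on fresh networks and summarized by the mean
across repetitions.

Two-stage fit: hidden-unit centers come from k-means on the training
features; each unit's width is the mean distance to its nearest other
center (floored at a small ε). The output weights then solve a linear
least-squares problem, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import softmax

from .association import chisq_test
from .clustering import ClusteringConfig, kmeans

WIDTH_EPS = 1e-6


@dataclass
class TrainingProtocol:
    train_fraction: float = 0.60
    test_fraction: float = 0.10
    holdout_fraction: float = 0.30
    repetitions: int = 10
    seed: int = 0
    h_range: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        total = self.train_fraction + self.test_fraction + self.holdout_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class RBFNetwork:
    centers: np.ndarray  # h × p
    widths: np.ndarray  # h
    weights: np.ndarray  # (h+1) × 2, first row is the bias
    h: int

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Normalized Gaussian activations; each row sums to one."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = cdist(X, self.centers, metric="sqeuclidean")
        # subtract the row-min exponent for numerical stability
        logits = -d2 / (2.0 * self.widths[None, :] ** 2)
        logits -= logits.max(axis=1, keepdims=True)
        phi = np.exp(logits)
        return phi / phi.sum(axis=1, keepdims=True)

    def scores(self, X: np.ndarray) -> np.ndarray:
        phi = self.hidden(X)
        design = np.hstack([np.ones((phi.shape[0], 1)), phi])
        return design @ self.weights


class SplitError(ValueError):
    """Stratified split impossible (a class is absent)."""


def stratified_split(
    labels: np.ndarray, protocol: TrainingProtocol, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified train/test/holdout partition of subject indices.

    Within each class, subjects are shuffled and cut at the protocol
    fractions, so class proportions in every split stay within rounding
    of the global proportions; the three index sets are disjoint and
    exhaustive.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise SplitError("both classes must be present for a stratified split")
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    n = len(labels)
    n_train = int(round(protocol.train_fraction * n))
    n_test = int(round(protocol.test_fraction * n))
    # systematic proportional merge: shuffle within class, then key each
    # subject by its relative rank in its class so a global cut at the
    # split boundaries keeps every class near its overall proportion
    keys = np.empty(n)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        keys[idx] = (np.arange(len(idx)) + 0.5) / len(idx)
    order = np.argsort(keys, kind="stable")
    train = order[:n_train]
    test = order[n_train:n_train + n_test]
    holdout = order[n_train + n_test:]
    return np.sort(train), np.sort(test), np.sort(holdout)


def _fit_network(X: np.ndarray, y: np.ndarray, h: int, seed: int) -> RBFNetwork:
    km = kmeans(X, h, ClusteringConfig(k_candidates=(2,), n_restarts=5,
                                       max_iterations=300, seed=seed))
    centers = km.centroids
    if h == 1:
        widths = np.array([max(X.std(), WIDTH_EPS)])
    else:
        d = cdist(centers, centers)
        np.fill_diagonal(d, np.inf)
        widths = np.maximum(d.min(axis=1), WIDTH_EPS)
    phi = np.hstack([np.ones((X.shape[0], 1)),
                     RBFNetwork(centers, widths, np.zeros((h + 1, 2)), h).hidden(X)])
    onehot = np.eye(2)[y.astype(int)]
    weights, *_ = np.linalg.lstsq(phi, onehot, rcond=None)
    if not np.isfinite(weights).all():  # ridge fallback for singular systems
        lam = 1e-6
        weights = np.linalg.solve(phi.T @ phi + lam * np.eye(h + 1), phi.T @ onehot)
    return RBFNetwork(centers, widths, weights, h)


def train_rbf(
    features: np.ndarray,
    labels: np.ndarray,
    protocol: TrainingProtocol,
    test_features: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    seed: int | None = None,
) -> RBFNetwork:
    """Fit an NRBF network; h is selected on the test split when given.

    Candidate hidden-unit counts come from ``protocol.h_range`` (capped at
    the training-set size); with no test split the largest-margin training
    accuracy wins. Ties prefer the smaller h.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    seed = protocol.seed if seed is None else seed
    candidates = [h for h in protocol.h_range if h <= X.shape[0]]
    if not candidates:
        raise ValueError(f"h_range {protocol.h_range} exceeds training size {X.shape[0]}")
    best_net, best_acc = None, -1.0
    Xv = X if test_features is None else np.asarray(test_features, dtype=float)
    yv = y if test_labels is None else np.asarray(test_labels).astype(int)
    for h in candidates:
        net = _fit_network(X, y, h, seed)
        acc = float((predict(net, Xv)[1] == yv).mean())
        if acc > best_acc + 1e-12:
            best_net, best_acc = net, acc
    return best_net


def predict(net: RBFNetwork, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class pseudo-probabilities (softmax of output scores) and labels.

    Exact score ties break deterministically to class 0.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != net.centers.shape[1]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match network input {net.centers.shape[1]}"
        )
    scores = net.scores(X)
    proba = softmax(scores, axis=1)
    label = (scores[:, 1] > scores[:, 0]).astype(int)
    return proba, label


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over unique scores; trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney statistic U/(n₁n₂) of the
    class-1 scores against the class-0 scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep only the last point of each tied-score run
    last = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvaluationReport:
    per_repetition: "np.ndarray | None"
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    auc_train_test: float
    holdout_chi2: float
    holdout_chi2_p: float
    repetition_rows: list[dict] = field(default_factory=list)


def _rates(true: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    pos = true == 1
    neg = ~pos
    sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    return sens, spec, float((pred == true).mean())


def repeated_evaluation(
    features: np.ndarray, labels: np.ndarray, protocol: TrainingProtocol
) -> EvaluationReport:
    """Repeated randomized-split NRBF evaluation.

    Each repetition draws a fresh stratified partition, trains a new
    network (h selected on the test split), and measures holdout
    sensitivity/specificity/accuracy. The report averages over the
    repetitions; the ROC/AUC and the holdout-agreement χ² come from the
    last repetition (combined train+test for the ROC, holdout for the χ²).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    master = np.random.default_rng(protocol.seed)
    rows = []
    errors: list[str] = []
    auc = float("nan")
    chi2_stat = chi2_p = float("nan")
    for rep in range(protocol.repetitions):
        rep_seed = int(master.integers(2**31 - 1))
        try:
            tr, te, ho = stratified_split(y, protocol, seed=rep_seed)
            net = train_rbf(X[tr], y[tr], protocol, X[te], y[te], seed=rep_seed)
            _, pred_ho = predict(net, X[ho])
            sens, spec, acc = _rates(y[ho], pred_ho)
            proba_trte, _ = predict(net, X[np.r_[tr, te]])
            _, _, auc = roc_curve(proba_trte[:, 1], y[np.r_[tr, te]])
            table = np.array([[(pred_ho[y[ho] == 0] == 0).sum(), (pred_ho[y[ho] == 0] == 1).sum()],
                              [(pred_ho[y[ho] == 1] == 0).sum(), (pred_ho[y[ho] == 1] == 1).sum()]])
            if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                res = chisq_test(table)
                chi2_stat, chi2_p = res.statistic, res.p
            rows.append({"repetition": rep, "sensitivity": sens,
                         "specificity": spec, "accuracy": acc, "auc": auc})
        except ValueError as exc:  # pragma: no cover - per-repetition failure path
            errors.append(f"repetition {rep}: {exc}")
    if not rows:
        raise RuntimeError("all repetitions failed: " + "; ".join(errors))
    arr = {k: np.array([r[k] for r in rows]) for k in ("sensitivity", "specificity", "accuracy")}
    return EvaluationReport(
        per_repetition=None,
        sensitivity_mean=float(arr["sensitivity"].mean()),
        sensitivity_sd=float(arr["sensitivity"].std(ddof=1)) if len(rows) > 1 else 0.0,
        specificity_mean=float(arr["specificity"].mean()),
        specificity_sd=float(arr["specificity"].std(ddof=1)) if len(rows) > 1 else 0.0,
        accuracy_mean=float(arr["accuracy"].mean()),
        accuracy_sd=float(arr["accuracy"].std(ddof=1)) if len(rows) > 1 else 0.0,
        auc_train_test=auc,
        holdout_chi2=chi2_stat,
        holdout_chi2_p=chi2_p,
        repetition_rows=rows,
    )
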