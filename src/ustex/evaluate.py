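"""Classifier evaluation: [0,1] normalization, logistic model, Mann-Whitney
AUROC on pooled cross-validation predictions, and the two expert-transfer
scenarios.

Performance is always the AUROC of the *pooled* prediction vector of one
cross-validation pass (one score per instance), never an average of
per-fold areas; the repeated-CV mean is the mean of those per-repeat pooled
AUROCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .selection import InstanceSet

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Repeated-CV outcome for one instance set."""

    set_id: tuple
    round_index: int
    auroc_per_repeat: np.ndarray
    mean_auroc: float
    sd_auroc: float
    predictions: np.ndarray  # (repeats, n) pooled score vectors


def minmax_normalize(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-feature min-max scaling fitted on the training rows only.

    Returns ``(train_scaled, apply_scaled, (mins, ranges))``.  Zero-range
    features map to 0 everywhere; values outside the training range are not
    clipped (test values may leave [0, 1]).
    """
    train = np.asarray(train, dtype=np.float64)
    apply_to = np.asarray(apply_to, dtype=np.float64)
    if train.size == 0:
        raise ValueError("training rows must be non-empty")
    mins = train.min(axis=0)
    ranges = train.max(axis=0) - mins
    scale = np.where(ranges > 0, 1.0 / np.where(ranges > 0, ranges, 1.0), 0.0)
    return (
        (train - mins) * scale,
        (apply_to - mins) * scale,
        (mins, ranges),
    )


def fit_predict_logistic(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Fit an L2-regularized logistic model and return class-1 (cirrhosis)
    probabilities for the test rows.  Deterministic given the data."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training data must contain both classes")
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)  # L2 by default
    model.fit(train_X, train_y)
    return model.predict_proba(test_X)[:, 1]


def fit_predict_linear_svm(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C: float = 1.0,
) -> np.ndarray:
    """Linear-kernel SVM decision scores (sensitivity alternative to the
    logistic model)."""
    from sklearn.svm import LinearSVC

    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training data must contain both classes")
    model = LinearSVC(C=C)
    model.fit(train_X, train_y)
    return model.decision_function(test_X)


def auroc_u(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC from the Mann-Whitney U statistic with midrank tie handling:
    ``AUROC = U1 / (n1 * n0)``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u1 = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def cv_predictions(
    iset: InstanceSet,
    folds: int,
    seed: int,
    C: float = 1.0,
) -> np.ndarray:
    """One stratified CV pass: per fold normalize on the training part,
    fit, score the held-out part; return the pooled score vector."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.full(iset.n, np.nan)
    for train_idx, test_idx in skf.split(iset.features, iset.labels):
        tr, te, _ = minmax_normalize(
            iset.features[train_idx], iset.features[test_idx]
        )
        preds[test_idx] = fit_predict_logistic(
            tr, iset.labels[train_idx], te, C=C
        )
    return preds


def repeated_cv(
    iset: InstanceSet,
    folds: int = 10,
    repeats: int = 10,
    rng: np.random.Generator | None = None,
    round_index: int = 0,
    C: float = 1.0,
) -> EvalResult:
    """Repeated stratified cross-validation with pooled-prediction AUROC.

    Folds are redrawn at random each repeat; if the smaller class has fewer
    rows than ``folds`` the fold count is reduced (with a logged warning).
    """
    rng = rng if rng is not None else np.random.default_rng()
    min_class = min(iset.class_counts().values())
    folds_eff = min(folds, min_class)
    if folds_eff < folds:
        logger.warning(
            "set %s: reducing folds from %d to %d (smallest class has %d rows)",
            iset.set_id,
            folds,
            folds_eff,
            min_class,
        )
    if folds_eff < 2:
        raise ValueError(f"set {iset.set_id}: not enough rows per class for CV")
    aucs = np.empty(repeats)
    preds = np.empty((repeats, iset.n))
    for r in range(repeats):
        seed = int(rng.integers(0, 2**31 - 1))
        p = cv_predictions(iset, folds_eff, seed, C=C)
        preds[r] = p
        aucs[r] = auroc_u(p, iset.labels)
    return EvalResult(
        set_id=iset.set_id,
        round_index=round_index,
        auroc_per_repeat=aucs,
        mean_auroc=float(aucs.mean()),
        sd_auroc=float(aucs.std(ddof=1)) if repeats > 1 else 0.0,
        predictions=preds,
    )


def _train_test_auroc(train: InstanceSet, test: InstanceSet, C: float = 1.0) -> float:
    tr, te, _ = minmax_normalize(train.features, test.features)
    scores = fit_predict_logistic(tr, train.labels, te, C=C)
    return auroc_u(scores, test.labels)


def scenario_same_expert(
    sets_by_iteration: dict[int, InstanceSet], C: float = 1.0
) -> list[dict]:
    """Scenario 1: train on one iteration's set, test on every other
    iteration of the same expert (ordered pairs)."""
    iters = sorted(sets_by_iteration)
    if len(iters) < 2:
        raise ValueError("need at least 2 iterations")
    out = []
    for i in iters:
        for j in iters:
            if i == j:
                continue
            auc = _train_test_auroc(
                sets_by_iteration[i], sets_by_iteration[j], C=C
            )
            out.append({"train_iteration": i, "test_iteration": j, "auroc": auc})
    return out


def scenario_cross_expert(
    sets: dict[tuple[int, int], InstanceSet],
    C: float = 1.0,
    pair_iterations: str = "different",
) -> list[dict]:
    """Scenario 2: train with one expert's set, test with every *other*
    expert's set (the table diagonal is absent).

    ``pair_iterations`` selects which establishment iterations are paired:
    ``"different"`` (default) tests against the other experts' sets from
    other iterations — the clinically relevant situation, where the new
    images were never seen by the training expert; ``"same"`` pairs sets
    of equal iteration index.
    """
    if pair_iterations not in ("different", "same"):
        raise ValueError("pair_iterations must be 'different' or 'same'")
    experts = sorted({e for e, _ in sets})
    iterations = sorted({z for _, z in sets})
    out = []
    for a in experts:
        for b in experts:
            if a == b:
                continue
            for z_train in iterations:
                if (a, z_train) not in sets:
                    continue
                if pair_iterations == "same":
                    z_tests = [z_train]
                else:
                    z_tests = [z for z in iterations if z != z_train]
                for z_test in z_tests:
                    if (b, z_test) not in sets:
                        continue
                    auc = _train_test_auroc(
                        sets[(a, z_train)], sets[(b, z_test)], C=C
                    )
                    out.append(
                        {
                            "train_expert": a,
                            "test_expert": b,
                            "train_iteration": z_train,
                            "test_iteration": z_test,
                            "auroc": auc,
                        }
                    )
    return out
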