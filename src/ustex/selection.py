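"""Correlation-based feature selection under the subsample-and-exclude
protocol.

To keep feature selection independent of the data the classifier is later
evaluated on, a small class-balanced sample (``k/2`` per class) is drawn
from each instance set and *moved* into a pooled selection dataset; CFS runs
on the pool only, and the source sets — with the pooled rows removed — are
filtered to the selected features.  The whole procedure is repeated for a
number of independent rounds, each redrawing from the original sets.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np

_EPS = 1e-12


@dataclass
class InstanceSet:
    """One labeled feature vector per patient for one (expert, iteration)."""

    set_id: tuple
    features: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) int 0 (F0) / 1 (F4)
    patient_ids: tuple
    feature_names: tuple

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape[0] != len(self.labels):
            raise ValueError("features and labels disagree on row count")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("features and names disagree on column count")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in (0, 1)}

    def subset_rows(self, idx: np.ndarray) -> "InstanceSet":
        return replace(
            self,
            features=self.features[idx],
            labels=self.labels[idx],
            patient_ids=tuple(self.patient_ids[i] for i in idx),
        )

    def subset_features(self, names) -> "InstanceSet":
        cols = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            features=self.features[:, cols],
            feature_names=tuple(names),
        )


@dataclass
class SelectionRound:
    """One round of the selection protocol."""

    round_index: int
    pooled: InstanceSet
    selected: tuple
    filtered_sets: dict = field(default_factory=dict)


def sample_balanced(
    iset: InstanceSet, k: int, rng: np.random.Generator
) -> tuple[InstanceSet, InstanceSet]:
    """Draw ``k/2`` rows per class without replacement; return
    ``(pooled, remainder)`` with disjoint rows that union to the input."""
    if k % 2:
        raise ValueError("k must be even")
    take = k // 2
    picked: list[int] = []
    for cls in (0, 1):
        cls_idx = np.where(iset.labels == cls)[0]
        if len(cls_idx) < take:
            raise ValueError(
                f"class {'F0' if cls == 0 else 'F4'} has only {len(cls_idx)} "
                f"rows in set {iset.set_id}, need {take}"
            )
        picked.extend(rng.choice(cls_idx, size=take, replace=False))
    picked_arr = np.sort(np.asarray(picked))
    rest = np.setdiff1d(np.arange(iset.n), picked_arr)
    return iset.subset_rows(picked_arr), iset.subset_rows(rest)


def _correlations(X: np.ndarray, y: np.ndarray):
    """Absolute Pearson feature-feature and feature-class (point-biserial)
    correlations; constant columns correlate 0 with everything."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    ok = sd > _EPS
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / sd[ok]
    n = X.shape[0]
    rff = np.abs(Z.T @ Z / n)
    np.fill_diagonal(rff, 1.0)
    yc = y - y.mean()
    ysd = yc.std()
    if ysd > _EPS:
        rcf = np.abs(Z.T @ (yc / ysd) / n)
    else:
        rcf = np.zeros(X.shape[1])
    return rcf, rff


def cfs_merit(subset, rcf: np.ndarray, rff: np.ndarray) -> float:
    """CFS merit ``m * r_cf / sqrt(m + m (m-1) r_ff)`` of a feature subset
    (empty subset has merit 0)."""
    m = len(subset)
    if m == 0:
        return 0.0
    idx = np.asarray(sorted(subset))
    rcf_sum = rcf[idx].sum()
    sub = rff[np.ix_(idx, idx)]
    rff_sum = (sub.sum() - m) / 2.0
    return float(rcf_sum / np.sqrt(m + 2.0 * rff_sum))


def cfs_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names,
    max_stall: int = 5,
) -> tuple:
    """Best-first forward CFS search over the pooled selection dataset.

    Expands the currently best-scoring subset by one feature at a time
    (ties broken by registry order) and stops after ``max_stall``
    consecutive expansions that fail to improve the best merit.
    Returns selected names in registry order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rcf, rff = _correlations(X, y)
    p = X.shape[1]

    best_subset: frozenset = frozenset()
    best_merit = 0.0
    counter = 0
    heap: list = [(-0.0, counter, frozenset())]
    visited = {frozenset()}
    stall = 0
    while heap and stall < max_stall:
        _, _, node = heapq.heappop(heap)
        improved = False
        for f in range(p):
            if f in node:
                continue
            child = node | {f}
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, rcf, rff)
            counter += 1
            heapq.heappush(heap, (-merit, counter, child))
            if merit > best_merit + 1e-10:
                best_merit = merit
                best_subset = child
                improved = True
        stall = 0 if improved else stall + 1
    return tuple(feature_names[i] for i in sorted(best_subset))


def selection_protocol(
    sets: list[InstanceSet],
    k: int = 10,
    rounds: int = 20,
    rng: np.random.Generator | None = None,
) -> list[SelectionRound]:
    """Run the pooled-subsample CFS protocol for independent rounds.

    Per round: draw ``k`` class-balanced rows from each of the ``S`` input
    sets (pool size ``S*k``), run CFS on the pool, and emit each source set
    with the pooled rows excluded and only the selected feature columns
    kept.  Rounds redraw from the original sets.
    """
    rng = rng if rng is not None else np.random.default_rng()
    out: list[SelectionRound] = []
    for r in range(1, rounds + 1):
        pooled_parts = []
        remainders = {}
        for iset in sets:
            pooled, rest = sample_balanced(iset, k, rng)
            pooled_parts.append(pooled)
            remainders[iset.set_id] = rest
        pool = InstanceSet(
            set_id=("pool", r),
            features=np.vstack([p.features for p in pooled_parts]),
            labels=np.concatenate([p.labels for p in pooled_parts]),
            patient_ids=tuple(
                pid for p in pooled_parts for pid in p.patient_ids
            ),
            feature_names=sets[0].feature_names,
        )
        selected = cfs_select(pool.features, pool.labels, pool.feature_names)
        if not selected:  # fall back to the single most class-correlated feature
            rcf, _ = _correlations(pool.features, pool.labels.astype(float))
            selected = (pool.feature_names[int(np.argmax(rcf))],)
        filtered = {
            sid: rest.subset_features(selected) for sid, rest in remainders.items()
        }
        out.append(
            SelectionRound(
                round_index=r, pooled=pool, selected=selected, filtered_sets=filtered
            )
        )
    return out
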