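"""Random-forest regression with an optional class-balanced bootstrap.

Clinical-score cohorts are small and their score distributions uneven:
with 0–66 Fugl-Meyer totals binned into the five severity classes
(≤30, 30–38, 38–47, 47–56, >56), a typical sample has 2–15 subjects per
class.  A plain bootstrap then under-represents the extreme classes in
almost every tree, and the ensemble regresses their predictions toward
the cohort middle.  The balanced bootstrap counters this by drawing, for
every tree, an equal number of samples **with replacement from each
nonempty class**, so each severity band carries the same weight in every
tree regardless of raw frequency.

Trees are CART regression trees (scikit-learn ``DecisionTreeRegressor``)
with ``max_features = p/3`` (regression convention), unlimited depth and
minimum leaf size 1 by default; the ensemble prediction is the tree
mean.  Out-of-bag predictions are available for leakage-free stacking.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FMA_CLASS_EDGES",
    "fma_class",
    "balanced_bootstrap",
    "BootstrapForestRegressor",
    "fit_task_rf",
]

#: Severity-class boundaries on the FMA scale; right-inclusive, i.e.
#: class 1 is FMA <= 30, class 2 is 30 < FMA <= 38, ..., class 5 is > 56.
FMA_CLASS_EDGES = (30.0, 38.0, 47.0, 56.0)


def fma_class(y, class_edges=FMA_CLASS_EDGES) -> np.ndarray:
    """Map scores to 1-based severity classes (boundaries right-inclusive)."""
    edges = np.asarray(class_edges, float)
    if not (np.all(np.diff(edges) > 0) and edges[0] > 0 and edges[-1] < 66):
        raise ValueError(f"class edges {class_edges} not increasing in (0, 66)")
    return np.searchsorted(edges, np.asarray(y, float), side="left") + 1


def balanced_bootstrap(
    y: np.ndarray,
    class_edges=FMA_CLASS_EDGES,
    per_class_draw: int | str = "mean-class",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of one balanced bag: ``per_class_draw`` draws with
    replacement from each nonempty class.

    ``per_class_draw="mean-class"`` (default) draws ``round(n / k)`` per
    nonempty class, i.e. the bag keeps roughly the ordinary bootstrap
    size while equalizing class shares — rebalancing the training set
    rather than shrinking it.  ``"min-class"`` uses the smallest
    nonempty class size (the classical balanced-ensemble down-sampling
    convention).  With all samples in a single class the draw
    degenerates to a plain bootstrap (with a warning).
    """
    y = np.asarray(y, float)
    rng = np.random.default_rng() if rng is None else rng
    classes = fma_class(y, class_edges)
    groups = [np.flatnonzero(classes == c) for c in np.unique(classes)]
    if len(groups) < 2:
        warnings.warn(
            "only one nonempty score class; falling back to plain bootstrap"
        )
        return rng.choice(len(y), size=len(y), replace=True)
    if per_class_draw == "mean-class":
        draw = max(1, round(len(y) / len(groups)))
    elif per_class_draw == "min-class":
        draw = min(len(g) for g in groups)
    else:
        draw = int(per_class_draw)
    if draw < 1:
        raise ValueError(f"per_class_draw={per_class_draw!r} must be >= 1")
    return np.concatenate(
        [rng.choice(g, size=draw, replace=True) for g in groups]
    )


def _resolve_max_features(rule, p: int) -> int:
    if rule in ("third", None):
        return max(1, round(p / 3))
    if isinstance(rule, float):
        return max(1, round(rule * p))
    return min(p, int(rule))


class BootstrapForestRegressor:
    """Bagged regression trees with plain or class-balanced bootstrap.

    Parameters
    ----------
    n_trees : int
        Ensemble size.
    class_edges : sequence of float or None
        ``None`` gives a plain bootstrap (bag size n).  Otherwise each
        bag is balanced across the score classes these edges define.
    per_class_draw : int, "mean-class", or "min-class"
        Draws per class per tree in balanced mode.
    max_features : "third", float fraction, or int
        Features considered per split.
    random_state : int or numpy Generator
        Sole source of randomness; fitting is deterministic given it.
    """

    def __init__(
        self,
        n_trees: int = 100,
        *,
        class_edges=None,
        per_class_draw: int | str = "mean-class",
        max_features="third",
        min_samples_leaf: int = 1,
        random_state=None,
    ):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.class_edges = class_edges
        self.per_class_draw = per_class_draw
        self.max_features = max_features
        self.min_samples_leaf = int(min_samples_leaf)
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BootstrapForestRegressor":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        mf = _resolve_max_features(self.max_features, p)
        # trees consume pre-validated float32 (sklearn's internal dtype);
        # validation is done once here instead of once per tree
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        self.trees_: list[DecisionTreeRegressor] = []
        self.bags_: list[np.ndarray] = []
        self.n_features_ = p
        self.y_train_ = y.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("once")
            for _ in range(self.n_trees):
                if self.class_edges is None:
                    bag = rng.choice(n, size=n, replace=True)
                else:
                    bag = balanced_bootstrap(
                        y, self.class_edges, self.per_class_draw, rng
                    )
                tree = DecisionTreeRegressor(
                    max_features=mf,
                    min_samples_leaf=self.min_samples_leaf,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                tree.fit(
                    np.ascontiguousarray(X32[bag]), y[bag], check_input=False
                )
                self.trees_.append(tree)
                self.bags_.append(bag)
        return self

    @staticmethod
    def _as32(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        return np.ascontiguousarray(X, dtype=np.float32)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X32 = self._as32(X)
        preds = np.zeros(X32.shape[0])
        for tree in self.trees_:
            preds += tree.predict(X32, check_input=False)
        return preds / len(self.trees_)

    def oob_predict(self, X: np.ndarray) -> np.ndarray:
        """Out-of-bag prediction per training row.

        Rows that appear in every bag (possible in balanced mode with a
        singleton class) fall back to the full-ensemble prediction.
        """
        X32 = self._as32(X)
        n = X32.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, bag in zip(self.trees_, self.bags_):
            all_pred = tree.predict(X32, check_input=False)
            oob = np.ones(n, dtype=bool)
            oob[bag] = False
            total[oob] += all_pred[oob]
            count[oob] += 1
        out = np.where(count > 0, total / np.maximum(count, 1), 0.0)
        never = count == 0
        if never.any():
            out[never] = self.predict(X32[never])
        return out


def fit_task_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed=None,
    *,
    class_edges=None,
    per_class_draw: int | str = "mean-class",
    max_features="third",
) -> BootstrapForestRegressor:
    """Fit the per-task regression forest (plain bootstrap by default)."""
    return BootstrapForestRegressor(
        n_trees,
        class_edges=class_edges,
        per_class_draw=per_class_draw,
        max_features=max_features,
        random_state=seed,
    ).fit(X, y)
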