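"""Clinical-score estimators: the FAS pipeline and four FMA methods.

FAS (movement quality, 0–5): a 100-tree regression forest per task
estimates the per-repetition FAS from the trial features; repetition
estimates are averaged per task, the eight per-task averages are summed,
and the sum ``Σ`` is mapped to the total score through the fixed linear
calibration

    FAS_Total = (Σ · 1.78 + 2.97) / 15

then clipped to [0, 5].

FMA (impairment severity, 0–66), four methods of increasing structure:

* **Method 1** — ordinary least squares of true FMA on true FAS total,
  fit on the training subjects, evaluated at the sensor-estimated FAS.
* **Method 2** — per-task 100-tree forests mapping trial features to
  FMA, repetition-averaged into an 8-vector of per-task estimates that a
  50-tree aggregator forest combines into the total.
* **Method 3** — Method 2 with every forest trained on class-balanced
  bootstrap bags (severity classes ≤30, 30–38, 38–47, 47–56, >56).
* **Method 4** (proposed) — Method 3 with the sensor-estimated FAS
  appended as an input to each per-task forest and to the aggregator.

The aggregator is trained on *out-of-bag* per-task estimates of the
training subjects, so its inputs have test-like error structure without
extra model fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression

from .features import catalog_for, cfs_select, extract_features
from .forest import FMA_CLASS_EDGES, BootstrapForestRegressor, fit_task_rf
from .types import TASKS, SubjectSession

__all__ = [
    "FAS_SLOPE",
    "FAS_INTERCEPT",
    "FAS_DIVISOR",
    "fas_total",
    "ModelConfig",
    "FeatureTable",
    "build_feature_table",
    "estimate_fas",
    "predict_fas_fold",
    "fit_method1",
    "predict_fma_fold",
    "FMA_METHODS",
]

FAS_SLOPE = 1.78
FAS_INTERCEPT = 2.97
FAS_DIVISOR = 15.0

FMA_METHODS = ("m1_linreg", "m2_rf", "m3_balanced_rf", "m4_proposed")


def fas_total(task_sum: float) -> float:
    """Total-FAS calibration: ``(Σ·1.78 + 2.97)/15``, clipped to [0, 5]."""
    return float(np.clip((task_sum * FAS_SLOPE + FAS_INTERCEPT) / FAS_DIVISOR,
                         0.0, 5.0))


@dataclass
class ModelConfig:
    """Estimator hyperparameters; defaults follow the published pipeline
    (100 task trees, 50 aggregator trees, severity edges 30/38/47/56)."""

    task_trees: int = 100
    aggregator_trees: int = 50
    class_edges: tuple = FMA_CLASS_EDGES
    per_class_draw: int | str = "mean-class"
    max_features: str | float | int = "third"
    balance_aggregator: bool = True


@dataclass
class FeatureTable:
    """Per-cohort feature precomputation shared across CV folds.

    Feature extraction is fold-independent (no fitting), so it is done
    once; feature *selection* stays inside each training fold.
    """

    feature_names: tuple[str, ...]
    subjects: list[str]
    fma: dict[str, float]
    fas_total_true: dict[str, float]
    X: dict[str, np.ndarray] = field(default_factory=dict)       # task -> rows
    y_fas: dict[str, np.ndarray] = field(default_factory=dict)
    y_fma: dict[str, np.ndarray] = field(default_factory=dict)
    row_subject: dict[str, np.ndarray] = field(default_factory=dict)

    def complete_subjects(self) -> list[str]:
        """Subjects with at least one trial in every task."""
        ok = []
        for s in self.subjects:
            if all(np.any(self.row_subject[t] == s) for t in TASKS):
                ok.append(s)
        return ok


def build_feature_table(sessions: list[SubjectSession]) -> FeatureTable:
    """Extract features for every trial of every session."""
    catalog = None
    per_task: dict[str, list] = {t: [] for t in TASKS}
    fma: dict[str, float] = {}
    fas_tot: dict[str, float] = {}
    subjects: list[str] = []
    for session in sessions:
        session.validate()
        subjects.append(session.subject_id)
        fma[session.subject_id] = float(session.fma_true)
        fas_tot[session.subject_id] = fas_total(
            sum(session.fas_true_per_task.get(t, 0.0) for t in TASKS)
        )
        for trial in session.trials:
            if catalog is None:
                catalog = catalog_for(trial.channels.keys())
            vec = extract_features(
                trial, catalog=catalog, subject_id=session.subject_id
            )
            per_task[trial.task_id].append(
                (vec.values, session.fas_true_per_task.get(trial.task_id),
                 float(session.fma_true), session.subject_id)
            )
    table = FeatureTable(
        feature_names=catalog.names,
        subjects=subjects,
        fma=fma,
        fas_total_true=fas_tot,
    )
    for t, rows in per_task.items():
        if not rows:
            continue
        table.X[t] = np.array([r[0] for r in rows])
        table.y_fas[t] = np.array(
            [np.nan if r[1] is None else float(r[1]) for r in rows]
        )
        table.y_fma[t] = np.array([r[2] for r in rows])
        table.row_subject[t] = np.array([r[3] for r in rows])
    return table


def estimate_fas(task_to_trial_preds: dict[str, list[float]]) -> float:
    """Aggregate per-trial FAS predictions into the total score.

    Repetition predictions are averaged per task, summed across the
    eight tasks, and passed through the total-FAS calibration.  All
    eight tasks are required — the calibration was derived for the full
    battery.
    """
    missing = [t for t in TASKS if not task_to_trial_preds.get(t)]
    if missing:
        raise ValueError(f"missing task estimates for {missing}")
    task_sum = sum(
        float(np.mean(task_to_trial_preds[t])) for t in TASKS
    )
    return fas_total(task_sum)


def _subject_means(values: np.ndarray, subjects: np.ndarray,
                   order: list[str]) -> np.ndarray:
    return np.array(
        [values[subjects == s].mean() for s in order]
    )


def predict_fas_fold(
    table: FeatureTable,
    train_subjects: list[str],
    test_subjects: list[str],
    config: ModelConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Fit per-task FAS forests on the training subjects and return the
    total-FAS estimate for each test subject.

    Feature selection (CFS against the per-repetition FAS labels) runs
    inside this fold only.
    """
    train_set = set(train_subjects)
    per_subject: dict[str, dict[str, list[float]]] = {
        s: {} for s in test_subjects
    }
    for task in TASKS:
        subj = table.row_subject[task]
        tr = np.isin(subj, list(train_set))
        Xtr, ytr = table.X[task][tr], table.y_fas[task][tr]
        if np.any(np.isnan(ytr)):
            raise ValueError(f"task {task}: training rows lack FAS labels")
        mask = cfs_select(Xtr, ytr)
        if not mask.any():
            mask = np.ones(Xtr.shape[1], dtype=bool)
        rf = fit_task_rf(
            Xtr[:, mask], ytr, n_trees=config.task_trees,
            seed=int(rng.integers(2**31 - 1)),
            max_features=config.max_features,
        )
        for s in test_subjects:
            rows = table.row_subject[task] == s
            if not rows.any():
                raise ValueError(f"subject {s} has no trials for {task}")
            preds = rf.predict(table.X[task][rows][:, mask])
            per_subject[s][task] = [float(p) for p in preds]
    return {
        s: estimate_fas(per_subject[s]) for s in test_subjects
    }


def fit_method1(
    fas_true: np.ndarray, fma_true: np.ndarray
) -> LinearRegression:
    """OLS of true FMA on true FAS total (Method 1's calibration)."""
    fas_true = np.asarray(fas_true, float)
    if np.var(fas_true) < 1e-18:
        raise ValueError("Method 1 needs non-constant training FAS")
    return LinearRegression().fit(fas_true[:, None], np.asarray(fma_true))


def predict_fma_fold(
    table: FeatureTable,
    train_subjects: list[str],
    test_subjects: list[str],
    fas_hat: dict[str, float],
    config: ModelConfig,
    rng: np.random.Generator,
    methods: tuple[str, ...] = FMA_METHODS,
) -> dict[str, dict[str, float]]:
    """One cross-validation fold of the requested FMA methods.

    Returns ``{method: {subject: estimate}}`` with estimates clipped to
    [0, 66].  ``fas_hat`` must hold leakage-free sensor-based FAS
    estimates for every train and test subject (Methods 1 and 4).
    """
    for m in methods:
        if m not in FMA_METHODS:
            raise ValueError(f"unknown FMA method {m!r}")
    train = list(train_subjects)
    out: dict[str, dict[str, float]] = {m: {} for m in methods}
    y_train = np.array([table.fma[s] for s in train])

    if "m1_linreg" in methods:
        reg = fit_method1(
            np.array([table.fas_total_true[s] for s in train]), y_train
        )
        for s in test_subjects:
            val = reg.predict(np.array([[fas_hat[s]]]))[0]
            out["m1_linreg"][s] = float(np.clip(val, 0.0, 66.0))

    forest_methods = [m for m in methods if m != "m1_linreg"]
    if not forest_methods:
        return out

    # per-task forests; aggregator inputs are subject-level OOB means for
    # training subjects and ordinary predictions for test subjects
    agg_train = {m: np.zeros((len(train), len(TASKS))) for m in forest_methods}
    agg_test = {
        m: {s: np.zeros(len(TASKS)) for s in test_subjects}
        for m in forest_methods
    }
    for ti, task in enumerate(TASKS):
        subj = table.row_subject[task]
        tr = np.isin(subj, train)
        Xtr_full, ytr = table.X[task][tr], table.y_fma[task][tr]
        subj_tr = subj[tr]
        mask = cfs_select(Xtr_full, ytr)
        if not mask.any():
            mask = np.ones(Xtr_full.shape[1], dtype=bool)
        Xtr = Xtr_full[:, mask]
        if "m4_proposed" in forest_methods:
            fh_tr = np.array([fas_hat[s] for s in subj_tr])[:, None]
        for m in forest_methods:
            edges = None if m == "m2_rf" else config.class_edges
            Xm = np.hstack([Xtr, fh_tr]) if m == "m4_proposed" else Xtr
            rf = BootstrapForestRegressor(
                config.task_trees,
                class_edges=edges,
                per_class_draw=config.per_class_draw,
                max_features=config.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xm, ytr)
            oob = rf.oob_predict(Xm)
            agg_train[m][:, ti] = _subject_means(oob, subj_tr, train)
            for s in test_subjects:
                rows = subj == s
                if not rows.any():
                    raise ValueError(f"subject {s} has no trials for {task}")
                Xte = table.X[task][rows][:, mask]
                if m == "m4_proposed":
                    Xte = np.hstack(
                        [Xte, np.full((Xte.shape[0], 1), fas_hat[s])]
                    )
                agg_test[m][s][ti] = float(rf.predict(Xte).mean())

    for m in forest_methods:
        balanced = m != "m2_rf" and config.balance_aggregator
        edges = config.class_edges if balanced else None
        A_train = agg_train[m]
        if m == "m4_proposed":
            fh = np.array([fas_hat[s] for s in train])[:, None]
            A_train = np.hstack([A_train, fh])
        agg = BootstrapForestRegressor(
            config.aggregator_trees,
            class_edges=edges,
            per_class_draw=config.per_class_draw,
            max_features=config.max_features,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(A_train, y_train)
        for s in test_subjects:
            a = agg_test[m][s]
            if m == "m4_proposed":
                a = np.concatenate([a, [fas_hat[s]]])
            out[m][s] = float(np.clip(agg.predict(a[None, :])[0], 0.0, 66.0))
    return out
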