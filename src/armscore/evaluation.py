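"""Cross-validation harness and accuracy metrics.

The primary harness is leave-one-subject-out (LOSO) cross-validation:
every fold holds out *all* trials of one subject, and everything that is
fitted — feature selection, the per-task and aggregator forests, the
Method-1 regression, and the sensor-based FAS estimates that feed
Methods 1 and 4 — uses only the remaining subjects.  A record-level
k-fold mode is provided as a deliberately optimistic comparator: it
splits individual trial repetitions, so repetitions of one subject leak
between training and test, which inflates apparent accuracy.

Accuracy is summarized by RMSE, the coefficient of determination
r² = 1 − SSE/SST, and bias (mean of estimate − truth); these satisfy
RMSE² = bias² + error variance.  Per-severity-class signed-error
distributions (median, Q1, Q3 by linear-interpolation quantiles,
grouped by the *true* score's class) expose how the error varies with
impairment, and paired t tests on per-subject absolute errors compare
methods within a class.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import cfs_select
from .forest import FMA_CLASS_EDGES, fit_task_rf, fma_class
from .models import (
    FMA_METHODS,
    FeatureTable,
    ModelConfig,
    build_feature_table,
    predict_fas_fold,
    predict_fma_fold,
)
from .types import TASKS, ScoreEstimate, SubjectSession

__all__ = [
    "loso_cv",
    "metrics",
    "per_class_errors",
    "paired_class_test",
    "EvalReport",
    "build_report",
    "first_module_cv",
    "mean_predictor_loso",
]

ALL_METHODS = ("fas_rf",) + FMA_METHODS


def _fold_rng(seed: int, stream: str, fold: int) -> np.random.Generator:
    name = int.from_bytes(stream.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([seed, name, fold]))


def loso_cv(
    sessions: list[SubjectSession],
    methods: tuple[str, ...] = ALL_METHODS,
    config: ModelConfig | None = None,
    seed: int = 0,
    fas_hat_mode: str = "shared",
    table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Leave-one-subject-out estimates for the requested methods.

    Returns a tidy frame with one row per (subject, scale, method):
    columns ``subject_id, scale, method, value, fold_id, truth``.

    ``fas_hat_mode`` controls how the sensor-based FAS fed to Methods 1
    and 4 is obtained: ``"shared"`` (default) computes one LOSO pass so
    each subject's FAS estimate comes from models never trained on that
    subject; ``"nested"`` recomputes FAS estimates for the training
    subjects inside every outer fold, additionally excluding the test
    subject (far costlier, negligibly different in practice).

    Subjects missing trials for any task are excluded with a warning.
    """
    config = config or ModelConfig()
    if table is None:
        table = build_feature_table(sessions)
    subjects = table.complete_subjects()
    dropped = sorted(set(table.subjects) - set(subjects))
    if dropped:
        warnings.warn(f"excluding subjects missing tasks: {dropped}")
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 complete subjects")
    need_fas = bool(set(methods) & {"fas_rf", "m1_linreg", "m4_proposed"})
    fma_methods = tuple(m for m in methods if m in FMA_METHODS)

    fas_hat: dict[str, float] = {}
    if need_fas:
        for k, s in enumerate(subjects):
            train = [x for x in subjects if x != s]
            fas_hat[s] = predict_fas_fold(
                table, train, [s], config, _fold_rng(seed, "fas", k)
            )[s]

    rows = []
    if "fas_rf" in methods:
        for s in subjects:
            rows.append(
                ScoreEstimate(s, "FAS", "fas_rf", fas_hat[s], fold_id=s)
            )

    for k, s in enumerate(subjects):
        if not fma_methods:
            break
        train = [x for x in subjects if x != s]
        fh = fas_hat
        if fas_hat_mode == "nested" and (
            {"m1_linreg", "m4_proposed"} & set(fma_methods)
        ):
            fh = {}
            for j, t in enumerate(train):
                inner = [x for x in train if x != t]
                fh[t] = predict_fas_fold(
                    table, inner, [t], config,
                    _fold_rng(seed, "nfas", k * len(subjects) + j),
                )[t]
            fh[s] = fas_hat[s]
        preds = predict_fma_fold(
            table, train, [s], fh, config,
            _fold_rng(seed, "fma", k), methods=fma_methods,
        )
        for m in fma_methods:
            rows.append(ScoreEstimate(s, "FMA", m, preds[m][s], fold_id=s))

    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "scale": r.scale,
                "method": r.method,
                "value": r.value,
                "fold_id": r.fold_id,
                "truth": (
                    table.fas_total_true[r.subject_id]
                    if r.scale == "FAS"
                    else table.fma[r.subject_id]
                ),
            }
            for r in rows
        ]
    )
    return frame


def metrics(estimates, truth) -> dict[str, float]:
    """RMSE, r² (about the truth mean), and bias of paired estimates."""
    est = np.asarray(estimates, float)
    y = np.asarray(truth, float)
    if est.size == 0 or est.shape != y.shape:
        raise ValueError("estimates and truth must be nonempty and paired")
    err = est - y
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sst <= 0 else float(1.0 - np.sum(err**2) / sst)
    return {"rmse": rmse, "r2": r2, "bias": bias}


def per_class_errors(
    estimates, truth, class_edges=FMA_CLASS_EDGES
) -> list[dict]:
    """Signed-error quartiles grouped by the true score's severity class.

    Signed error is estimate − truth (overestimation of the most
    impaired shows as a positive median in class 1).  Empty classes are
    reported with ``n=0`` and null quantiles.
    """
    est = np.asarray(estimates, float)
    y = np.asarray(truth, float)
    err = est - y
    cls = fma_class(y, class_edges)
    out = []
    for c in range(1, len(class_edges) + 2):
        e = err[cls == c]
        if e.size == 0:
            out.append(
                {"class": c, "n": 0, "median": None, "q1": None, "q3": None}
            )
        else:
            q1, med, q3 = np.percentile(e, [25, 50, 75])  # linear (type-7)
            out.append(
                {"class": c, "n": int(e.size), "median": float(med),
                 "q1": float(q1), "q3": float(q3)}
            )
    return out


def paired_class_test(errors_a, errors_b) -> float:
    """Two-sided paired t test on per-subject absolute errors.

    Returns NaN for n < 2 or zero-variance differences (degenerate t).
    """
    a = np.abs(np.asarray(errors_a, float))
    b = np.abs(np.asarray(errors_b, float))
    if a.shape != b.shape:
        raise ValueError("error vectors must be paired")
    if a.size < 2:
        return float("nan")
    d = a - b
    if np.std(d, ddof=1) < 1e-15:
        return float("nan")
    return float(sstats.ttest_rel(a, b).pvalue)


@dataclass
class EvalReport:
    """Accuracy report for one method on one scale."""

    method: str
    scale: str
    n: int
    rmse: float
    r2: float
    bias: float
    per_class: list[dict]

    def to_dict(self) -> dict:
        return asdict(self)


def compare_methods_per_class(
    frame: pd.DataFrame,
    method_a: str,
    method_b: str,
    scale: str = "FMA",
    class_edges=FMA_CLASS_EDGES,
) -> dict[int, float]:
    """Per-severity-class paired t tests of absolute error, A vs B.

    Subjects are matched across methods; classes with fewer than two
    subjects (or degenerate differences) report NaN.
    """
    sub_a = frame[(frame["method"] == method_a) & (frame["scale"] == scale)]
    sub_b = frame[(frame["method"] == method_b) & (frame["scale"] == scale)]
    merged = sub_a.merge(
        sub_b, on="subject_id", suffixes=("_a", "_b"), validate="1:1"
    )
    if merged.empty:
        raise ValueError(f"no paired estimates for {method_a} vs {method_b}")
    err_a = merged["value_a"].to_numpy() - merged["truth_a"].to_numpy()
    err_b = merged["value_b"].to_numpy() - merged["truth_b"].to_numpy()
    cls = fma_class(merged["truth_a"].to_numpy(), class_edges)
    return {
        int(c): paired_class_test(err_a[cls == c], err_b[cls == c])
        for c in range(1, len(class_edges) + 2)
    }


def build_report(
    frame: pd.DataFrame, method: str, scale: str,
    class_edges=FMA_CLASS_EDGES,
) -> EvalReport:
    sub = frame[(frame["method"] == method) & (frame["scale"] == scale)]
    if sub.empty:
        raise ValueError(f"no estimates for {method}/{scale}")
    m = metrics(sub["value"].to_numpy(), sub["truth"].to_numpy())
    pc = (
        per_class_errors(
            sub["value"].to_numpy(), sub["truth"].to_numpy(), class_edges
        )
        if scale == "FMA"
        else []
    )
    return EvalReport(
        method=method, scale=scale, n=len(sub),
        rmse=m["rmse"], r2=m["r2"], bias=m["bias"], per_class=pc,
    )


def mean_predictor_loso(sessions_or_truth) -> dict[str, float]:
    """LOSO estimates of a training-mean baseline; r² ≤ 0 by construction."""
    if isinstance(sessions_or_truth, dict):
        truth = dict(sessions_or_truth)
    else:
        truth = {
            s.subject_id: float(s.fma_true) for s in sessions_or_truth
        }
    ids = list(truth)
    vals = np.array([truth[s] for s in ids])
    n = len(ids)
    return {
        s: float((vals.sum() - vals[i]) / (n - 1)) for i, s in enumerate(ids)
    }


def first_module_cv(
    sessions: list[SubjectSession],
    mode: str = "loso",
    k: int = 10,
    leaky_selection: bool = False,
    seed: int = 0,
    n_trees: int = 100,
    table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Per-task-forest FMA estimation without the aggregator stage.

    Subject estimates are the mean of the per-task forest predictions
    over all of a subject's held-out trials.  ``mode="loso"`` holds out
    subjects; ``mode="kfold"`` splits individual trial records so a
    subject's repetitions leak across folds, and ``leaky_selection``
    additionally runs feature selection on the full data — together the
    classic recipe for optimistic small-sample accuracy.
    """
    if table is None:
        table = build_feature_table(sessions)
    subjects = table.complete_subjects()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    pred_sum = {s: 0.0 for s in subjects}
    pred_n = {s: 0 for s in subjects}
    for task in TASKS:
        X, y = table.X[task], table.y_fma[task]
        subj = table.row_subject[task]
        keep = np.isin(subj, subjects)
        X, y, subj = X[keep], y[keep], subj[keep]
        n = len(y)
        if leaky_selection:
            mask_all = cfs_select(X, y)
            if not mask_all.any():
                mask_all = np.ones(X.shape[1], bool)
        if mode == "loso":
            folds = [(subj != s, subj == s) for s in subjects]
        elif mode == "kfold":
            perm = rng.permutation(n)
            folds = []
            for part in np.array_split(perm, k):
                te = np.zeros(n, bool)
                te[part] = True
                folds.append((~te, te))
        else:
            raise ValueError(f"unknown cv mode {mode!r}")
        for tr, te in folds:
            if not te.any():
                continue
            mask = (
                mask_all if leaky_selection else cfs_select(X[tr], y[tr])
            )
            if not mask.any():
                mask = np.ones(X.shape[1], bool)
            rf = fit_task_rf(
                X[tr][:, mask], y[tr], n_trees=n_trees,
                seed=int(rng.integers(2**31 - 1)),
            )
            p = rf.predict(X[te][:, mask])
            for s, v in zip(subj[te], p):
                pred_sum[s] += float(v)
                pred_n[s] += 1
    return pd.DataFrame(
        {
            "subject_id": subjects,
            "value": [
                float(np.clip(pred_sum[s] / pred_n[s], 0, 66))
                for s in subjects
            ],
            "truth": [table.fma[s] for s in subjects],
        }
    )
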