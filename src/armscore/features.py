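"""Per-trial feature extraction and correlation-based feature selection.

Nine feature families are computed from the filtered kinematic magnitude
series (displacement, velocity, acceleration, jerk) of every worn
sensor: min / max / mean, RMS, dominant-frequency ratio (periodogram
peak power over total non-DC power), bias-corrected skewness, excess
kurtosis, histogram Shannon entropy, plus inter-axis and inter-sensor
correlation coefficients and the trial duration.  The inter-sensor
correlations of acceleration magnitude capture relative movement of body
segments — e.g. trunk lean accompanying an arm reach, the classic
compensation pattern in hemiparesis.

Feature selection is Hall's correlation-based feature selection (CFS): a
best-first search over feature subsets ``S`` maximizing the merit

    M(S) = k · r̄_cf / sqrt(k + k(k−1) · r̄_ff)

where ``k = |S|``, ``r̄_cf`` is the mean absolute Pearson correlation of
the subset's features with the target and ``r̄_ff`` the mean absolute
pairwise correlation within the subset.  The search stops after five
consecutive non-improving node expansions.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .dsp import bandfilter, derive_kinematics, segment_trial
from .types import PLACEMENTS, FeatureVector, SensorTrial

__all__ = [
    "FeatureCatalog",
    "catalog_for",
    "extract_features",
    "series_stats",
    "safe_corr",
    "cfs_merit",
    "cfs_select",
    "ENTROPY_BINS",
]

ENTROPY_BINS = 16
_SERIES = ("disp", "vel", "acc", "jerk")
_STATS = (
    "min",
    "max",
    "mean",
    "rms",
    "domfreq_ratio",
    "skew",
    "kurtosis",
    "entropy",
)
_VAR_TOL = 1e-24


@dataclass(frozen=True)
class FeatureCatalog:
    """Deterministic ordered list of feature identifiers for a montage."""

    placements: tuple[str, ...]
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)


def catalog_for(placements) -> FeatureCatalog:
    placements = tuple(p for p in PLACEMENTS if p in set(placements))
    names: list[str] = []
    for p in placements:
        for series in _SERIES:
            for stat in _STATS:
                names.append(f"{p}.{series}.{stat}")
    # intra-sensor inter-axis correlations of the filtered acceleration
    axis_names = ("x", "y", "z")
    for p in placements:
        n_axes = 2 if p in ("thumb_affected", "index_affected") else 3
        for i in range(n_axes):
            for j in range(i + 1, n_axes):
                names.append(f"{p}.acc_axes.corr_{axis_names[i]}{axis_names[j]}")
    # inter-sensor correlations of acceleration magnitude
    for i, p in enumerate(placements):
        for q in placements[i + 1:]:
            names.append(f"corr.{p}.{q}")
    names.append("duration")
    return FeatureCatalog(placements=placements, names=tuple(names))


def safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, defined as 0.0 when either input is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or np.var(a) < _VAR_TOL or np.var(b) < _VAR_TOL:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _dominant_frequency_ratio(x: np.ndarray) -> float:
    # rectangular-window periodogram; DC bin excluded (the high-pass has
    # removed DC anyway, and including it would make the peak degenerate)
    power = np.abs(np.fft.rfft(x)) ** 2
    power = power[1:]
    total = power.sum()
    if total <= 0.0:
        return 0.0
    return float(power.max() / total)


def _entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return 0.0
    z = (x - lo) / (hi - lo)
    counts, _ = np.histogram(z, bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def _bias_corrected_moments(x: np.ndarray) -> tuple[float, float]:
    """Sample skewness G1 and excess kurtosis G2 (bias-corrected, the
    scipy ``bias=False`` convention), computed directly from moments."""
    n = x.size
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 < _VAR_TOL or n < 4:
        return 0.0, 0.0
    g1 = np.mean(xc**3) / m2**1.5
    g2 = np.mean(xc**4) / m2**2 - 3.0
    G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
    G2 = ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))
    return float(G1), float(G2)


def series_stats(x: np.ndarray) -> dict[str, float]:
    """The eight scalar statistics for one magnitude series."""
    x = np.asarray(x, float)
    skew, kurt = _bias_corrected_moments(x)
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "rms": float(np.sqrt(np.mean(x**2))),
        "domfreq_ratio": _dominant_frequency_ratio(x),
        "entropy": _entropy(x),
        "skew": skew,
        "kurtosis": kurt,
    }


def extract_features(
    trial: SensorTrial, *, catalog: FeatureCatalog | None = None,
    subject_id: str = "",
) -> FeatureVector:
    """Segment, filter, and featurize one trial.

    Output order follows the catalog and is identical across trials of
    the same montage.
    """
    if catalog is None:
        catalog = catalog_for(trial.channels.keys())
    seg = segment_trial(trial)
    fs = seg.fs
    filtered = {
        p: bandfilter(ch.samples, fs) for p, ch in seg.channels.items()
    }
    kin = {}
    for p in catalog.placements:
        ch = seg.channels[p]
        kin[p] = derive_kinematics(
            type(ch)(p, filtered[p], fs), prefiltered=True
        ).as_dict()
    values: dict[str, float] = {}
    for p in catalog.placements:
        for series in _SERIES:
            for stat, v in series_stats(kin[p][series]).items():
                values[f"{p}.{series}.{stat}"] = v
    axis_names = ("x", "y", "z")
    for p in catalog.placements:
        sig = filtered[p]
        for i in range(sig.shape[1]):
            for j in range(i + 1, sig.shape[1]):
                values[f"{p}.acc_axes.corr_{axis_names[i]}{axis_names[j]}"] = (
                    safe_corr(sig[:, i], sig[:, j])
                )
    for i, p in enumerate(catalog.placements):
        for q in catalog.placements[i + 1:]:
            values[f"corr.{p}.{q}"] = safe_corr(kin[p]["acc"], kin[q]["acc"])
    values["duration"] = seg.n_samples / fs
    vec = FeatureVector(
        names=list(catalog.names),
        values=np.array([values[n] for n in catalog.names]),
        task_id=trial.task_id,
        subject_id=subject_id,
        repetition=trial.repetition,
    )
    vec.validate()
    return vec


# ---------------------------------------------------------------------------
# correlation-based feature selection


def _abs_correlations(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    ok = (sx > 1e-12) & np.isfinite(sx)
    rcf = np.zeros(p)
    if sy > 1e-12:
        rcf[ok] = np.abs(Xc[:, ok].T @ yc) / (sx[ok] * sy)
    denom = np.outer(sx, sx)
    with np.errstate(invalid="ignore", divide="ignore"):
        rff = np.abs(Xc.T @ Xc) / denom
    rff[~ok, :] = 0.0
    rff[:, ~ok] = 0.0
    rff = np.nan_to_num(rff, nan=0.0)
    np.fill_diagonal(rff, 1.0)
    return np.clip(rcf, 0, 1), np.clip(rff, 0, 1)


def cfs_merit(X: np.ndarray, y: np.ndarray, subset) -> float:
    """CFS merit of an explicit feature subset (column indices)."""
    subset = list(subset)
    if not subset:
        return 0.0
    rcf, rff = _abs_correlations(np.asarray(X, float), np.asarray(y, float))
    return _merit_from(rcf, rff, subset)


def _merit_from(rcf, rff, subset) -> float:
    k = len(subset)
    num = rcf[subset].sum()
    idx = np.asarray(subset)
    pair_sum = (rff[np.ix_(idx, idx)].sum() - k) / 2.0
    den = np.sqrt(k + 2.0 * pair_sum)
    return float(num / den) if den > 0 else 0.0


def cfs_select(
    X: np.ndarray,
    y: np.ndarray,
    *,
    patience: int = 5,
    max_expansions: int = 2000,
) -> np.ndarray:
    """Best-first CFS; returns a boolean mask over feature columns.

    Raises ``ValueError`` for fewer than 2 features or a constant target;
    returns an empty mask (with a warning) when every feature is
    constant.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if p < 2:
        raise ValueError("CFS needs at least 2 candidate features")
    if np.var(y) < _VAR_TOL:
        raise ValueError("CFS target is constant")
    rcf, rff = _abs_correlations(X, y)
    if not np.any(rcf > 0):
        warnings.warn("all features constant or uncorrelated; empty selection")
        return np.zeros(p, dtype=bool)

    # node: (-merit, tiebreak, subset tuple, rcf sum, pairwise rff sum)
    heap: list[tuple] = [(0.0, 0, (), 0.0, 0.0)]
    visited = {()}
    best_merit, best_subset = 0.0, ()
    nonimproving = 0
    counter = 1
    expansions = 0
    while heap and nonimproving < patience and expansions < max_expansions:
        _, _, subset, num, pair_sum = heapq.heappop(heap)
        expansions += 1
        k = len(subset)
        in_subset = np.zeros(p, dtype=bool)
        in_subset[list(subset)] = True
        cand = np.flatnonzero(~in_subset)
        if cand.size == 0:
            nonimproving += 1
            continue
        if k:
            add_ff = rff[np.ix_(cand, list(subset))].sum(axis=1)
        else:
            add_ff = np.zeros(cand.size)
        nums = num + rcf[cand]
        dens = np.sqrt((k + 1) + 2.0 * (pair_sum + add_ff))
        merits = np.where(dens > 0, nums / dens, 0.0)
        improved = False
        order = np.argsort(merits)[::-1][:50]  # bound the frontier width
        for oi in order:
            f = int(cand[oi])
            child = tuple(sorted(subset + (f,)))
            if child in visited:
                continue
            visited.add(child)
            m = float(merits[oi])
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
            heapq.heappush(
                heap, (-m, counter, child, float(nums[oi]),
                       float(pair_sum + add_ff[oi]))
            )
            counter += 1
        nonimproving = 0 if improved else nonimproving + 1

    mask = np.zeros(p, dtype=bool)
    mask[list(best_subset)] = True
    return mask
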