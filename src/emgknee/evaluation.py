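"""Metrics, cross-validation folds, stride averaging and method comparison.

NRMSE is the root-mean-squared error normalized by the measured-angle range
and reported in percent; CC is the Pearson correlation coefficient between
measured and estimated angles.  Methods are compared per fold with the
Kruskal-Wallis rank test (p < 0.05 convention).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .exceptions import EmptyInputError, MetricError, ParameterError, PartitionError


def nrmse(y, y_hat) -> float:
    """Range-normalized RMSE in percent: 100 * RMSE / (y_max - y_min)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ParameterError("y and y_hat must be equal-length non-empty vectors")
    rng = y.max() - y.min()
    if rng <= 0:
        raise MetricError("NRMSE undefined for constant measured angles")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / rng * 100.0)


def cc(y, y_hat) -> float:
    """Pearson correlation C_{y,y_hat} / (sigma_y sigma_y_hat)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size < 2:
        raise ParameterError("need two equal-length vectors of length >= 2")
    sy = y.std()
    syh = y_hat.std()
    if sy == 0 or syh == 0:
        raise MetricError("correlation undefined for a constant series")
    cov = np.mean((y - y.mean()) * (y_hat - y_hat.mean()))
    return float(cov / (sy * syh))


def make_folds(n=None, k=5, scheme="trial", trial_ids=None, seed=0) -> np.ndarray:
    """Assign each window to one of ``k`` test folds.

    scheme="trial" (default): whole trials are grouped contiguously so that
    overlapping windows from one trial never span the train/test split; trial
    counts per fold differ by at most one.  scheme="window": seeded random
    partition of window indices with sizes differing by at most one (for
    leakage ablations).
    """
    if scheme == "trial":
        if trial_ids is None:
            raise ParameterError("scheme='trial' needs trial_ids")
        trial_ids = np.asarray(trial_ids)
        trials = list(dict.fromkeys(trial_ids.tolist()))  # order of appearance
        if k > len(trials):
            raise PartitionError(f"k={k} folds but only {len(trials)} trials")
        groups = np.array_split(np.arange(len(trials)), k)
        lookup = {}
        for fold, grp in enumerate(groups):
            for gi in grp:
                lookup[trials[gi]] = fold
        return np.array([lookup[t] for t in trial_ids.tolist()], dtype=int)
    if scheme == "window":
        if n is None:
            raise ParameterError("scheme='window' needs n")
        if k > n:
            raise PartitionError(f"k={k} folds but only {n} windows")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for fold, grp in enumerate(np.array_split(perm, k)):
            folds[grp] = fold
        return folds
    raise ParameterError(f"unknown scheme {scheme!r}")


def train_test_indices(fold_ids, fold):
    """(train_idx, test_idx) for one fold; asserts the split is disjoint."""
    fold_ids = np.asarray(fold_ids)
    test = np.flatnonzero(fold_ids == fold)
    train = np.flatnonzero(fold_ids != fold)
    assert np.intersect1d(train, test).size == 0
    return train, test


def stride_average(y, cycle_bounds, n_points=101):
    """Average a time series across gait cycles on a 0-100% phase grid.

    ``cycle_bounds`` are sample positions (float allowed) of consecutive
    cycle starts; each cycle [b_i, b_{i+1}) is linearly resampled to
    ``n_points`` points and the cycles are averaged pointwise.
    """
    y = np.asarray(y, dtype=float)
    b = np.asarray(cycle_bounds, dtype=float)
    if b.size < 2:
        raise EmptyInputError("need at least one complete cycle")
    grid = np.arange(y.size, dtype=float)
    profiles = []
    for lo, hi in zip(b[:-1], b[1:]):
        pts = np.linspace(lo, hi, n_points)
        profiles.append(np.interp(pts, grid, y))
    return np.mean(profiles, axis=0)


def detect_cycles(angle, angle_rate, min_cycle_s=0.6):
    """Cycle starts as knee-angle minima (heel-strike proxy), sample indices."""
    from scipy.signal import find_peaks

    angle = np.asarray(angle, dtype=float)
    distance = max(int(min_cycle_s * angle_rate), 1)
    idx, _ = find_peaks(-angle, distance=distance)
    return idx.astype(float)


def kruskal_wallis(*groups):
    """Kruskal-Wallis H (tie-corrected) and chi-square p across >= 2 groups."""
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise EmptyInputError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ParameterError("need at least three observations in total")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        raise MetricError("all observations identical; ranks are degenerate")
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)
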