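"""The 14-value handcrafted sEMG feature bank.

For a window ``x = {x_1, ..., x_n}`` the features, in fixed order, are

==========  ===========================================================
iemg        integrated EMG, sum of |x_i|
mav         mean absolute value, iemg / n
mean        arithmetic mean
rms         root mean square
var         sample variance (ddof = 1)
kurtosis    Pearson kurtosis m4 / m2^2 (biased central moments, not excess)
skewness    m3 / m2^(3/2)
zc          zero crossings: pairs with x_i * x_{i+1} < 0 and
            |x_i - x_{i+1}| >= zc_threshold
ssc         slope sign changes: interior points with
            (x_i - x_{i-1}) (x_i - x_{i+1}) > 0 and
            max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) >= ssc_threshold
wl          waveform length, sum of |x_{i+1} - x_i|
ar1..ar4    Yule-Walker AR(4) coefficients (Levinson-Durbin) of the
            demeaned window, predictor sign convention
            x_t = sum_k ar_k x_{t-k} + e_t
==========  ===========================================================

Both thresholds default to 0.  Windows with zero variance return 0 for the
moment ratios and the AR coefficients instead of NaN, so downstream
regressors never see non-finite values.
"""

from __future__ import annotations

import numpy as np

from .exceptions import WindowSizeError

FEATURE_NAMES = (
    "iemg", "mav", "mean", "rms", "var", "kurtosis", "skewness",
    "zc", "ssc", "wl", "ar1", "ar2", "ar3", "ar4",
)

N_FEATURES = len(FEATURE_NAMES)  # 14

_AR_ORDER = 4
_MIN_WINDOW = 8  # AR(4) needs autocovariances to lag 4 on a demeaned window


def _autocovariances(w: np.ndarray, order: int) -> np.ndarray:
    """Biased autocovariances r_0..r_order of demeaned rows of w (N, n)."""
    n = w.shape[1]
    d = w - w.mean(axis=1, keepdims=True)
    r = np.empty((w.shape[0], order + 1))
    for k in range(order + 1):
        r[:, k] = np.einsum("ij,ij->i", d[:, : n - k], d[:, k:]) / n
    return r


def ar_coefficients_matrix(windows: np.ndarray, order: int = _AR_ORDER):
    """Yule-Walker AR coefficients for every row, via Levinson-Durbin.

    Returns ``(coeffs, degenerate)`` where ``coeffs`` has shape (N, order) and
    ``degenerate`` flags rows whose recursion broke down (zero variance or a
    vanishing prediction-error power); those rows are all-zero.
    """
    w = np.atleast_2d(np.asarray(windows, dtype=float))
    if w.shape[1] <= order:
        raise WindowSizeError(f"need more than {order} samples for AR({order})")
    r = _autocovariances(w, order)
    N = w.shape[0]
    phi = np.zeros((N, order))        # current-order coefficients
    err = r[:, 0].copy()              # prediction-error power
    degenerate = err <= 0.0
    err[degenerate] = 1.0             # placeholder; rows zeroed at the end
    for k in range(1, order + 1):
        acc = r[:, k].copy()
        for j in range(1, k):
            acc -= phi[:, j - 1] * r[:, k - j]
        kappa = acc / err
        new_phi = phi.copy()
        new_phi[:, k - 1] = kappa
        for j in range(1, k):
            new_phi[:, j - 1] = phi[:, j - 1] - kappa * phi[:, k - j - 1]
        phi = new_phi
        err = err * (1.0 - kappa ** 2)
        bad = ~np.isfinite(err) | (err <= 0.0)
        if k < order:
            degenerate |= bad
            err[bad] = 1.0
    degenerate |= ~np.isfinite(phi).all(axis=1)
    phi[degenerate] = 0.0
    return phi, degenerate


def ar_coefficients(window: np.ndarray, order: int = _AR_ORDER):
    """AR coefficients of a single window; see :func:`ar_coefficients_matrix`."""
    phi, flag = ar_coefficients_matrix(np.asarray(window, dtype=float)[None, :], order)
    return phi[0], bool(flag[0])


def feature_matrix(windows: np.ndarray, zc_threshold=0.0, ssc_threshold=0.0) -> np.ndarray:
    """Compute the 14 features for every row of ``windows`` (N, n) -> (N, 14)."""
    w = np.atleast_2d(np.asarray(windows, dtype=float))
    N, n = w.shape
    if n < _MIN_WINDOW:
        raise WindowSizeError(f"window of {n} samples; need at least {_MIN_WINDOW}")

    out = np.empty((N, N_FEATURES))
    absw = np.abs(w)
    out[:, 0] = absw.sum(axis=1)                      # iemg
    out[:, 1] = out[:, 0] / n                         # mav
    mean = w.mean(axis=1)
    out[:, 2] = mean
    out[:, 3] = np.sqrt(np.einsum("ij,ij->i", w, w) / n)  # rms
    d = w - mean[:, None]
    m2 = np.einsum("ij,ij->i", d, d) / n
    out[:, 4] = m2 * n / (n - 1)                      # var, ddof=1
    m3 = (d ** 3).sum(axis=1) / n
    m4 = (d ** 4).sum(axis=1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = m4 / m2 ** 2
        skew = m3 / m2 ** 1.5
    zero_var = m2 <= 0.0
    out[:, 5] = np.where(zero_var, 0.0, kurt)
    out[:, 6] = np.where(zero_var, 0.0, skew)

    step = np.abs(np.diff(w, axis=1))
    out[:, 7] = ((w[:, :-1] * w[:, 1:] < 0) & (step >= zc_threshold)).sum(axis=1)
    dl = w[:, 1:-1] - w[:, :-2]    # x_i - x_{i-1}
    dr = w[:, 1:-1] - w[:, 2:]     # x_i - x_{i+1}
    out[:, 8] = (
        (dl * dr > 0) & (np.maximum(np.abs(dl), np.abs(dr)) >= ssc_threshold)
    ).sum(axis=1)
    out[:, 9] = step.sum(axis=1)                      # wl

    out[:, 10:14], _ = ar_coefficients_matrix(w)
    return out


def extract_handcrafted(window, zc_threshold=0.0, ssc_threshold=0.0) -> np.ndarray:
    """The 14-feature vector **p** for a single window."""
    return feature_matrix(np.asarray(window, dtype=float)[None, :],
                          zc_threshold, ssc_threshold)[0]


def features_to_frame(features: np.ndarray):
    """Wrap a feature matrix in a DataFrame with the canonical column names."""
    import pandas as pd

    return pd.DataFrame(np.atleast_2d(features), columns=list(FEATURE_NAMES))
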