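"""Normalized lagged cross-correlation and synchronization-peak detection.

The statistic for a lag tau (in samples) is

    R_xy(tau) = 1/(N-1) * sum_t (x(t+tau) - xbar) (y(t) - ybar) / (sx * sy)

with the sum over the overlapping range, means and sample SDs (N-1
denominator) taken over the full series.  R_xy(0) = 1 when x == y.

Sign convention: pairing x(t+tau) with y(t) means a peak at *positive*
tau indicates that y's fluctuations precede x's by tau samples (y leads,
x follows).  Under this convention the blindfolded partner's documented
lead is negative in BO (x blindfolded) and positive in OB.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .datatypes import CrossCorrResult


def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int | None = None,
    fs: float = 200.0,
) -> CrossCorrResult:
    """Normalized cross-correlation of two equal-length series.

    Parameters
    ----------
    x, y
        Equal-length 1-D series (already detrended/tapered as desired).
    max_lag
        Largest |tau| in samples.  Defaults to 5 s worth of samples
        (capped at N-1), enough context around the +/-1 s peak window.
    fs
        Sampling rate, used only to express lags in ms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of identical length")
    n = len(x)
    if n < 2:
        raise ValueError("series must have length >= 2")
    if max_lag is None:
        max_lag = min(n - 1, int(round(5 * fs)))
    if not 0 <= max_lag < n:
        raise ValueError("max_lag must satisfy 0 <= max_lag < len(x)")

    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()

    # full overlapping-range lagged sums: index n-1+tau holds
    # sum_t x(t+tau) * y(t).  FFT-based correlate reproduces the direct
    # sum to ~1e-12 relative error.
    full = signal.correlate(xc, yc, mode="full", method="auto")
    lags = np.arange(-max_lag, max_lag + 1)
    values = full[(n - 1) + lags] / ((n - 1) * sx * sy)

    result = CrossCorrResult(lags=lags, values=values, fs=fs, n_points=n)
    try:
        result.peak_lag_ms = detect_peak_lag(result)
        in_window = np.abs(result.lags_ms) <= 1000.0 + 1e-9
        result.peak_value = float(
            np.max(result.values[in_window])
        )
    except ValueError:
        pass  # lag range narrower than the default peak window: leave unset
    return result


def average_curves(results: Sequence[CrossCorrResult]) -> CrossCorrResult:
    """Point-wise mean of correlation curves sharing one lag grid."""
    results = list(results)
    if not results:
        raise ValueError("no curves to average")
    first = results[0]
    for r in results[1:]:
        if not np.array_equal(r.lags, first.lags):
            raise ValueError("curves have mismatched lag grids")
        if r.fs != first.fs:
            raise ValueError("curves have mismatched sampling rates")
    values = np.mean([r.values for r in results], axis=0)
    out = CrossCorrResult(
        lags=first.lags.copy(),
        values=values,
        fs=first.fs,
        n_points=first.n_points,
    )
    try:
        out.peak_lag_ms = detect_peak_lag(out)
        in_window = np.abs(out.lags_ms) <= 1000.0 + 1e-9
        out.peak_value = float(np.max(out.values[in_window]))
    except ValueError:
        pass
    return out


def detect_peak_lag(
    result: CrossCorrResult,
    window_s: float = 1.0,
    use_abs: bool = False,
) -> float:
    """Lag (ms) of the maximum correlation within ``[-window_s, +window_s]``.

    The peak is the maximum *positive* correlation by default
    (``use_abs=True`` switches to the maximum magnitude).  Exact ties are
    broken toward the smallest |lag| and, among equal |lag|, the negative
    one — a fixed, documented rule so results are deterministic.
    """
    lags_ms = result.lags_ms
    mask = np.abs(lags_ms) <= window_s * 1000.0 + 1e-9
    if not np.any(mask):
        raise ValueError("peak window contains no computed lags")
    vals = np.abs(result.values[mask]) if use_abs else result.values[mask]
    win_lags = lags_ms[mask]
    best = vals.max()
    candidates = win_lags[vals == best]
    order = np.lexsort((candidates, np.abs(candidates)))
    return float(candidates[order[0]])


def peak_lag_table(
    trials_and_curves: Iterable[tuple], window_s: float = 1.0
):
    """Long-format table of per-trial peak lags.

    ``trials_and_curves`` yields (SwayTrial, CrossCorrResult) pairs; the
    returned DataFrame has one row per trial with full provenance.
    """
    import pandas as pd

    rows = []
    for trial, curve in trials_and_curves:
        lag = detect_peak_lag(curve, window_s=window_s)
        in_window = np.abs(curve.lags_ms) <= window_s * 1000.0 + 1e-9
        rows.append(
            {
                "pair_id": trial.pair_id,
                "axis": trial.axis,
                "distance": trial.distance,
                "condition": trial.condition,
                "trial_id": trial.trial_id,
                "peak_lag_ms": lag,
                "peak_value": float(np.max(curve.values[in_window])),
            }
        )
    return pd.DataFrame(rows)
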