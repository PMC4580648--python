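"""Bivariate autoregressive (AR) estimation at the 5 Hz model rate.

Each channel is regressed by ordinary least squares on the joint history
of both channels over N lags:

    x(t) = sum_i a_i x(t-i) + sum_i b_i y(t-i) + u_x(t)
    y(t) = sum_i c_i x(t-i) + sum_i d_i y(t-i) + u_y(t)

No intercept is included: inputs are detrended before fitting.  The model
order is selected by minimizing AIC over 1..20 as a diagnostic, but the
production analyses fix order 3 so that order selection cannot leak into
the statistical comparisons.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ARModel

#: AR order used by all production analyses.
PRODUCTION_ORDER = 3


def _lagged_design(z: np.ndarray, order: int, start: int) -> np.ndarray:
    """Regressor matrix with columns [x(t-1), y(t-1), ..., x(t-p), y(t-p)].

    ``z`` has shape (2, n); rows of the output correspond to t = start..n-1.
    """
    n = z.shape[1]
    cols = []
    for lag in range(1, order + 1):
        cols.append(z[0, start - lag : n - lag])
        cols.append(z[1, start - lag : n - lag])
    return np.column_stack(cols)


def fit_var(
    x: np.ndarray,
    y: np.ndarray,
    order: int = PRODUCTION_ORDER,
    fs: float = 5.0,
) -> ARModel:
    """OLS fit of the bivariate AR model of the given order.

    Noise variances are residual sums of squares divided by
    ``n_eff - 2*order`` (the per-equation parameter count), the unbiased
    per-equation estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of identical length")
    if order < 1:
        raise ValueError("order must be >= 1")
    n = len(x)
    if n <= 10 * order:
        raise ValueError(
            f"series length {n} too short for order {order} "
            f"(need > {10 * order} samples)"
        )
    z = np.vstack([x, y])
    design = _lagged_design(z, order, order)
    target = z[:, order:].T  # (n_eff, 2)
    n_eff = target.shape[0]

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < "
            f"{design.shape[1]}): channels are collinear or degenerate"
        )
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)

    # beta has shape (2*order, 2): column 0 = x-equation, column 1 = y-eq.
    coeffs = np.empty((order, 2, 2))
    for i in range(order):
        coeffs[i, 0, 0] = beta[2 * i, 0]      # a_{i+1}
        coeffs[i, 0, 1] = beta[2 * i + 1, 0]  # b_{i+1}
        coeffs[i, 1, 0] = beta[2 * i, 1]      # c_{i+1}
        coeffs[i, 1, 1] = beta[2 * i + 1, 1]  # d_{i+1}

    resid = (target - design @ beta).T  # (2, n_eff)
    dof = n_eff - 2 * order
    if dof <= 0:
        raise ValueError("not enough observations for the requested order")
    noise_var = (
        float(resid[0] @ resid[0] / dof),
        float(resid[1] @ resid[1] / dof),
    )
    aic = _aic(resid, n_eff, order)
    return ARModel(
        order=order,
        coeffs=coeffs,
        noise_var=noise_var,
        residuals=resid,
        fs=fs,
        aic=aic,
        n_obs=n,
    )


def _aic(resid: np.ndarray, n_eff: int, order: int) -> float:
    """AIC = n_eff * ln det(Sigma_ML) + 2 * (4 * order)."""
    sigma = resid @ resid.T / n_eff
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return float("inf")
    return float(n_eff * logdet + 2 * (4 * order))


def select_order_aic(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = 20,
    fs: float = 5.0,
) -> tuple[int, np.ndarray]:
    """AIC-minimizing AR order over 1..max_order.

    All candidate orders are fit on the same effective sample (the first
    ``max_order`` points are withheld for every candidate) so the AIC
    values are comparable.  Returns ``(best_order, aic_curve)`` where
    ``aic_curve[p-1]`` is AIC at order p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of identical length")
    n = len(x)
    if n <= 10 * max_order:
        raise ValueError(
            f"series length {n} too short for max_order {max_order}"
        )
    z = np.vstack([x, y])
    target = z[:, max_order:].T
    n_eff = target.shape[0]
    full_design = _lagged_design(z, max_order, max_order)

    aics = np.empty(max_order)
    for p in range(1, max_order + 1):
        design = full_design[:, : 2 * p]
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = (target - design @ beta).T
        aics[p - 1] = _aic(resid, n_eff, p)
    best = int(np.argmin(aics)) + 1
    return best, aics


def check_residual_whiteness(
    model: ARModel, max_lag: int = 10, alpha: float = 0.05
) -> dict:
    """Ljung-Box whiteness per channel plus residual cross-correlation.

    Returns a report dict with per-channel portmanteau statistics and
    p-values at ``max_lag`` lags, the lag-0 cross-correlation between the
    two residual channels, and pass/fail flags at ``alpha``.
    """
    resid = model.residuals
    n = resid.shape[1]
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the residual length")

    from statsmodels.stats.diagnostic import acorr_ljungbox

    report: dict = {"max_lag": max_lag, "alpha": alpha, "channels": {}}
    all_white = True
    for name, series in (("x", resid[0]), ("y", resid[1])):
        lb = acorr_ljungbox(series, lags=[max_lag], return_df=True)
        stat = float(lb["lb_stat"].iloc[0])
        p = float(lb["lb_pvalue"].iloc[0])
        white = p > alpha
        all_white &= white
        report["channels"][name] = {"lb_stat": stat, "p": p, "white": white}

    r0 = float(np.corrcoef(resid[0], resid[1])[0, 1])
    # 2/sqrt(n) is the usual approximate 95% band for a correlation of
    # independent series; used as the independence screen.
    independent = abs(r0) < 2.0 / np.sqrt(n)
    report["residual_cross_corr_lag0"] = r0
    report["noise_independent"] = independent
    report["passed"] = bool(all_white and independent)
    return report
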