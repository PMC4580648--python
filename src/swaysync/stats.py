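"""Inferential statistics for the synchronization analyses.

Units of analysis follow the study design: lag tests and the
influence-difference regression operate on *pairs* (one lag and one
SigmaNCR difference per dyad), while the SigmaNCR ANOVA operates on
*individual participants* (each participant contributes a complete
2 x 2 x 2 SENDER x RECEIVER x DISTANCE cell table, SigmaNCR being the
influence that participant received from the partner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AnovaEffect, AnovaResult, RegressionResult
from .preprocess import detrend_linear


def bonferroni_correct(p: float, m: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p)


def single_regression(
    X: np.ndarray, Y: np.ndarray, bonferroni: int = 1
) -> RegressionResult:
    """OLS of Y on X with t-tests (n - 2 df) on intercept and slope."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("X and Y must be 1-D vectors of equal length")
    n = len(X)
    if n < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.ptp(X) == 0:
        raise ValueError("X has zero variance: slope undefined")

    xm, ym = X.mean(), Y.mean()
    sxx = np.sum((X - xm) ** 2)
    b1 = np.sum((X - xm) * (Y - ym)) / sxx
    b0 = ym - b1 * xm
    resid = Y - (b0 + b1 * X)
    df = n - 2
    s2 = np.sum(resid**2) / df if df > 0 else 0.0
    se_b1 = np.sqrt(s2 / sxx)
    se_b0 = np.sqrt(s2 * (1.0 / n + xm**2 / sxx))
    if s2 == 0:
        t0 = np.inf if b0 != 0 else 0.0
        t1 = np.inf if b1 != 0 else 0.0
        p0 = 0.0 if b0 != 0 else 1.0
        p1 = 0.0 if b1 != 0 else 1.0
    else:
        t0, t1 = b0 / se_b0, b1 / se_b1
        p0 = 2 * sps.t.sf(abs(t0), df)
        p1 = 2 * sps.t.sf(abs(t1), df)

    m = bonferroni
    return RegressionResult(
        B0=float(b0),
        B1=float(b1),
        t_B0=float(t0),
        t_B1=float(t1),
        p_B0=bonferroni_correct(float(p0), m),
        p_B1=bonferroni_correct(float(p1), m),
        n=n,
        corrected=m,
        p_B0_raw=float(p0),
        p_B1_raw=float(p1),
    )


def lag_ttests(lags_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    """Synchronization-lag tests: OO vs 0, then BO and OB vs OO.

    OO mean lags are tested against 0 ms with a one-sample t-test
    (uncorrected); BO and OB are tested against OO with paired t-tests,
    Bonferroni-corrected for the two comparisons.  Input is a dict of
    per-pair mean lags with aligned pair order.
    """
    if "OO" not in lags_by_condition:
        raise ValueError("OO condition is required as the reference")
    oo = np.asarray(lags_by_condition["OO"], dtype=float)
    if len(oo) < 2:
        raise ValueError("need at least 2 pairs")

    rows = []
    t, p = sps.ttest_1samp(oo, 0.0)
    rows.append(
        {
            "condition": "OO",
            "comparison": "vs 0 ms",
            "mean_lag_ms": oo.mean(),
            "sd_lag_ms": oo.std(ddof=1),
            "t": float(t),
            "p_raw": float(p),
            "p_corrected": float(p),
            "n_pairs": len(oo),
        }
    )
    paired = [c for c in ("BO", "OB") if c in lags_by_condition]
    for cond in paired:
        vals = np.asarray(lags_by_condition[cond], dtype=float)
        if vals.shape != oo.shape:
            raise ValueError(
                f"{cond} lags are not paired with OO ({len(vals)} vs {len(oo)})"
            )
        t, p = sps.ttest_rel(vals, oo)
        rows.append(
            {
                "condition": cond,
                "comparison": "vs OO (paired)",
                "mean_lag_ms": vals.mean(),
                "sd_lag_ms": vals.std(ddof=1),
                "t": float(t),
                "p_raw": float(p),
                "p_corrected": bonferroni_correct(float(p), len(paired)),
                "n_pairs": len(vals),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (all factors 2-level)
# ---------------------------------------------------------------------------

_CELL_ORDER = [
    # (sender, receiver, distance), fixed column order for the 8-cell table
    ("O", "O", "Near"), ("O", "O", "Far"),
    ("O", "B", "Near"), ("O", "B", "Far"),
    ("B", "O", "Near"), ("B", "O", "Far"),
    ("B", "B", "Near"), ("B", "B", "Far"),
]

def _rm_effects(
    cells: np.ndarray,
    factors: list[str],
    cell_levels: list[tuple] = _CELL_ORDER,
) -> AnovaResult:
    """Within-subject ANOVA on a (n_subjects, n_cells) array of means.

    ``cell_levels[j]`` gives the factor levels of cell column j, one entry
    per factor.  With every factor at 2 levels, each effect reduces to a
    one-sample t-test on the per-subject contrast score (the difference
    between the two level means, using product coding for interactions):
    F = t^2 with df (1, n-1) and eta_p^2 = t^2 / (t^2 + n - 1).
    """
    n, n_cells = cells.shape
    if n < 2:
        raise ValueError("ANOVA needs at least 2 subjects")
    if len(cell_levels) != n_cells:
        raise ValueError("cell_levels must describe every cell column")
    result = AnovaResult()
    names: list[tuple[str, np.ndarray]] = []
    # +/-1 coding per factor, derived from each column's level labels
    codes = []
    for j, _ in enumerate(factors):
        levels = [lv[j] for lv in cell_levels]
        ref = levels[0]
        codes.append(np.array([+1 if lv == ref else -1 for lv in levels]))
    from itertools import combinations

    # order: main effects, two-way interactions, highest interaction
    for k in range(1, len(factors) + 1):
        for combo in combinations(range(len(factors)), k):
            code = np.prod([codes[i] for i in combo], axis=0)
            name = "x".join(factors[i] for i in combo)
            names.append((name, code))
    half = cells.shape[1] // 2
    for name, code in names:
        # per-subject contrast: mean of + cells minus mean of - cells
        score = cells @ (code / half)
        if np.allclose(score.std(ddof=1), 0.0):
            # degenerate: no between-subject variability in the contrast
            if np.allclose(score.mean(), 0.0):
                F, p, eta = 0.0, 1.0, 0.0
            else:
                F, p, eta = float("inf"), 0.0, 1.0
        else:
            t, p = sps.ttest_1samp(score, 0.0)
            F = float(t) ** 2
            eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
        result.effects.append(
            AnovaEffect(
                effect=name,
                df1=1,
                df2=n - 1,
                F=F,
                p=float(p),
                eta_p2=float(eta),
            )
        )
    return result


def rm_anova_ncr(table: pd.DataFrame) -> AnovaResult:
    """Three-way repeated-measures ANOVA on received influence (SigmaNCR).

    ``table`` is long-format with columns ``participant``, ``sender``,
    ``receiver``, ``distance``, ``sncr`` (O/B for the visual states).
    Each participant must cover all 8 cells; multiple trials per cell are
    averaged first.  Returns F, p and partial eta squared for the three
    main effects, the three two-way interactions and the three-way
    interaction, with df (1, n_participants - 1).
    """
    required = {"participant", "sender", "receiver", "distance", "sncr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    cell_means = (
        table.groupby(["participant", "sender", "receiver", "distance"])[
            "sncr"
        ]
        .mean()
        .unstack(["sender", "receiver", "distance"])
    )
    try:
        cells = cell_means[_CELL_ORDER].to_numpy()
    except KeyError as exc:
        raise ValueError(f"incomplete design cells: {exc}") from exc
    if np.any(np.isnan(cells)):
        raise ValueError("incomplete cells: some participant misses a cell")
    return _rm_effects(cells, ["SENDER", "RECEIVER", "DISTANCE"], _CELL_ORDER)


def rm_anova_by_receiver(table: pd.DataFrame) -> dict[str, AnovaResult]:
    """Follow-up two-way (SENDER x DISTANCE) ANOVAs per RECEIVER level."""
    out = {}
    for level in ("O", "B"):
        sub = table[table["receiver"] == level]
        cell_means = (
            sub.groupby(["participant", "sender", "distance"])["sncr"]
            .mean()
            .unstack(["sender", "distance"])
        )
        order = [
            ("O", "Near"), ("O", "Far"), ("B", "Near"), ("B", "Far"),
        ]
        cells = cell_means[order].to_numpy()
        if np.any(np.isnan(cells)):
            raise ValueError("incomplete cells in follow-up ANOVA")
        out[level] = _rm_effects(cells, ["SENDER", "DISTANCE"], order)
    return out


def variance_summary(trials) -> pd.DataFrame:
    """Mean detrended signal variance per axis, distance and visual state.

    Each participant-trial contributes one variance (mm^2), stratified
    by the participant's own visual state and the partner's state, e.g.
    "O (with partner: B)".
    """
    rows = []
    for trial in trials:
        for series, own, partner in (
            (trial.x, trial.condition[0], trial.condition[1]),
            (trial.y, trial.condition[1], trial.condition[0]),
        ):
            rows.append(
                {
                    "axis": trial.axis,
                    "distance": trial.distance,
                    "state": f"{own} (with partner: {partner})",
                    "variance_mm2": float(
                        np.var(detrend_linear(series), ddof=1)
                    ),
                }
            )
    if not rows:
        raise ValueError("no trials supplied")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["axis", "distance", "state"], as_index=False)[
            "variance_mm2"
        ]
        .mean()
        .sort_values(["axis", "distance", "state"])
        .reset_index(drop=True)
    )


@dataclass
class SncrRow:
    """One directed-influence observation in the ANOVA's long format."""

    participant: int
    sender: str
    receiver: str
    distance: str
    sncr: float


def sncr_long_table(records) -> pd.DataFrame:
    """Build the ANOVA long table from per-trial directed SigmaNCR records.

    ``records`` yields dicts with keys pair_id, condition, distance,
    sncr_y_to_x, sncr_x_to_y (percent).  Each trial contributes two rows:
    participant x receives sncr_y_to_x (sender = y's state, receiver =
    x's state) and participant y receives sncr_x_to_y.
    """
    rows = []
    for rec in records:
        cond = rec["condition"]
        x_state, y_state = cond[0], cond[1]
        pid_x = rec["pair_id"] * 2
        pid_y = rec["pair_id"] * 2 + 1
        rows.append(
            SncrRow(pid_x, y_state, x_state, rec["distance"],
                    rec["sncr_y_to_x"]).__dict__
        )
        rows.append(
            SncrRow(pid_y, x_state, y_state, rec["distance"],
                    rec["sncr_x_to_y"]).__dict__
        )
    return pd.DataFrame(rows)
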