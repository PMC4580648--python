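"""Shared data containers for the dyadic sway-synchronization pipeline.

Conventions used throughout the package
---------------------------------------
* A *trial* is one 60 s recording of a pair standing face to face: two
  1-D head-position series (mm), one per participant, on a single body
  axis (anterior-posterior or left-right), sampled at 200 Hz.
* The two participants are always called ``x`` and ``y``.  Condition
  labels are two letters, the first for x, the second for y
  (``"BO"`` = x blindfolded, y eyes open).
* Lag sign: a cross-correlation peak at positive lag means participant
  y's fluctuations *precede* participant x's (x follows y).  This is the
  convention implied by pairing x(t+tau) with y(t) in the lagged
  correlation, and it makes the blindfolded partner's lead come out
  negative in BO and positive in OB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AXES = ("AP", "LR")
DISTANCES = ("Near", "Far")
CONDITIONS = ("OO", "BO", "OB", "BB")


@dataclass
class SwayTrial:
    """One trial's paired head-position series with its design metadata."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    axis: str
    distance: str
    condition: str
    pair_id: int
    trial_id: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("trial series must be 1-D")
        if len(self.x) != len(self.y):
            raise ValueError(
                f"x and y lengths differ: {len(self.x)} vs {len(self.y)}"
            )
        if len(self.x) < 2:
            raise ValueError("trial series must have length >= 2")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.distance not in DISTANCES:
            raise ValueError(
                f"distance must be one of {DISTANCES}, got {self.distance!r}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CrossCorrResult:
    """Lag-indexed normalized cross-correlation curve with detected peak.

    ``lags`` are integer sample offsets tau; ``values[i]`` is R_xy(lags[i]).
    Positive tau = y precedes x (see module docstring).
    """

    lags: np.ndarray
    values: np.ndarray
    fs: float
    n_points: int
    peak_lag_ms: float | None = None
    peak_value: float | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have identical shape")

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


@dataclass
class ARModel:
    """Fitted bivariate AR model.

    ``coeffs[i]`` is the 2x2 matrix [[a_{i+1}, b_{i+1}], [c_{i+1}, d_{i+1}]]
    multiplying the state one-plus-``i`` steps back: row 0 is the equation for
    x, row 1 for y; column 0 weights past x, column 1 past y.
    """

    order: int
    coeffs: np.ndarray  # (order, 2, 2)
    noise_var: tuple[float, float]
    residuals: np.ndarray  # (2, n_obs - order)
    fs: float
    aic: float
    n_obs: int

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.order, 2, 2):
            raise ValueError(
                f"coeffs must have shape ({self.order}, 2, 2), "
                f"got {self.coeffs.shape}"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not all(v > 0 for v in self.noise_var):
            raise ValueError("noise variances must be positive")

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)

    @property
    def is_stationary(self) -> bool:
        return self.spectral_radius < 1.0


def companion_matrix(coeffs: Sequence[np.ndarray]) -> np.ndarray:
    """Stacked one-step (companion) form of a k-dim AR(p) coefficient set."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, k2 = coeffs.shape
    if k != k2:
        raise ValueError("coefficient matrices must be square")
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return comp


def companion_spectral_radius(coeffs: Sequence[np.ndarray]) -> float:
    """Largest eigenvalue magnitude of the companion matrix (< 1 = stable)."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


@dataclass
class NCRSpectrum:
    """Frequency-resolved directed noise contribution ratios and integrals.

    ``power_x_own``/``power_x_partner`` decompose x's AR power spectrum into
    the part driven by its own innovation (|alpha|^2 sigma_ux^2) and the part
    driven by the partner's (|beta|^2 sigma_uy^2); likewise for y.
    ``sum_ncr_*`` are bandwidth-normalized trapezoidal integrals in percent.
    """

    freqs: np.ndarray
    ncr_y_to_x: np.ndarray
    ncr_x_to_y: np.ndarray
    power_x_own: np.ndarray
    power_x_partner: np.ndarray
    power_y_own: np.ndarray
    power_y_partner: np.ndarray
    fs: float
    sum_ncr_y_to_x: float | None = None
    sum_ncr_x_to_y: float | None = None


@dataclass
class SimulatedPair:
    """A white-noise-driven realization of a fitted bivariate AR model."""

    x_sim: np.ndarray
    y_sim: np.ndarray
    source_model: ARModel
    seed: int
    noise: np.ndarray  # (2, n) driving noise kept after burn-in

    @property
    def n_samples(self) -> int:
        return len(self.x_sim)


@dataclass
class RegressionResult:
    """Simple linear regression Y = B0 + B1 X with t-tests on both terms."""

    B0: float
    B1: float
    t_B0: float
    t_B1: float
    p_B0: float
    p_B1: float
    n: int
    corrected: int = 1  # Bonferroni multiplier already applied to p-values
    p_B0_raw: float | None = None
    p_B1_raw: float | None = None


@dataclass
class AnovaEffect:
    """One row of a repeated-measures ANOVA table."""

    effect: str
    df1: int
    df2: int
    F: float
    p: float
    eta_p2: float


@dataclass
class AnovaResult:
    effects: list[AnovaEffect] = field(default_factory=list)

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "df1": e.df1,
                    "df2": e.df2,
                    "F": e.F,
                    "p": e.p,
                    "eta_p2": e.eta_p2,
                }
                for e in self.effects
            ]
        )
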