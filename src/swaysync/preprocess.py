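"""Signal conditioning applied before every analysis stage.

Two preprocessing paths exist, mirroring the split between the two
analyses:

* cross-correlation runs on the raw-rate (200 Hz) series after linear
  detrending and a full-length Hanning taper;
* AR model estimation runs at 5 Hz, obtained by 40-fold FIR decimation
  (30th-order low-pass, applied zero-phase) followed by linear detrending.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import SwayTrial

#: decimation defaults: 200 Hz -> 5 Hz with a 30th-order FIR anti-alias filter
DECIMATION_FACTOR = 40
FIR_ORDER = 30


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Subtract the least-squares straight-line fit from ``series``.

    The returned series has (numerically) zero mean and zero linear trend.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("detrend_linear requires a 1-D series of length >= 2")
    return signal.detrend(series, type="linear")


def apply_hanning(series: np.ndarray) -> np.ndarray:
    """Taper ``series`` with a Hanning window of the same length."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("apply_hanning requires a 1-D series of length >= 2")
    return series * np.hanning(len(series))


def decimate_fir(
    series: np.ndarray,
    factor: int = DECIMATION_FACTOR,
    fir_order: int = FIR_ORDER,
) -> np.ndarray:
    """Anti-alias FIR low-pass then subsample every ``factor``-th point.

    The filter is a ``fir_order``-th order FIR low-pass with cutoff at the
    post-decimation Nyquist, applied forward-backward (zero-phase) so that
    lag structure is not shifted.  Subsampling starts at index 0; the output
    length is ``ceil(len(series) / factor)``.
    """
    series = np.asarray(series, dtype=float)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return series.copy()
    if len(series) <= fir_order:
        raise ValueError(
            f"series length {len(series)} must exceed the FIR order {fir_order}"
        )
    taps = signal.firwin(fir_order + 1, 1.0 / factor)
    padlen = min(3 * (fir_order + 1), len(series) - 1)
    filtered = signal.filtfilt(taps, [1.0], series, padlen=padlen)
    return filtered[::factor]


def prepare_for_crosscorr(
    trial: SwayTrial, detrend: bool = True, window: str | None = "hanning"
) -> tuple[np.ndarray, np.ndarray]:
    """Detrended, Hanning-tapered 200 Hz series ready for lagged correlation.

    The correlation's means and SDs are later computed on exactly these
    tapered series, keeping the normalized correlation self-consistent.
    """
    x, y = trial.x, trial.y
    if detrend:
        x, y = detrend_linear(x), detrend_linear(y)
    if window == "hanning":
        x, y = apply_hanning(x), apply_hanning(y)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    return x, y


def prepare_for_var(
    trial: SwayTrial,
    factor: int = DECIMATION_FACTOR,
    fir_order: int = FIR_ORDER,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Decimate both channels to the model rate and detrend.

    Returns ``(x_5hz, y_5hz, fs_model)``.  Decimation precedes detrending,
    matching the order of operations used for the AR analysis.
    """
    x = detrend_linear(decimate_fir(trial.x, factor, fir_order))
    y = detrend_linear(decimate_fir(trial.y, factor, fir_order))
    return x, y, trial.fs / factor
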