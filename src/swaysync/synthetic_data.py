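"""Synthetic dyadic sway with known ground-truth coupling.

The generator emulates the recorded data's structure so that every
pipeline stage can be exercised against a known answer: a stable
bivariate AR process at the 5 Hz model rate supplies the coupled
dynamics, band-limited interpolation brings it to 200 Hz, and a random
linear drift plus white measurement noise stand in for the slow postural
trend and motion-capture jitter that the preprocessing stages must
remove.

Visual-interaction conditions map onto coupling topology: with both
partners sighted (OO) the cross-coupling is bidirectional and symmetric;
with one partner blindfolded (BO/OB) only the sighted partner's equation
receives cross terms (the blindfolded partner drives, the sighted one
follows); with both blindfolded (BB) the two channels are uncoupled.
Distance is emulated as a multiplicative coupling scale (Near = 1.0,
Far = 0.4 by default): the generative mechanism behind weaker influence
at larger distance is unknown, so the simplest monotone knob is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .datatypes import (
    AXES,
    CONDITIONS,
    DISTANCES,
    SwayTrial,
    companion_spectral_radius,
)
from .simulate import BURN_IN, var_recursion

#: relative weight of successive lags when spreading a coupling strength
#: over a multi-lag model; geometric with alternating sign so the sway
#: spectrum keeps a realistic low-frequency peak while every lag carries
#: an identifiable coefficient
LAG_DECAY = -0.45


def _lag_weights(order: int) -> np.ndarray:
    return LAG_DECAY ** np.arange(order)


def make_coupling_coefficients(
    self_strength: float,
    b_strength: float,
    c_strength: float,
    order: int = 3,
) -> np.ndarray:
    """Stable AR coefficient matrices with chosen directed couplings.

    ``b_strength`` is the lag-1 influence of y on x (entry b_1),
    ``c_strength`` the lag-1 influence of x on y (entry c_1); higher lags
    are geometrically decayed copies.  Raises if the companion spectral
    radius is >= 1.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    w = _lag_weights(order)
    base = np.array(
        [[self_strength, b_strength], [c_strength, self_strength]]
    )
    coeffs = w[:, None, None] * base[None, :, :]
    radius = companion_spectral_radius(coeffs)
    if radius >= 1.0:
        raise ValueError(
            f"requested strengths give an unstable model "
            f"(companion spectral radius {radius:.4f} >= 1)"
        )
    return coeffs


def make_condition_coefficients(
    condition: str,
    self_strength: float = 0.5,
    coupling_strength: float = 0.3,
    order: int = 3,
) -> np.ndarray:
    """Ground-truth AR matrices for a visual-interaction condition.

    OO: bidirectional symmetric coupling; BO: x blindfolded, so only y's
    equation receives cross terms (b = 0, c != 0); OB: the mirror image;
    BB: no cross terms at all.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    b = coupling_strength if condition in ("OO", "OB") else 0.0
    c = coupling_strength if condition in ("OO", "BO") else 0.0
    return make_coupling_coefficients(self_strength, b, c, order)


@dataclass
class SynthSpec:
    """Study-level configuration of the synthetic-data generator.

    Defaults reproduce the behavioral design: 22 pairs, 60 s trials at
    200 Hz (12000 samples), 4 trials per pair in each of the 2 x 4
    distance x visual-interaction cells, dynamics generated at 5 Hz and
    upsampled 40-fold.
    """

    model_order: int = 3
    self_strength: float = 0.5
    coupling_strength: float = 0.3
    far_coupling_scale: float = 0.4
    coeff_matrices: np.ndarray | None = None
    noise_sd: tuple[float, float] = (1.0, 1.0)
    fs_model: float = 5.0
    upsample_factor: int = 40
    trial_duration: float = 60.0
    trend_slope_range: tuple[float, float] = (-0.02, 0.02)  # mm/s
    measurement_noise_sd: float = 0.05  # mm
    n_pairs: int = 22
    n_trials_per_condition: int = 4
    axes: tuple[str, ...] = ("AP", "LR")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("innovation SDs must be positive")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.trial_duration <= 0:
            raise ValueError("trial duration must be positive")
        n_model = self.trial_duration * self.fs_model
        if abs(n_model - round(n_model)) > 1e-9:
            raise ValueError(
                "trial_duration x fs_model must be an integer sample count"
            )
        for ax in self.axes:
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}")
        if self.coeff_matrices is not None:
            self.coeff_matrices = np.asarray(self.coeff_matrices, dtype=float)
            radius = companion_spectral_radius(self.coeff_matrices)
            if radius >= 1.0:
                raise ValueError(
                    f"coeff_matrices are unstable (spectral radius "
                    f"{radius:.4f} >= 1)"
                )

    @property
    def n_model_samples(self) -> int:
        return int(round(self.trial_duration * self.fs_model))

    @property
    def n_output_samples(self) -> int:
        return self.n_model_samples * self.upsample_factor

    @property
    def fs_output(self) -> float:
        return self.fs_model * self.upsample_factor

    def condition_coefficients(
        self, condition: str, distance: str = "Near"
    ) -> np.ndarray:
        """Ground-truth matrices for one design cell."""
        if self.coeff_matrices is not None:
            return self.coeff_matrices
        scale = 1.0 if distance == "Near" else self.far_coupling_scale
        return make_condition_coefficients(
            condition,
            self_strength=self.self_strength,
            coupling_strength=self.coupling_strength * scale,
            order=self.model_order,
        )


def generate_trial(
    spec: SynthSpec,
    coeffs: np.ndarray,
    seed: int,
    axis: str = "AP",
    distance: str = "Near",
    condition: str = "OO",
    pair_id: int = 0,
    trial_id: int = 0,
) -> SwayTrial:
    """One synthetic 200 Hz trial from the given AR ground truth.

    The AR recursion runs at the model rate with a 500-sample burn-in,
    is upsampled by band-limited polyphase interpolation, and then
    receives a per-channel random linear trend and white measurement
    noise.  Identical (spec, coeffs, seed) gives bit-identical output.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    radius = companion_spectral_radius(coeffs)
    if radius >= 1.0:
        raise ValueError(
            f"unstable coefficients (spectral radius {radius:.4f} >= 1)"
        )
    rng = np.random.default_rng(seed)
    n_model = spec.n_model_samples
    innovations = rng.standard_normal((2, n_model + BURN_IN))
    innovations *= np.asarray(spec.noise_sd)[:, None]
    z = var_recursion(coeffs, innovations)[:, BURN_IN:]

    if spec.upsample_factor > 1:
        z = signal.resample_poly(z, spec.upsample_factor, 1, axis=1)
    n_out = spec.n_output_samples
    t = np.arange(n_out) / spec.fs_output
    slopes = rng.uniform(*spec.trend_slope_range, size=2)
    z = z + slopes[:, None] * t[None, :]
    if spec.measurement_noise_sd > 0:
        z = z + rng.normal(0.0, spec.measurement_noise_sd, size=z.shape)

    return SwayTrial(
        x=z[0],
        y=z[1],
        fs=spec.fs_output,
        axis=axis,
        distance=distance,
        condition=condition,
        pair_id=pair_id,
        trial_id=trial_id,
    )


def trial_seed(
    spec_seed: int,
    pair_id: int,
    distance: str,
    condition: str,
    trial_id: int,
    axis: str,
) -> int:
    """Deterministic per-trial seed derived from the study seed."""
    ss = np.random.SeedSequence(
        [
            spec_seed,
            pair_id,
            DISTANCES.index(distance),
            CONDITIONS.index(condition),
            trial_id,
            AXES.index(axis),
        ]
    )
    return int(ss.generate_state(1, np.uint32)[0] % 2**31)


def generate_dataset(spec: SynthSpec) -> list[SwayTrial]:
    """Full factorial pair x distance x condition x trial (x axis) dataset.

    Per-trial seeds are derived deterministically from ``spec.seed``, so
    regenerating any subset reproduces the identical arrays.
    """
    trials = []
    for pair_id in range(spec.n_pairs):
        for distance in DISTANCES:
            for condition in CONDITIONS:
                coeffs = spec.condition_coefficients(condition, distance)
                for trial_id in range(spec.n_trials_per_condition):
                    for axis in spec.axes:
                        seed = trial_seed(
                            spec.seed, pair_id, distance, condition,
                            trial_id, axis,
                        )
                        trials.append(
                            generate_trial(
                                spec,
                                coeffs,
                                seed,
                                axis=axis,
                                distance=distance,
                                condition=condition,
                                pair_id=pair_id,
                                trial_id=trial_id,
                            )
                        )
    return trials


def ground_truth_manifest(spec: SynthSpec) -> dict:
    """JSON-serializable record of the generator's ground truth."""
    cells = {}
    for distance in DISTANCES:
        for condition in CONDITIONS:
            coeffs = spec.condition_coefficients(condition, distance)
            cells[f"{distance}/{condition}"] = {
                "coeff_matrices": coeffs.tolist(),
                "spectral_radius": companion_spectral_radius(coeffs),
            }
    return {
        "seed": spec.seed,
        "n_pairs": spec.n_pairs,
        "n_trials_per_condition": spec.n_trials_per_condition,
        "axes": list(spec.axes),
        "fs_model": spec.fs_model,
        "fs_output": spec.fs_output,
        "trial_duration_s": spec.trial_duration,
        "noise_sd": list(spec.noise_sd),
        "measurement_noise_sd": spec.measurement_noise_sd,
        "trend_slope_range": list(spec.trend_slope_range),
        "far_coupling_scale": spec.far_coupling_scale,
        "ground_truth": cells,
    }
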