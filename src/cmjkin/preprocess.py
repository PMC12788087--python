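"""Calibration and signal conditioning for marker trajectories.

2D video coordinates are scaled from pixels to metres with a
stature-based calibration: a vertical reference of ``reference_length_px``
pixels is declared to span the participant's body height. An imperfectly
drawn reference (relative error δ of the true pixel length) propagates
multiplicatively — every displacement is inflated by 1/(1−δ) — while
leaving fractional-threshold event timing untouched.

Conditioning follows standard motion-capture practice: brief occlusion
gaps are reconstructed by linear or polynomial interpolation, a centred
moving-average filter suppresses high-frequency tracking noise, and
velocity is obtained by numerical differentiation (central differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNIT_METRES, UNIT_PIXELS, Trajectory


class UnrecoverableTrajectoryError(ValueError):
    """Gap structure that conditioning refuses to repair (trial exclusion)."""


@dataclass
class CalibrationSpec:
    """Stature-based pixel→metre calibration.

    ``rel_error`` is the relative error δ of the drawn reference length:
    the drawn line spans ``reference_length_px`` pixels but the true
    body-height span is ``reference_length_px · (1 − δ)`` pixels, so the
    effective scale is ``body_height_m / (reference_length_px · (1 − δ))``
    metres per pixel and all displacements are multiplied by 1/(1−δ)
    relative to a perfect calibration.
    """

    body_height_m: float
    reference_length_px: float
    rel_error: float = 0.0

    def __post_init__(self) -> None:
        if self.body_height_m <= 0:
            raise ValueError("body height must be positive")
        if self.reference_length_px <= 0:
            raise ValueError("reference length must be positive")
        if not abs(self.rel_error) < 1:
            raise ValueError("|rel_error| must be < 1")

    @property
    def scale(self) -> float:
        """Nominal scale (m/px) of a perfectly drawn reference."""
        return self.body_height_m / self.reference_length_px

    @property
    def effective_scale(self) -> float:
        """Scale actually applied, inflated by the reference error."""
        return self.scale / (1.0 - self.rel_error)


@dataclass
class ConditioningConfig:
    """Gap-filling and smoothing parameters.

    gap_method : {"linear", "polynomial"}
    poly_degree : int
        Degree for polynomial gap interpolation (>= 2).
    support : int
        Non-missing support samples taken on each side of a gap for the
        polynomial fit.
    max_gap_s : float
        Longest repairable gap in seconds; longer gaps mark the trial
        unrecoverable (mirroring the exclusion of chronically occluded
        markers).
    ma_window_s : float
        Moving-average window length in seconds; converted to the
        nearest odd sample count at the trajectory's rate. Default
        ~17 ms (5 samples at 300 Hz): long enough to suppress
        high-frequency tracking noise, short enough not to alter the
        motion pattern — wider windows measurably bias the detected
        trough on curvature-asymmetric jumps.
    """

    gap_method: str = "linear"
    poly_degree: int = 3
    support: int = 2
    max_gap_s: float = 0.05
    ma_window_s: float = 0.0167

    def __post_init__(self) -> None:
        if self.gap_method not in ("linear", "polynomial"):
            raise ValueError(f"unknown gap_method {self.gap_method!r}")
        if self.gap_method == "polynomial" and self.poly_degree < 2:
            raise ValueError("poly_degree must be >= 2")
        if self.max_gap_s <= 0 or self.ma_window_s < 0:
            raise ValueError("durations must be non-negative")

    def window_samples(self, rate: float) -> int:
        """Odd window length in samples for a given sampling rate."""
        w = int(round(self.ma_window_s * rate))
        if w % 2 == 0:
            w += 1
        return max(w, 1)


def apply_calibration(traj: Trajectory, spec: CalibrationSpec) -> Trajectory:
    """Scale a pixel-valued trajectory to metres."""
    if traj.unit != UNIT_PIXELS:
        raise ValueError("trajectory is already calibrated (unit is metres)")
    s = spec.effective_scale
    if not np.isfinite(s):
        raise ValueError("non-finite calibration scale")
    return traj.with_z(traj.z * s, unit=UNIT_METRES)


def _gap_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous missing runs as (start, stop) half-open index pairs."""
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(traj: Trajectory, cfg: ConditioningConfig | None = None
              ) -> Trajectory:
    """Reconstruct interior occlusion gaps by interpolation.

    Non-missing samples are untouched; the missing mask is cleared.
    Boundary gaps and gaps longer than ``max_gap_s`` raise
    :class:`UnrecoverableTrajectoryError`.
    """
    cfg = cfg or ConditioningConfig()
    if traj.n_missing == 0:
        return traj.with_z(traj.z)
    missing = traj.missing
    if missing[0] or missing[-1]:
        raise UnrecoverableTrajectoryError("gap at trajectory boundary")
    max_gap = max(int(round(cfg.max_gap_s * traj.rate)), 1)
    runs = _gap_runs(missing)
    if any(stop - start > max_gap for start, stop in runs):
        raise UnrecoverableTrajectoryError(
            f"gap longer than {max_gap} samples at rate {traj.rate} Hz")

    z = traj.z.copy()
    good = ~missing
    if cfg.gap_method == "linear":
        z[missing] = np.interp(traj.t[missing], traj.t[good], traj.z[good])
    else:
        good_idx = np.nonzero(good)[0]
        for start, stop in runs:
            left = good_idx[good_idx < start][-cfg.support:]
            right = good_idx[good_idx >= stop][:cfg.support]
            support = np.concatenate([left, right])
            deg = min(cfg.poly_degree, len(support) - 1)
            # Shift times for numerical conditioning of the Vandermonde fit.
            t0 = traj.t[support].mean()
            coeff = np.polynomial.polynomial.polyfit(
                traj.t[support] - t0, traj.z[support], deg)
            z[start:stop] = np.polynomial.polynomial.polyval(
                traj.t[start:stop] - t0, coeff)
    return traj.with_z(z, missing=np.zeros_like(missing))


def moving_average(z: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking symmetric edge windows.

    Interior samples average ``window`` points; near the edges the
    half-width shrinks to keep the window symmetric, so the output has
    the input's length and a constant signal is a fixed point.
    """
    if window % 2 == 0:
        raise ValueError("moving-average window must be odd")
    z = np.asarray(z, float)
    n = len(z)
    if window > n:
        raise ValueError("window longer than signal")
    if window == 1:
        return z.copy()
    h = window // 2
    c = np.concatenate([[0.0], np.cumsum(z)])
    out = np.empty(n)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        out[i] = (c[i + hi + 1] - c[i - hi]) / (2 * hi + 1)
    return out


def smooth_ma(traj: Trajectory, window: int | None = None,
              cfg: ConditioningConfig | None = None) -> Trajectory:
    """Moving-average filter a gap-free trajectory (length preserved)."""
    if traj.n_missing:
        raise ValueError("fill gaps before smoothing")
    if window is None:
        window = (cfg or ConditioningConfig()).window_samples(traj.rate)
    return traj.with_z(moving_average(traj.z, window))


def differentiate(traj: Trajectory) -> np.ndarray:
    """Velocity (m/s) by central differences, one-sided at the ends."""
    if traj.n_missing:
        raise ValueError("fill gaps before differentiating")
    if len(traj) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(traj.z, traj.t)


def condition(traj: Trajectory, cfg: ConditioningConfig | None = None,
              calibration: CalibrationSpec | None = None) -> Trajectory:
    """Full conditioning chain: calibrate (if pixels) → fill gaps → smooth."""
    cfg = cfg or ConditioningConfig()
    if traj.unit == UNIT_PIXELS:
        if calibration is None:
            raise ValueError("pixel-valued trajectory requires a calibration")
        traj = apply_calibration(traj, calibration)
    traj = fill_gaps(traj, cfg)
    return smooth_ma(traj, cfg=cfg)
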