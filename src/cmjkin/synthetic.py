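"""Ground-truthed synthetic countermovement-jump recordings.

The simulator produces paired recordings with the structure of a
concurrent-validity study: for every participant-trial one "mocap"
reference recording (300 Hz) and two "video" renditions (240 Hz) that
share the same underlying jump and differ only in rater tracking noise.

The jump itself is a C1-continuous piecewise displacement model (gain
``c`` scales a marker's amplitude relative to the hip):

* quiet standing  z = 0 for ``t_quiet`` seconds;
* eccentric descent, half-cosine ``z(τ) = −c·depth/2·(1 − cos(πτ/T_ecc))``
  reaching the trough ``−c·depth`` with zero velocity at ``T_ecc``;
* propulsion, the cubic through ``z(0) = −c·depth, ż(0) = 0`` and
  ``z(T_pp) = c·z_to, ż(T_pp) = c·v_to``;
* ballistic flight ``z(τ) = c·(z_to + v_to·τ − g·τ²/2)`` with apex
  ``c·(z_to + v_to²/(2g))``, ending back at take-off height;
* a landing cubic decelerating into a shallow dip, a half-cosine rise
  back to standing, and a quiet tail (present only so detectors can be
  stressed with post-flight motion; no claim of biomechanical realism).

Because the model is analytic, the 5 %-rule event times are available in
closed form (onset) or by root solving (take-off), giving exact ground
truth for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from .core import MARKERS, UNIT_METRES, Trajectory, TrialRecording
from .events import EventConfig

DEFAULT_MARKER_GAINS = {"shoulder": 1.05, "hip": 1.0, "knee": 0.35}


def _hermite(tau: np.ndarray, T: float, p0: float, m0: float,
             p1: float, m1: float) -> np.ndarray:
    """Cubic Hermite segment on [0, T] with endpoint values/slopes."""
    s = tau / T
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * (T * m0) + h01 * p1 + h11 * (T * m1)


@dataclass
class GroundTruthJump:
    """Parameters of one true (noise-free, continuous-time) jump.

    Amplitudes are hip-referenced; ``marker_gains`` scale them to each
    marker. Durations are in seconds, displacements in metres.
    """

    t_quiet: float = 1.0
    T_ecc: float = 0.50
    T_pp: float = 0.31
    depth: float = 0.28
    v_to: float = 2.65
    z_to: float = 0.10
    g: float = 9.81
    marker_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_GAINS))
    # Landing/settle shape — unconstrained plumbing for detector robustness.
    T_land: float = 0.20
    land_depth_frac: float = 0.5
    T_settle: float = 0.40
    t_tail: float = 0.50

    def __post_init__(self) -> None:
        for name in ("t_quiet", "T_ecc", "T_pp", "T_land", "T_settle",
                     "t_tail", "depth", "v_to", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.z_to < 0:
            raise ValueError("take-off displacement must be non-negative")
        if any(g <= 0 for g in self.marker_gains.values()):
            raise ValueError("marker gains must be strictly positive")
        # Landing dip must stay above the countermovement trough so the
        # trough remains the global minimum.
        if not 0 < self.land_depth_frac < 1:
            raise ValueError("land_depth_frac must lie in (0, 1)")
        # The propulsion cubic (zero start velocity, v_to end velocity)
        # is monotone — so the countermovement trough stays the global
        # minimum — iff v_to·T_pp < 3·(z_to + depth).
        if self.v_to * self.T_pp >= 3.0 * (self.z_to + self.depth):
            raise ValueError(
                "inconsistent propulsion parameters: v_to*T_pp must be "
                "< 3*(z_to+depth) or the ascent would dip below the trough")

    # -- phase bookkeeping -------------------------------------------------
    @property
    def T_flight(self) -> float:
        return 2.0 * self.v_to / self.g

    @property
    def apex_height(self) -> float:
        """Apex displacement above baseline for gain 1: z_to + v_to²/(2g)."""
        return self.z_to + self.v_to**2 / (2.0 * self.g)

    def phase_times(self) -> dict[str, float]:
        """Absolute boundary times of the piecewise model."""
        t1 = self.t_quiet
        t2 = t1 + self.T_ecc          # trough
        t3 = t2 + self.T_pp           # physical take-off
        t4 = t3 + self.T_flight       # touchdown
        t5 = t4 + self.T_land         # landing dip
        t6 = t5 + self.T_settle       # settled
        return {"descent_start": t1, "trough": t2, "takeoff": t3,
                "apex": t3 + self.v_to / self.g, "touchdown": t4,
                "landing_dip": t5, "settled": t6, "end": t6 + self.t_tail}

    @property
    def duration(self) -> float:
        return self.phase_times()["end"]

    # -- continuous signal -------------------------------------------------
    def displacement(self, t: np.ndarray, marker: str = "hip") -> np.ndarray:
        """Evaluate the continuous displacement model at times ``t``."""
        c = self.marker_gains[marker]
        t = np.asarray(t, float)
        p = self.phase_times()
        z = np.zeros_like(t)
        d_land = self.land_depth_frac * self.depth

        m = (t >= p["descent_start"]) & (t < p["trough"])
        tau = t[m] - p["descent_start"]
        z[m] = -self.depth / 2.0 * (1.0 - np.cos(np.pi * tau / self.T_ecc))

        m = (t >= p["trough"]) & (t < p["takeoff"])
        tau = t[m] - p["trough"]
        z[m] = _hermite(tau, self.T_pp, -self.depth, 0.0, self.z_to, self.v_to)

        m = (t >= p["takeoff"]) & (t < p["touchdown"])
        tau = t[m] - p["takeoff"]
        z[m] = self.z_to + self.v_to * tau - self.g * tau**2 / 2.0

        m = (t >= p["touchdown"]) & (t < p["landing_dip"])
        tau = t[m] - p["touchdown"]
        z[m] = _hermite(tau, self.T_land, self.z_to, -self.v_to, -d_land, 0.0)

        m = (t >= p["landing_dip"]) & (t < p["settled"])
        tau = t[m] - p["landing_dip"]
        z[m] = -d_land / 2.0 * (1.0 + np.cos(np.pi * tau / self.T_settle))

        return c * z

    # -- analytic ground-truth events --------------------------------------
    def true_event_times(self, cfg: Optional[EventConfig] = None
                         ) -> dict[str, float]:
        """Continuous-time 5 %-rule event times (gain-independent).

        Onset has a closed form on the cosine descent; take-off is root
        solved on the (monotone) propulsion/flight ascent.
        """
        cfg = cfg or EventConfig()
        p = self.phase_times()
        # cosine descent crosses −f·depth where 1 − cos(πτ/T) = 2f
        tau_on = self.T_ecc / math.pi * math.acos(1.0 - 2.0 * cfg.onset_fraction)
        z_min, z_apex = -self.depth, self.apex_height
        rng = z_apex - z_min
        if cfg.takeoff_rule == "literal":
            thr = z_min + cfg.takeoff_fraction * rng
        else:
            thr = z_apex - cfg.takeoff_fraction * rng
        t_to = brentq(lambda t: self.displacement(np.array([t]))[0] - thr,
                      p["trough"], p["apex"])
        return {
            "t_onset": p["descent_start"] + tau_on,
            "t_min": p["trough"],
            "t_takeoff": float(t_to),
            "t_apex": p["apex"],
        }

    def true_variables(self, marker: str = "hip",
                       cfg: Optional[EventConfig] = None) -> dict[str, float]:
        """Ground-truth values of the five jump variables for one marker."""
        cfg = cfg or EventConfig()
        ev = self.true_event_times(cfg)
        c = self.marker_gains[marker]
        if cfg.hmax_reference == "baseline":
            h_max = c * self.apex_height
        else:
            z_at_to = float(self.displacement(
                np.array([ev["t_takeoff"]]), marker))
            h_max = c * self.apex_height - z_at_to
        return {
            "dt_ecc": ev["t_min"] - ev["t_onset"],
            "dt_PP": ev["t_takeoff"] - ev["t_min"],
            "dt_take_off": ev["t_takeoff"] - ev["t_onset"],
            "h_Z_min": -c * self.depth,
            "h_Z_max": h_max,
        }


def generate_trajectory(gt: GroundTruthJump, rate: float,
                        marker: str = "hip") -> Trajectory:
    """Sample the continuous jump model on a uniform grid (noise-free).

    Deterministic: noise lives in :func:`corrupt`. Raises if the rate
    cannot represent the shortest phase with at least two samples.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    shortest = min(gt.T_ecc, gt.T_pp, gt.T_flight, gt.T_land, gt.T_settle)
    if rate < 2.0 / shortest:
        raise ValueError(
            f"rate {rate} Hz gives fewer than 2 samples in the shortest "
            f"phase ({shortest:.3f} s)")
    n = int(math.floor(gt.duration * rate)) + 1
    t = np.arange(n) / rate
    return Trajectory(marker=marker, t=t, z=gt.displacement(t, marker),
                      unit=UNIT_METRES, rate=rate)


@dataclass
class NoiseModel:
    """Measurement-chain corruption of a clean trajectory.

    sigma_track : additive white tracking noise SD (m).
    occlusion_rate : expected number of gaps per trial (Poisson).
    occlusion_len : inclusive (min, max) gap length in samples.
    rater_jitter_sd : SD (m) of a smooth low-frequency perturbation that
        models a rater's slowly drifting marker-centre placement.
    jitter_corr_s : correlation time (s) of that drift.
    calib_error : relative scale error δ of the calibration reference;
        the whole signal is multiplied by 1/(1−δ).
    """

    sigma_track: float = 0.0
    occlusion_rate: float = 0.0
    occlusion_len: tuple[int, int] = (2, 10)
    rater_jitter_sd: float = 0.0
    jitter_corr_s: float = 1.0
    calib_error: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_track < 0 or self.rater_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.occlusion_rate < 0:
            raise ValueError("occlusion rate must be non-negative")
        lo, hi = self.occlusion_len
        if lo < 1 or hi < lo:
            raise ValueError("occlusion_len must satisfy 1 <= min <= max")
        if not abs(self.calib_error) < 1:
            raise ValueError("|calib_error| must be < 1")


def corrupt(traj: Trajectory, noise: NoiseModel, seed: int) -> Trajectory:
    """Apply a noise model to a clean metre-valued trajectory.

    Order of operations: rater drift + white noise are added, the whole
    signal is rescaled by 1/(1−δ) (a mis-drawn calibration reference
    scales everything that was tracked), then occlusion gaps are masked
    (samples set to NaN; never the first or last sample). Identical seed
    ⇒ identical output.
    """
    if traj.unit != UNIT_METRES:
        raise ValueError("corrupt expects a metre-valued trajectory")
    if traj.n_missing:
        raise ValueError("corrupt expects a gap-free trajectory")
    n = len(traj)
    if noise.occlusion_rate > 0 and noise.occlusion_len[1] >= n // 4:
        raise ValueError("occlusion gaps could erase an entire phase")

    rng = np.random.default_rng(seed)
    z = traj.z.copy()
    if noise.rater_jitter_sd > 0:
        white = rng.standard_normal(n)
        drift = gaussian_filter1d(white, sigma=noise.jitter_corr_s * traj.rate,
                                  mode="nearest")
        sd = drift.std()
        if sd > 0:
            z = z + drift * (noise.rater_jitter_sd / sd)
    if noise.sigma_track > 0:
        z = z + rng.normal(0.0, noise.sigma_track, size=n)
    if noise.calib_error != 0.0:
        z = z / (1.0 - noise.calib_error)

    missing = np.zeros(n, dtype=bool)
    if noise.occlusion_rate > 0:
        lo, hi = noise.occlusion_len
        for _ in range(rng.poisson(noise.occlusion_rate)):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, n - length))  # interior only
            missing[start:start + length] = True
        z[missing] = np.nan
    return traj.with_z(z, missing=missing)


@dataclass
class StudyDesign:
    """Sampling design of a simulated concurrent-validity study."""

    n_participants: int = 10
    n_trials: int = 3
    rate_2d: float = 240.0
    rate_3d: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_trials < 1:
            raise ValueError("need at least 1 trial per participant")
        if self.rate_2d <= 0 or self.rate_3d <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class JumpPopulation:
    """Between-/within-subject variability of jump parameters.

    Defaults emulate a recreationally trained cohort: hip
    countermovement depth ≈ 0.27–0.30 m, apex displacement ≈ 0.45–0.48 m,
    eccentric ≈ 0.5 s and propulsion ≈ 0.31 s. Trial-to-trial variation
    is ``within_frac`` of the between-subject SD.
    """

    depth_mean: float = 0.28
    depth_sd: float = 0.05
    v_to_mean: float = 2.65
    v_to_sd: float = 0.15
    T_ecc_mean: float = 0.50
    T_ecc_sd: float = 0.06
    T_pp_mean: float = 0.31
    T_pp_sd: float = 0.035
    within_frac: float = 0.3
    z_to: float = 0.10
    t_quiet: float = 1.0
    marker_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_GAINS))

    def sample_participant(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            "depth": max(rng.normal(self.depth_mean, self.depth_sd), 0.15),
            "v_to": max(rng.normal(self.v_to_mean, self.v_to_sd), 1.5),
            "T_ecc": max(rng.normal(self.T_ecc_mean, self.T_ecc_sd), 0.20),
            "T_pp": max(rng.normal(self.T_pp_mean, self.T_pp_sd), 0.15),
        }

    def sample_trial(self, base: dict[str, float],
                     rng: np.random.Generator) -> GroundTruthJump:
        w = self.within_frac
        depth = max(rng.normal(base["depth"], w * self.depth_sd), 0.15)
        v_to = max(rng.normal(base["v_to"], w * self.v_to_sd), 1.5)
        t_pp = max(rng.normal(base["T_pp"], w * self.T_pp_sd), 0.15)
        # keep the propulsion cubic monotone (see GroundTruthJump)
        t_pp = min(t_pp, 0.85 * 3.0 * (self.z_to + depth) / v_to)
        return GroundTruthJump(
            t_quiet=self.t_quiet,
            T_ecc=max(rng.normal(base["T_ecc"], w * self.T_ecc_sd), 0.20),
            T_pp=t_pp,
            depth=depth,
            v_to=v_to,
            z_to=self.z_to,
            marker_gains=dict(self.marker_gains),
        )


#: Noise defaults: sub-millimetre mocap tracking vs few-millimetre video
#: tracking plus a slow rater-placement drift; occasional short occlusions.
DEFAULT_NOISE_3D = NoiseModel(sigma_track=0.0005, occlusion_rate=0.3,
                              occlusion_len=(2, 8))
DEFAULT_NOISE_2D = NoiseModel(sigma_track=0.002, occlusion_rate=0.5,
                              occlusion_len=(2, 10), rater_jitter_sd=0.002)


@dataclass
class SimulatedStudy:
    """Recordings plus the analytic ground truth they were drawn from."""

    design: StudyDesign
    recordings: list[TrialRecording]
    ground_truth: pd.DataFrame  # per participant/trial/marker true values
    jumps: dict[tuple[str, int], GroundTruthJump]


def simulate_study(design: StudyDesign,
                   population: Optional[JumpPopulation] = None,
                   noise_2d_rater_a: Optional[NoiseModel] = None,
                   noise_2d_rater_b: Optional[NoiseModel] = None,
                   noise_3d: Optional[NoiseModel] = None,
                   event_cfg: Optional[EventConfig] = None) -> SimulatedStudy:
    """Simulate a full paired study.

    For every participant-trial, three recordings share one underlying
    true jump: a mocap reference at ``rate_3d`` and two video renditions
    at ``rate_2d`` that differ only in the rater noise realisation.
    Ground-truth event times and variables are returned for recovery
    tests. Fully reproducible from ``design.seed``.
    """
    population = population or JumpPopulation()
    noise_2d_rater_a = noise_2d_rater_a or DEFAULT_NOISE_2D
    noise_2d_rater_b = noise_2d_rater_b or DEFAULT_NOISE_2D
    noise_3d = noise_3d or DEFAULT_NOISE_3D
    event_cfg = event_cfg or EventConfig()

    root = np.random.SeedSequence(design.seed)
    pop_ss, noise_ss = root.spawn(2)
    rng_pop = np.random.default_rng(pop_ss)
    rng_seeds = np.random.default_rng(noise_ss)

    recordings: list[TrialRecording] = []
    truth_rows: list[dict] = []
    jumps: dict[tuple[str, int], GroundTruthJump] = {}
    sources = (("mocap", None, design.rate_3d, noise_3d),
               ("video", "A", design.rate_2d, noise_2d_rater_a),
               ("video", "B", design.rate_2d, noise_2d_rater_b))

    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        base = population.sample_participant(rng_pop)
        for trial in range(1, design.n_trials + 1):
            gt = population.sample_trial(base, rng_pop)
            jumps[(pid, trial)] = gt
            ev = gt.true_event_times(event_cfg)
            for marker in gt.marker_gains:
                truth_rows.append({"participant": pid, "trial": trial,
                                   "marker": marker, **ev,
                                   **gt.true_variables(marker, event_cfg)})
            clean = {rate: {m: generate_trajectory(gt, rate, m)
                            for m in gt.marker_gains}
                     for rate in {design.rate_2d, design.rate_3d}}
            for source, rater, rate, noise in sources:
                trajs = {m: corrupt(clean[rate][m], noise,
                                    int(rng_seeds.integers(2**31)))
                         for m in gt.marker_gains}
                recordings.append(TrialRecording(
                    participant=pid, trial=trial, source=source,
                    rater=rater, trajectories=trajs))

    return SimulatedStudy(design=design, recordings=recordings,
                          ground_truth=pd.DataFrame(truth_rows), jumps=jumps)
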