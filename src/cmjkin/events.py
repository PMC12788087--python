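"""CMJ phase segmentation by fractional displacement thresholds.

The displacement–time curve of a countermovement jump is segmented with
two 5 % rules applied to the baseline-referenced signal ``z`` (quiet
standing = 0, upward positive):

* the **trough** ``i_min`` is the lowest point of the signal — the
  eccentric→concentric transition;
* **onset** is the first sample of the descent into the countermovement
  at which the marker has dropped by ``onset_fraction`` (default 5 %) of
  the total downward displacement ``|z[i_min]|``;
* **take-off** is the first sample after the trough at which the marker
  has risen by ``takeoff_fraction`` (default 5 %) of the total upward
  displacement ``z[i_apex] − z[i_min]`` (the *literal* rule), or is
  within that fraction of the apex (the *apex-referenced* rule);
* the **apex** ``i_apex`` is the highest point after the trough.

Five variables are derived: eccentric duration ``dt_ecc`` (onset→trough),
propulsion duration ``dt_PP`` (trough→take-off), total take-off time
``dt_take_off`` (their sum), countermovement depth ``h_Z_min``
(= z at the trough, negative) and maximum vertical displacement
``h_Z_max`` (apex above baseline by default, or above the take-off
position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NoCountermovementError(ValueError):
    """Signal has no detectable descent-then-ascent jump pattern."""


@dataclass
class EventConfig:
    """Detection thresholds and references.

    onset_fraction, takeoff_fraction : float in (0, 1)
        Fractional displacement thresholds (default 0.05 each).
    takeoff_rule : {"literal", "apex_referenced"}
        "literal" places take-off where the signal has risen 5 % of the
        trough-to-apex range above the trough; "apex_referenced" where it
        is within 5 % of the apex.
    baseline_window : float
        Duration (s) of initial quiet standing used to define z = 0.
    hmax_reference : {"baseline", "takeoff"}
        Reference for h_Z_max: apex above standing baseline, or apex
        above the take-off position.
    """

    onset_fraction: float = 0.05
    takeoff_fraction: float = 0.05
    takeoff_rule: str = "literal"
    baseline_window: float = 0.5
    hmax_reference: str = "baseline"

    def __post_init__(self) -> None:
        for f in (self.onset_fraction, self.takeoff_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("threshold fractions must lie in (0, 1)")
        if self.takeoff_rule not in ("literal", "apex_referenced"):
            raise ValueError(f"unknown takeoff_rule {self.takeoff_rule!r}")
        if self.hmax_reference not in ("baseline", "takeoff"):
            raise ValueError(f"unknown hmax_reference {self.hmax_reference!r}")
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")


@dataclass
class CMJEvents:
    """Detected sample indices and times of the four jump events."""

    i_onset: int
    i_min: int
    i_takeoff: int
    i_apex: int
    t_onset: float
    t_min: float
    t_takeoff: float
    t_apex: float

    def __post_init__(self) -> None:
        if not (self.i_onset < self.i_min < self.i_takeoff <= self.i_apex):
            raise ValueError(
                "event order violated: onset < min < takeoff <= apex required")


@dataclass
class CMJVariables:
    """The five derived jump variables (s / m)."""

    dt_ecc: float
    dt_PP: float
    dt_take_off: float
    h_Z_min: float
    h_Z_max: float

    _FIELDS = ("dt_ecc", "dt_PP", "dt_take_off", "h_Z_min", "h_Z_max")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


def estimate_baseline(z: np.ndarray, t: np.ndarray,
                      cfg: EventConfig) -> float:
    """Mean displacement over the initial quiet-standing window.

    Returned offset is what callers subtract before detection; applying
    the centring twice is idempotent (the second offset is ~0).
    """
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    in_window = t <= t[0] + cfg.baseline_window
    if in_window.all() and t[-1] - t[0] < cfg.baseline_window:
        raise ValueError("baseline window longer than signal")
    return float(z[in_window].mean())


def detect_events(z: np.ndarray, t: np.ndarray,
                  cfg: EventConfig | None = None) -> CMJEvents:
    """Segment a baseline-referenced displacement signal into CMJ events.

    ``z`` must be in metres, gap-free, and contain a descent below
    baseline followed by an ascent above it.

    Raises :class:`NoCountermovementError` for flat/monotone signals, an
    apex not above baseline, or thresholds that are never crossed.
    """
    cfg = cfg or EventConfig()
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    if len(z) < 3:
        raise NoCountermovementError("signal too short")

    i_min = int(np.argmin(z))  # first global minimum on ties
    z_min = z[i_min]
    if z_min >= 0.0 or i_min == 0 or i_min == len(z) - 1:
        raise NoCountermovementError(
            "no countermovement: signal never descends below baseline "
            "between interior samples")

    i_apex = i_min + int(np.argmax(z[i_min:]))
    z_apex = z[i_apex]
    if z_apex <= 0.0:
        raise NoCountermovementError("apex not above baseline")

    # Onset: walk backward from the trough through the contiguous run of
    # samples that have descended at least onset_fraction of the downward
    # range; its first sample is the onset. Walking backward means
    # pre-movement sway below the threshold (separated from the descent
    # by a recovery above it) cannot trigger onset.
    thr_on = cfg.onset_fraction * z_min  # negative
    j = i_min
    while j > 0 and z[j - 1] <= thr_on:
        j -= 1
    if j == 0:
        raise NoCountermovementError(
            "onset threshold already crossed at first sample "
            "(no quiet baseline before the descent)")
    i_onset = j

    rng = z_apex - z_min
    if cfg.takeoff_rule == "literal":
        thr_to = z_min + cfg.takeoff_fraction * rng
    else:  # apex_referenced
        thr_to = z_apex - cfg.takeoff_fraction * rng
    above = np.nonzero(z[i_min + 1:i_apex + 1] >= thr_to)[0]
    if len(above) == 0:
        raise NoCountermovementError("take-off threshold never crossed")
    i_takeoff = i_min + 1 + int(above[0])

    return CMJEvents(
        i_onset=i_onset, i_min=i_min, i_takeoff=i_takeoff, i_apex=i_apex,
        t_onset=float(t[i_onset]), t_min=float(t[i_min]),
        t_takeoff=float(t[i_takeoff]), t_apex=float(t[i_apex]),
    )


def extract_variables(ev: CMJEvents, z: np.ndarray, t: np.ndarray,
                      cfg: EventConfig | None = None) -> CMJVariables:
    """Derive the five jump variables from detected events."""
    cfg = cfg or EventConfig()
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    dt_ecc = float(t[ev.i_min] - t[ev.i_onset])
    dt_pp = float(t[ev.i_takeoff] - t[ev.i_min])
    if cfg.hmax_reference == "baseline":
        h_max = float(z[ev.i_apex])
    else:
        h_max = float(z[ev.i_apex] - z[ev.i_takeoff])
    return CMJVariables(
        dt_ecc=dt_ecc,
        dt_PP=dt_pp,
        dt_take_off=dt_ecc + dt_pp,
        h_Z_min=float(z[ev.i_min]),
        h_Z_max=h_max,
    )


def detect_and_extract(z: np.ndarray, t: np.ndarray,
                       cfg: EventConfig | None = None,
                       ) -> tuple[CMJEvents, CMJVariables]:
    """Baseline-centre, detect events and extract variables in one call."""
    cfg = cfg or EventConfig()
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    z0 = z - estimate_baseline(z, t, cfg)
    ev = detect_events(z0, t, cfg)
    return ev, extract_variables(ev, z0, t, cfg)
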