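"""Core domain containers for marker displacement time series.

A countermovement jump (CMJ) recording is, for our purposes, a set of
vertical marker displacement signals (shoulder, hip, knee) sampled on a
uniform time base, originating either from a 3D motion-capture export
(``source="mocap"``) or from a 2D video-tracking export produced by a
particular rater (``source="video"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

MARKERS = ("shoulder", "hip", "knee")

#: Unit tags for displacement samples.
UNIT_PIXELS = "pixels"
UNIT_METRES = "metres"


@dataclass
class Trajectory:
    """One marker's vertical displacement signal.

    Parameters
    ----------
    marker : str
        Anatomical landmark name, one of ``shoulder``, ``hip``, ``knee``.
    t : ndarray
        Strictly increasing sample times in seconds.
    z : ndarray
        Vertical displacement samples, upward positive, in ``unit``.
    unit : str
        ``"pixels"`` (uncalibrated video) or ``"metres"``.
    rate : float
        Nominal sampling rate in Hz.
    missing : ndarray of bool, optional
        Per-sample missing indicator (occluded frames). Defaults to all
        present.
    """

    marker: str
    t: np.ndarray
    z: np.ndarray
    unit: str
    rate: float
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.t.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if self.t.ndim != 1:
            raise ValueError("time base must be one-dimensional")
        if not (len(self.t) == len(self.z) == len(self.missing)):
            raise ValueError("t, z and missing must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.unit not in (UNIT_PIXELS, UNIT_METRES):
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Nominal sample period in seconds."""
        return 1.0 / self.rate

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def with_z(self, z: np.ndarray, *, unit: Optional[str] = None,
               missing: Optional[np.ndarray] = None) -> "Trajectory":
        """Copy with replaced samples (and optionally unit / missing mask)."""
        return replace(
            self,
            z=np.asarray(z, dtype=float),
            unit=self.unit if unit is None else unit,
            missing=(self.missing.copy() if missing is None
                     else np.asarray(missing, dtype=bool)),
        )


@dataclass
class TrialRecording:
    """All marker trajectories for one participant-trial from one source."""

    participant: str
    trial: int
    source: str  # "mocap" | "video"
    trajectories: dict[str, Trajectory] = field(default_factory=dict)
    rater: Optional[str] = None  # video only

    def __post_init__(self) -> None:
        if self.source not in ("mocap", "video"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "mocap" and self.rater is not None:
            raise ValueError("mocap recordings carry no rater")
        n = {len(tr) for tr in self.trajectories.values()}
        if len(n) > 1:
            raise ValueError("all trajectories must share one time base")

    @property
    def label(self) -> str:
        """Method label used in agreement tables: 'mocap' or 'video:<rater>'."""
        if self.source == "mocap":
            return "mocap"
        return f"video:{self.rater}" if self.rater else "video"

    def markers(self) -> list[str]:
        return list(self.trajectories)
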