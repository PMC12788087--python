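"""Readers and writers for trajectory exports and canonical tables.

Three on-disk forms are supported, all plain delimited text:

* **video dialect** — spreadsheet exports of 2D tracking software: one
  time column plus one vertical-coordinate column per marker, with a
  declared delimiter (comma/semicolon/tab), decimal separator (dot or
  comma), time unit (s or ms) and coordinate unit (pixels or metres).
  Blank cells are occluded samples.
* **mocap dialect** — tab-delimited trajectory exports with leading
  ``KEY<TAB>value`` header lines (frame count, frequency, marker names,
  units) followed by per-frame X/Y/Z columns per marker; the vertical
  (Z) component is retained, mm converted to m, and all-zero frames are
  occluded samples.
* **canonical long table** — columns ``participant, trial, source,
  rater, marker, time_s, z_m, missing``; the interchange format between
  pipeline stages.

Dialects are declared, never sniffed: export layouts vary by software
version, so silent guessing is worse than an explicit option.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UNIT_METRES, UNIT_PIXELS, Trajectory, TrialRecording
from .events import CMJVariables

CANONICAL_COLUMNS = ["participant", "trial", "source", "rater", "marker",
                     "time_s", "z_m", "missing"]


@dataclass
class VideoDialect:
    """Declared layout of a 2D tracking spreadsheet export."""

    delimiter: str = ";"
    decimal: str = "."
    time_unit: str = "s"      # {"s", "ms"}
    unit: str = UNIT_METRES   # {"pixels", "metres"}
    time_column: str = "t"

    def __post_init__(self) -> None:
        if self.delimiter not in (",", ";", "\t"):
            raise ValueError("delimiter must be comma, semicolon or tab")
        if self.decimal not in (".", ","):
            raise ValueError("decimal separator must be dot or comma")
        if self.time_unit not in ("s", "ms"):
            raise ValueError("time unit must be 's' or 'ms'")
        if self.unit not in (UNIT_PIXELS, UNIT_METRES):
            raise ValueError("unit must be 'pixels' or 'metres'")
        if self.delimiter == self.decimal:
            raise ValueError("delimiter and decimal separator clash")


def read_video_export(path: str | os.PathLike | _io.StringIO,
                      dialect: VideoDialect | None = None,
                      *, participant: str = "unknown", trial: int = 1,
                      rater: str | None = None,
                      marker_map: dict[str, str] | None = None,
                      ) -> TrialRecording:
    """Parse a 2D tracking spreadsheet export into a TrialRecording.

    Every column other than the time column is taken as one marker's
    vertical coordinate; ``marker_map`` renames export headers to
    canonical marker names. Blank cells become missing samples. Raises
    on an empty file, a non-monotone time column, or unmapped markers
    when a map is given.
    """
    dialect = dialect or VideoDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    if df.empty:
        raise ValueError("empty video export")
    if dialect.time_column not in df.columns:
        raise ValueError(f"missing time column {dialect.time_column!r}")
    t = df[dialect.time_column].to_numpy(float)
    if dialect.time_unit == "ms":
        t = t / 1000.0
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column is not strictly increasing")
    if len(t) >= 2:
        rate = (len(t) - 1) / (t[-1] - t[0])
    else:
        rate = 1.0

    marker_cols = [c for c in df.columns if c != dialect.time_column]
    if marker_map is not None:
        unmapped = [c for c in marker_cols if c not in marker_map]
        if unmapped:
            raise ValueError(f"unmapped marker columns: {unmapped}")
    trajectories = {}
    for col in marker_cols:
        name = marker_map[col] if marker_map else col
        z = df[col].to_numpy(float)
        missing = np.isnan(z)
        trajectories[name] = Trajectory(
            marker=name, t=t, z=z, unit=dialect.unit, rate=rate,
            missing=missing)
    return TrialRecording(participant=participant, trial=trial,
                          source="video", rater=rater,
                          trajectories=trajectories)


def write_video_export(rec: TrialRecording,
                       path: str | os.PathLike | _io.StringIO,
                       dialect: VideoDialect | None = None) -> None:
    """Write a recording in the video spreadsheet dialect (round-trips)."""
    dialect = dialect or VideoDialect()
    t = next(iter(rec.trajectories.values())).t
    out = {dialect.time_column: t * (1000.0 if dialect.time_unit == "ms"
                                     else 1.0)}
    for name, traj in rec.trajectories.items():
        z = traj.z.astype(float).copy()
        z[traj.missing] = np.nan
        out[name] = z
    pd.DataFrame(out).to_csv(path, sep=dialect.delimiter,
                             decimal=dialect.decimal, index=False,
                             float_format="%.6g")


# ---------------------------------------------------------------------------
# mocap dialect
# ---------------------------------------------------------------------------

def read_mocap_export(path: str | os.PathLike | _io.StringIO,
                      *, participant: str = "unknown", trial: int = 1,
                      ) -> TrialRecording:
    """Parse a tab-delimited mocap trajectory export.

    Header lines ``NO_OF_FRAMES``, ``FREQUENCY``, ``MARKER_NAMES`` and
    ``UNITS`` (mm or m) precede per-frame rows of X/Y/Z triplets per
    marker. The Z column is the vertical displacement; all-zero frames
    are occlusions. Raises when the declared frame count disagrees with
    the body or a marker's Z column is absent.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split("\t")
        key = parts[0].strip()
        if key.upper() in ("NO_OF_FRAMES", "FREQUENCY", "MARKER_NAMES",
                           "UNITS"):
            header[key.upper()] = "\t".join(parts[1:]).strip()
            body_start = i + 1
        else:
            break
    for req in ("NO_OF_FRAMES", "FREQUENCY", "MARKER_NAMES"):
        if req not in header:
            raise ValueError(f"mocap export missing header line {req}")
    n_frames = int(header["NO_OF_FRAMES"])
    rate = float(header["FREQUENCY"])
    markers = header["MARKER_NAMES"].split()
    unit_scale = 1e-3 if header.get("UNITS", "mm").lower() == "mm" else 1.0

    rows = [ln.split("\t") for ln in lines[body_start:] if ln.strip()]
    if len(rows) != n_frames:
        raise ValueError(
            f"declared {n_frames} frames but body has {len(rows)} rows")
    data = np.array([[float(v) for v in row] for row in rows])
    if data.shape[1] < 3 * len(markers):
        raise ValueError("missing vertical component: fewer than 3 columns "
                         "per declared marker")
    t = np.arange(n_frames) / rate
    trajectories = {}
    for k, name in enumerate(markers):
        xyz = data[:, 3 * k:3 * k + 3]
        missing = np.all(xyz == 0.0, axis=1)  # occluded frames zero-filled
        z = xyz[:, 2] * unit_scale
        z[missing] = np.nan
        trajectories[name] = Trajectory(marker=name, t=t, z=z,
                                        unit=UNIT_METRES, rate=rate,
                                        missing=missing)
    return TrialRecording(participant=participant, trial=trial,
                          source="mocap", trajectories=trajectories)


def write_mocap_export(rec: TrialRecording,
                       path: str | os.PathLike | _io.StringIO,
                       units: str = "mm") -> None:
    """Write a recording in the mocap dialect (X=Y=0, Z vertical)."""
    trajs = rec.trajectories
    markers = list(trajs)
    n = len(next(iter(trajs.values())))
    rate = next(iter(trajs.values())).rate
    scale = 1e3 if units == "mm" else 1.0
    lines = [f"NO_OF_FRAMES\t{n}", f"FREQUENCY\t{rate:g}",
             f"MARKER_NAMES\t{' '.join(markers)}", f"UNITS\t{units}"]
    for i in range(n):
        row: list[str] = []
        for m in markers:
            if trajs[m].missing[i]:
                row += ["0", "0", "0"]
            else:
                row += ["0", "0", f"{trajs[m].z[i] * scale:.6f}"]
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# canonical long table
# ---------------------------------------------------------------------------

def recordings_to_frame(recordings: list[TrialRecording]) -> pd.DataFrame:
    """Flatten recordings into the canonical long-format table."""
    frames = []
    for rec in recordings:
        for name, traj in rec.trajectories.items():
            frames.append(pd.DataFrame({
                "participant": rec.participant, "trial": rec.trial,
                "source": rec.source,
                "rater": rec.rater if rec.rater is not None else "",
                "marker": name, "time_s": traj.t, "z_m": traj.z,
                "missing": traj.missing.astype(int)}))
    if not frames:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CANONICAL_COLUMNS]


def frame_to_recordings(df: pd.DataFrame) -> list[TrialRecording]:
    """Rebuild TrialRecordings from a canonical long-format table."""
    recordings = []
    df = df.copy()
    df["rater"] = df["rater"].fillna("")
    for (pid, trial, source, rater), grp in df.groupby(
            ["participant", "trial", "source", "rater"], sort=True):
        trajectories = {}
        for marker, sub in grp.groupby("marker", sort=False):
            t = sub["time_s"].to_numpy(float)
            n = len(t)
            rate = (n - 1) / (t[-1] - t[0]) if n >= 2 else 1.0
            trajectories[marker] = Trajectory(
                marker=marker, t=t, z=sub["z_m"].to_numpy(float),
                unit=UNIT_METRES, rate=rate,
                missing=sub["missing"].to_numpy(bool))
        recordings.append(TrialRecording(
            participant=str(pid), trial=int(trial), source=str(source),
            rater=str(rater) or None, trajectories=trajectories))
    return recordings


def write_canonical(recordings: list[TrialRecording],
                    path: str | os.PathLike, *, overwrite: bool = False
                    ) -> None:
    _check_overwrite(path, overwrite)
    recordings_to_frame(recordings).to_csv(path, index=False,
                                           float_format="%.9g")


def read_canonical(path: str | os.PathLike) -> list[TrialRecording]:
    return frame_to_recordings(pd.read_csv(
        path, keep_default_na=True,
        dtype={"participant": str},
        converters={"rater": str}))


# ---------------------------------------------------------------------------
# variables tables
# ---------------------------------------------------------------------------

VARIABLE_KEY = ["participant", "trial", "source", "rater", "marker"]


def variables_to_frame(records: list[dict]) -> pd.DataFrame:
    """Long variables table: one row per trial × source × marker.

    Each record is a dict with the key fields plus a ``variables``
    entry holding a :class:`~cmjkin.events.CMJVariables`.
    """
    rows = []
    for rec in records:
        var = rec["variables"]
        values = var.as_dict() if isinstance(var, CMJVariables) else dict(var)
        rows.append({k: rec.get(k, "") for k in VARIABLE_KEY} | values)
    cols = VARIABLE_KEY + list(CMJVariables._FIELDS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def write_variables(records: list[dict] | pd.DataFrame,
                    path: str | os.PathLike, *, overwrite: bool = False
                    ) -> None:
    """Write a variables table; round-trips to 6 significant digits."""
    _check_overwrite(path, overwrite)
    df = (records if isinstance(records, pd.DataFrame)
          else variables_to_frame(records))
    df.to_csv(path, index=False, float_format="%.6g")


def read_variables(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant": str},
                       converters={"rater": str})


def _check_overwrite(path, overwrite: bool) -> None:
    if not overwrite and os.path.exists(path):
        raise FileExistsError(f"{path} exists; pass overwrite=True")
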