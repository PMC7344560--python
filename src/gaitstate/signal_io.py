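"""Reading and writing accelerometer recordings and feature tables.

Recordings are plain delimited text (comma or tab, sniffed), one row per
sample, either three numeric columns ``ax, ay, az`` or four with a leading
timestamp column. Acceleration is in units of g; the sensors this package
models saturate at +/-8 g, and values outside that range are either rejected
("strict") or clipped ("clip") — never passed through silently.

A cohort is declared by a small YAML file mapping each signal file to its
subject, knee, medication state and course; :func:`load_cohort` materialises
it into :class:`Cohort`.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

SENSOR_RANGE_G = 8.0
DEFAULT_FS = 32.0

KNEES = ("left", "right")
STATES = ("on", "off", "unknown")

#: Window-level statistical features, in published order (per knee).
STAT_FEATURE_NAMES = (
    "Mean",
    "Standard Deviation",
    "Median Absolute Deviation",
    "Minimum",
    "Maximum",
    "Energy Measure",
    "Inter Quartile Range",
    "Signal Magnitude Area",
    "Skewness",
    "Kurtosis",
)

#: Window-level spatiotemporal gait features, in published order (per knee).
GAIT_FEATURE_NAMES = (
    "Step Length",
    "Stride Length",
    "Step Time",
    "Stride Time",
    "Step Velocity",
    "Stride Velocity",
)

#: The 32 model features: 16 per knee, left block then right block.
FEATURE_NAMES = tuple(
    f"{name} ({knee} Knee)"
    for knee in ("Left", "Right")
    for name in STAT_FEATURE_NAMES + GAIT_FEATURE_NAMES
)

#: Metadata columns carried alongside the features in a feature table.
META_COLUMNS = ("subject_id", "course_id", "window_index", "label")

#: Per-knee quality flags for windows where too few gait events were found.
FLAG_COLUMNS = ("Gait Flag (Left Knee)", "Gait Flag (Right Knee)")


class ParseError(ValueError):
    """A signal file row could not be parsed."""


class RangeError(ValueError):
    """An acceleration value fell outside the sensor range under strict mode."""


@dataclass
class Recording:
    """One knee's tri-axial acceleration stream for one course.

    ``samples`` is an (n, 3) float array in g, ordered in time at a fixed
    sampling frequency ``fs``.
    """

    subject_id: str
    knee: str
    state: str
    samples: np.ndarray
    fs: float = DEFAULT_FS
    course_id: str = ""

    def __post_init__(self) -> None:
        if self.knee not in KNEES:
            raise ValueError(f"knee must be one of {KNEES}, got {self.knee!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if len(self.samples) == 0:
            raise ValueError("recording must contain at least one sample")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def replace(self, **kwargs) -> "Recording":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """A collection of recordings with a subject roster."""

    recordings: list[Recording] = field(default_factory=list)

    @property
    def roster(self) -> set[str]:
        return {rec.subject_id for rec in self.recordings}

    def __len__(self) -> int:
        return len(self.recordings)

    def knee_pair(self, subject_id: str, state: str) -> tuple[Recording, Recording]:
        """Return (left, right) recordings for one subject's course."""
        pair = {
            rec.knee: rec
            for rec in self.recordings
            if rec.subject_id == subject_id and rec.state == state
        }
        if set(pair) != {"left", "right"}:
            raise KeyError(
                f"subject {subject_id!r} state {state!r}: need one left and one "
                f"right recording, found knees {sorted(pair)}"
            )
        return pair["left"], pair["right"]

    def courses(self) -> list[tuple[str, str]]:
        """Ordered unique (subject_id, state) pairs present in the cohort."""
        seen: dict[tuple[str, str], None] = {}
        for rec in self.recordings:
            seen.setdefault((rec.subject_id, rec.state), None)
        return list(seen)

    def validate_complete(self) -> None:
        """Check the study shape: 4 recordings per subject (2 knees x 2 states)."""
        for sid in sorted(self.roster):
            combos = {
                (rec.knee, rec.state) for rec in self.recordings if rec.subject_id == sid
            }
            expected = {(k, s) for k in KNEES for s in ("on", "off")}
            if combos != expected:
                raise ValueError(
                    f"subject {sid!r} has knee/state combinations {sorted(combos)}, "
                    f"expected all of {sorted(expected)}"
                )


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _validate_range(values: np.ndarray, policy: str, path: str | os.PathLike) -> np.ndarray:
    if policy not in ("strict", "clip"):
        raise ValueError("range policy must be 'strict' or 'clip'")
    out_of_range = np.abs(values) > SENSOR_RANGE_G
    if out_of_range.any():
        if policy == "strict":
            row = int(np.argwhere(out_of_range)[0][0])
            raise RangeError(
                f"{path}: acceleration magnitude exceeds {SENSOR_RANGE_G} g "
                f"at data row {row + 1}"
            )
        values = np.clip(values, -SENSOR_RANGE_G, SENSOR_RANGE_G)
    return values


def read_recording(
    path: str | os.PathLike,
    *,
    subject_id: str,
    knee: str,
    state: str = "unknown",
    course_id: str = "",
    fs: float = DEFAULT_FS,
    range_policy: str = "strict",
) -> Recording:
    """Read one knee's tri-axial signal from a delimited text file.

    The file must have 3 numeric columns (ax, ay, az) or 4 with a leading
    timestamp. Timestamps are validated against ``fs`` (median interval within
    1%) and then discarded; the pipeline is index-based throughout.
    """
    rows: list[list[float]] = []
    ncols: int | None = None
    delim: str | None = None
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = [p for p in line.split(delim) if p.strip() != ""]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ParseError(f"{path}: malformed row at line {lineno}: {line!r}")
            if ncols is None:
                if len(values) not in (3, 4):
                    raise ParseError(
                        f"{path}: expected 3 or 4 numeric columns, "
                        f"got {len(values)} at line {lineno}"
                    )
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}: inconsistent column count at line {lineno}"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] == 4:
        t = data[:, 0]
        if len(t) > 1:
            median_dt = float(np.median(np.diff(t)))
            if not np.isclose(median_dt, 1.0 / fs, rtol=0.01):
                raise ParseError(
                    f"{path}: timestamp spacing {median_dt:.6g} s inconsistent "
                    f"with fs={fs} Hz (expected {1.0 / fs:.6g} s)"
                )
        data = data[:, 1:]
    data = _validate_range(data, range_policy, path)
    return Recording(
        subject_id=subject_id,
        knee=knee,
        state=state,
        samples=data,
        fs=fs,
        course_id=course_id or f"{subject_id}_{state}",
    )


def write_recording(rec: Recording, path: str | os.PathLike, *, timestamps: bool = False) -> None:
    """Write a recording as CSV (optionally with a leading time column)."""
    cols = {"ax": rec.samples[:, 0], "ay": rec.samples[:, 1], "az": rec.samples[:, 2]}
    if timestamps:
        cols = {"t": np.arange(len(rec.samples)) / rec.fs, **cols}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table as delimited text; round-trips losslessly."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: feature table missing columns {missing}")
    table["subject_id"] = table["subject_id"].astype(str)
    table["course_id"] = table["course_id"].astype(str)
    table["label"] = table["label"].astype(str)
    return table


def _coerce_state(value) -> str:
    # YAML 1.1 parses bare on/off as booleans; map them back.
    if value is True:
        return "on"
    if value is False:
        return "off"
    return str(value).lower()


def load_cohort(config_path: str | os.PathLike, *, range_policy: str = "strict") -> Cohort:
    """Load a cohort declared by a YAML layout file.

    The file holds ``fs`` (optional, default 32) and a ``recordings`` list of
    entries with keys path, subject_id, knee, state and optional course_id.
    Relative paths resolve against the config file's directory.
    """
    with open(config_path, "r", encoding="utf-8") as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, Mapping) or "recordings" not in cfg:
        raise ValueError(f"{config_path}: cohort config must map a 'recordings' list")
    fs = float(cfg.get("fs", DEFAULT_FS))
    base = os.path.dirname(os.fspath(config_path))
    recs = []
    for entry in cfg["recordings"]:
        path = entry["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        recs.append(
            read_recording(
                path,
                subject_id=str(entry["subject_id"]),
                knee=str(entry["knee"]).lower(),
                state=_coerce_state(entry.get("state", "unknown")),
                course_id=str(entry.get("course_id", "")),
                fs=fs,
                range_policy=range_policy,
            )
        )
    return Cohort(recordings=recs)


def save_cohort(
    cohort: Cohort, directory: str | os.PathLike, *, config_name: str = "cohort.yaml"
) -> str:
    """Write every recording plus a YAML layout file; returns the config path."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    fs = cohort.recordings[0].fs if cohort.recordings else DEFAULT_FS
    for rec in cohort.recordings:
        fname = f"{rec.subject_id}_{rec.state}_{rec.knee}.csv"
        write_recording(rec, os.path.join(directory, fname))
        entries.append(
            {
                "path": fname,
                "subject_id": rec.subject_id,
                "knee": rec.knee,
                "state": rec.state,
                "course_id": rec.course_id,
            }
        )
    config_path = os.path.join(directory, config_name)
    with open(config_path, "w", encoding="utf-8") as handle:
        yaml.safe_dump({"fs": float(fs), "recordings": entries}, handle, sort_keys=False)
    return config_path
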