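"""Readers and writers for every external table the pipeline touches.

Four streams are supported, each with a strict text dialect:

* pose tables — per-frame 2D coordinates + detection likelihood per body part,
  either in the three-header-row CSV exported by common pose-estimation tools
  (``scorer`` / ``bodyparts`` / ``coords`` header rows) or in a flat one-header
  dialect (``<bodypart>_x, <bodypart>_y, <bodypart>_likelihood`` columns);
* marker tables — per-frame 3D motion-capture marker positions as TSV with one
  ``<marker>_x/_y/_z`` column triple per marker;
* activity tables — timestamped step counts (CSV, ISO-8601 timestamps);
* event tables — labeled intervals or instants (CSV; empty ``end`` = instant).

Readers never impute: empty cells become NaN, never zeros, and timestamps are
required to be strictly increasing (no silent sorting).  Every writer emits a
file its reader parses back to an equal value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COORDS = ("x", "y", "likelihood")
AXES = ("x", "y", "z")
POD_NAMES = ("head", "shoulders", "rear")
LIMB_NAMES = ("LF", "RF", "LH", "RH")


class DialectError(ValueError):
    """The file does not conform to the declared table dialect."""


class ValidationError(ValueError):
    """The file parsed, but its content violates a domain invariant."""


class ParseError(ValueError):
    """A cell could not be converted to the required type."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class PoseTrack:
    """Per-frame 2D coordinates + confidence for one subject in one session.

    ``data`` has a two-level column index ``(bodypart, coord)`` with coords
    ``x``/``y`` in pixels and optionally ``likelihood`` in [0, 1]; the row
    index is the frame number (strictly increasing).
    """

    data: pd.DataFrame
    frame_rate: float
    subject_id: str = "unknown"
    session_time: str | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        idx = np.asarray(self.data.index)
        if len(idx) > 1 and not (np.diff(idx) > 0).all():
            raise ValidationError("frame indices must be strictly increasing")
        if self.has_likelihood:
            lik = self.data.xs("likelihood", axis=1, level=1).to_numpy(float)
            ok = np.isnan(lik) | ((lik >= 0) & (lik <= 1))
            if not ok.all():
                raise ValidationError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def has_likelihood(self) -> bool:
        return "likelihood" in self.data.columns.get_level_values(1)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Session length in seconds (frame count over frame rate)."""
        return self.n_frames / self.frame_rate

    def xy(self, bodypart: str) -> np.ndarray:
        """(n_frames, 2) pixel coordinates of one body part (NaN = missing)."""
        if bodypart not in self.bodyparts:
            raise KeyError(f"unknown bodypart {bodypart!r}; have {self.bodyparts}")
        return self.data[bodypart][["x", "y"]].to_numpy(float)

    def likelihood(self, bodypart: str) -> np.ndarray | None:
        if not self.has_likelihood:
            return None
        return self.data[(bodypart, "likelihood")].to_numpy(float)


@dataclass
class MarkerSeries:
    """Per-frame 3D positions (meters) of named reflective markers.

    ``pods`` maps each rigid pod (head/shoulders/rear) to exactly three marker
    names; ``limbs`` maps limb labels (LF/RF/LH/RH) to single leg markers.
    Gaps are NaN and stay NaN — downstream code decides what to do with them.
    """

    data: pd.DataFrame  # columns: MultiIndex (marker, axis in x/y/z)
    frame_rate: float
    pods: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    limbs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        for pod, markers in self.pods.items():
            if len(set(markers)) != 3:
                raise ValidationError(
                    f"pod {pod!r} must reference exactly 3 distinct markers, got {markers}"
                )
            missing = [m for m in markers if m not in self.markers]
            if missing:
                raise ValidationError(f"pod {pod!r} references unknown markers {missing}")
        for limb, marker in self.limbs.items():
            if marker not in self.markers:
                raise ValidationError(f"limb {limb!r} references unknown marker {marker!r}")

    @property
    def markers(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def xyz(self, marker: str) -> np.ndarray:
        """(n_frames, 3) positions of one marker in meters."""
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}; have {self.markers}")
        return self.data[marker][list(AXES)].to_numpy(float)

    def pod_xyz(self, pod: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The three marker trajectories of one pod, in pod_map order."""
        if pod not in self.pods:
            raise KeyError(f"unknown pod {pod!r}; have {list(self.pods)}")
        a, b, c = self.pods[pod]
        return self.xyz(a), self.xyz(b), self.xyz(c)


@dataclass
class ActivitySeries:
    """Timestamped step counts over one or more days."""

    data: pd.DataFrame  # columns: timestamp (datetime64), steps (int)
    timezone: str = "local"

    def __post_init__(self) -> None:
        ts = self.data["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValidationError("timestamps must be increasing (no silent sorting)")
        if len(ts) > 1 and ts.duplicated().any():
            raise ValidationError("timestamps must be strictly increasing (duplicates found)")
        if (self.data["steps"] < 0).any():
            raise ValidationError("step counts must be >= 0")

    @property
    def days(self) -> list:
        return sorted(self.data["timestamp"].dt.normalize().unique())


@dataclass
class EventLog:
    """Labeled, timestamped intervals or instants.

    ``start``/``end`` are session-relative seconds; ``end`` is NaN for instant
    events (e.g. a retrieval timestamp).
    """

    data: pd.DataFrame  # columns: session_id, label, start, end

    def __post_init__(self) -> None:
        bad = self.data["end"].notna() & (self.data["end"] < self.data["start"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"event row {row}: end < start")

    def with_labels(self, labels: Sequence[str]) -> "EventLog":
        """Restrict to a declared label vocabulary (copy)."""
        sub = self.data[self.data["label"].isin(list(labels))].reset_index(drop=True)
        return EventLog(sub)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

_POSE_HEADER = ("scorer", "bodyparts", "coords")


def read_pose_table(
    stream,
    frame_rate: float,
    dialect: str = "auto",
    subject_id: str = "unknown",
    session_time: str | None = None,
) -> PoseTrack:
    """Parse a pose-coordinate table into a :class:`PoseTrack`.

    ``dialect`` is ``"three_row"`` (scorer/bodyparts/coords header rows, the
    export format of common tracking tools), ``"flat"`` (single header of
    ``<bodypart>_<coord>`` columns), or ``"auto"`` to sniff.  Missing cells
    become NaN, never zeros.
    """
    text = _as_text(stream)
    if dialect == "auto":
        first = text.split("\n", 1)[0]
        # any of the three reserved header words marks an (attempted) three-row file
        dialect = "three_row" if first.split(",")[0].strip() in _POSE_HEADER else "flat"
    if dialect == "three_row":
        df = _read_pose_three_row(text)
    elif dialect == "flat":
        df = _read_pose_flat(text)
    else:
        raise ValueError(f"unknown pose dialect {dialect!r}")
    return PoseTrack(df, frame_rate=frame_rate, subject_id=subject_id, session_time=session_time)


def _read_pose_three_row(text: str) -> pd.DataFrame:
    lines = text.splitlines()
    if len(lines) < 3:
        raise DialectError("three-row pose dialect needs at least 3 header rows")
    for i, expected in enumerate(_POSE_HEADER):
        lead = lines[i].split(",")[0].strip()
        if lead != expected:
            raise DialectError(
                f"header row {i}: expected leading cell {expected!r}, found {lead!r}"
            )
    bp_cells = [c.strip() for c in lines[1].split(",")[1:]]
    coord_cells = [c.strip() for c in lines[2].split(",")[1:]]
    bad_coord = sorted({c for c in coord_cells if c not in COORDS})
    if bad_coord:
        raise DialectError(f"header row 2: unknown coord labels {bad_coord}")
    pairs = list(zip(bp_cells, coord_cells))
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValidationError(f"duplicate bodypart columns: {dupes}")
    df = pd.read_csv(io.StringIO(text), header=[0, 1, 2], index_col=0, float_precision="round_trip")
    # rebuild column labels from the raw header (read_csv mangles nothing here,
    # but this keeps labels exactly as written)
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["bodypart", "coord"])
    return df.astype(float)


def _read_pose_flat(text: str) -> pd.DataFrame:
    raw = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    if raw.columns[0] != "frame":
        raise DialectError(f"flat pose dialect: first column must be 'frame', got {raw.columns[0]!r}")
    raw = raw.set_index("frame")
    split = []
    for col in raw.columns:
        bp, _, coord = col.rpartition("_")
        if not bp or coord not in COORDS:
            raise DialectError(f"flat pose dialect: column {col!r} is not <bodypart>_<coord>")
        split.append((bp, coord))
    if len(set(split)) != len(split):
        raise ValidationError("duplicate bodypart/coord column")
    raw.columns = pd.MultiIndex.from_tuples(split, names=["bodypart", "coord"])
    return raw.astype(float)


def write_pose_table(track: PoseTrack, stream, dialect: str = "flat") -> None:
    """Write a pose table in the given dialect (inverse of the reader)."""
    if dialect == "flat":
        flat = track.data.copy()
        flat.columns = [f"{bp}_{coord}" for bp, coord in flat.columns]
        flat.index.name = "frame"
        flat.to_csv(stream)
    elif dialect == "three_row":
        out = track.data.copy()
        out.columns = pd.MultiIndex.from_tuples(
            [("pigpheno", bp, coord) for bp, coord in out.columns],
            names=list(_POSE_HEADER),
        )
        out.to_csv(stream)
    else:
        raise ValueError(f"unknown pose dialect {dialect!r}")


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------


def read_marker_table(
    stream,
    frame_rate: float,
    pod_map: Mapping[str, Sequence[str]] | None = None,
    limb_map: Mapping[str, str] | None = None,
) -> MarkerSeries:
    """Parse a marker TSV (one ``_x/_y/_z`` column triple per marker).

    ``pod_map`` resolves pod names to exactly three marker names each; a pod
    mapped to any other count is a :class:`ValidationError`.  Non-numeric
    cells raise :class:`ParseError` with the offending row index.
    """
    text = _as_text(stream)
    raw = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if raw.columns[0] != "frame":
        raise DialectError(f"marker TSV: first column must be 'frame', got {raw.columns[0]!r}")
    raw = raw.set_index("frame")
    split = []
    for col in raw.columns:
        marker, _, axis = col.rpartition("_")
        if not marker or axis not in AXES:
            raise DialectError(f"marker TSV: column {col!r} is not <marker>_<axis>")
        split.append((marker, axis))
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    nonempty = raw.notna() & raw.apply(lambda col: col.astype(str).str.strip() != "")
    fresh_nan = numeric.isna() & nonempty
    if fresh_nan.to_numpy().any():
        row = int(np.flatnonzero(fresh_nan.any(axis=1).to_numpy())[0])
        raise ParseError(f"non-numeric cell in data row {row}")
    numeric = raw.astype(float)  # numpy strtod: exact round trip of repr output
    numeric.columns = pd.MultiIndex.from_tuples(split, names=["marker", "axis"])
    numeric.index = pd.Index(pd.to_numeric(numeric.index), name="frame")
    pods = {k: tuple(v) for k, v in (pod_map or {}).items()}
    for pod, markers in pods.items():
        if len(markers) != 3:
            raise ValidationError(f"pod {pod!r} must map to 3 markers, got {len(markers)}")
    return MarkerSeries(
        numeric.astype(float),
        frame_rate=frame_rate,
        pods=pods,
        limbs=dict(limb_map or {}),
    )


def write_marker_table(series: MarkerSeries, stream) -> None:
    out = series.data.copy()
    out.columns = [f"{marker}_{axis}" for marker, axis in out.columns]
    out.index.name = "frame"
    out.to_csv(stream, sep="\t")


# ---------------------------------------------------------------------------
# activity and event tables
# ---------------------------------------------------------------------------


def read_activity_table(stream, timezone: str = "local") -> ActivitySeries:
    """Parse a step-count CSV with columns ``timestamp,steps``."""
    df = pd.read_csv(_wrap(stream), float_precision="round_trip")
    required = {"timestamp", "steps"}
    if not required.issubset(df.columns):
        raise DialectError(f"activity CSV needs columns {sorted(required)}, got {list(df.columns)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["steps"] = pd.to_numeric(df["steps"])
    if not (df["steps"] == df["steps"].round()).all():
        raise ParseError("step counts must be integers")
    df["steps"] = df["steps"].astype(int)
    return ActivitySeries(df[["timestamp", "steps"]], timezone=timezone)


def write_activity_table(series: ActivitySeries, stream) -> None:
    out = series.data.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(stream, index=False)


def read_event_table(stream) -> EventLog:
    """Parse an event CSV with columns ``session_id,label,start,end``."""
    df = pd.read_csv(_wrap(stream), float_precision="round_trip")
    required = {"session_id", "label", "start", "end"}
    if not required.issubset(df.columns):
        raise DialectError(f"event CSV needs columns {sorted(required)}, got {list(df.columns)}")
    df["start"] = pd.to_numeric(df["start"])
    df["end"] = pd.to_numeric(df["end"])
    return EventLog(df[["session_id", "label", "start", "end"]].reset_index(drop=True))


def write_event_table(log: EventLog, stream) -> None:
    log.data.to_csv(stream, index=False)


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["session_id", "metric", "value", "unit"]


def write_report(metrics: pd.DataFrame | Sequence[Mapping], stream) -> None:
    """Emit a metrics CSV: one row per (session, metric), with a units column."""
    df = pd.DataFrame(metrics)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"report is missing columns {missing}")
    df[REPORT_COLUMNS].to_csv(stream, index=False)


def read_report(stream) -> pd.DataFrame:
    df = pd.read_csv(_wrap(stream), float_precision="round_trip")
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"report is missing columns {missing}")
    return df[REPORT_COLUMNS]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_text(stream) -> str:
    if hasattr(stream, "read"):
        return stream.read()
    with open(stream, "r") as fh:
        return fh.read()


def _wrap(stream):
    if hasattr(stream, "read"):
        return stream
    return stream  # pandas accepts paths directly
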