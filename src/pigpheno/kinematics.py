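"""Rigid-pod kinematics and quadruped gait segmentation.

Three rigid marker pods (head, shoulders, rear) each carry three reflective
markers.  A local coordinate system is built per pod and frame: origin at the
markers' geometric center, one axis perpendicular to the pod base (plane of
the markers), an anterior axis toward a designated front marker, and a
medial-lateral axis completing a right-handed set.  The rotation from a
reference frame (first valid frame by default) to each frame is decomposed
into intrinsic z-y'-x'' Euler angles about the pod axes: yaw (left/right
rotation about the base-perpendicular axis), pitch (nodding, about the
medial-lateral axis) and roll (lateral tilt, about the anterior axis), in
degrees, unwrapped over time.

Leg markers define the gait: a touchdown is the onset of stance — the marker
drops into the lowest band of its vertical excursion while its speed falls
below a fraction of its peak — and one gait cycle is the touchdown sequence
left hind -> left front -> right hind -> right front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .io_formats import MarkerSeries

logger = logging.getLogger(__name__)

LIMB_ORDER = ("LH", "LF", "RH", "RF")  # touchdown order defining one cycle


class DegeneratePodError(ValueError):
    """The three pod markers are collinear or coincident."""


@dataclass
class LocalFrame:
    """Orthonormal right-handed pod frame: columns = (anterior, medial-lateral, perpendicular)."""

    origin: np.ndarray  # (3,)
    basis: np.ndarray  # (3, 3), columns are the axes in global coordinates


@dataclass
class AngleSeries:
    """Per-frame pod rotation relative to the reference frame, degrees, unwrapped."""

    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    pod_id: str
    frame_rate: float
    gimbal: np.ndarray = field(default=None)  # frames with |pitch| > 85 deg

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"yaw": self.yaw, "pitch": self.pitch, "roll": self.roll}[name]
        except KeyError:
            raise KeyError(f"channel must be yaw/pitch/roll, got {name!r}") from None


@dataclass
class GaitCycle:
    """One (possibly incomplete) LH->LF->RH->RF touchdown quadruple, seconds."""

    lh: float | None = None
    lf: float | None = None
    rh: float | None = None
    rf: float | None = None
    complete: bool = False

    @property
    def start(self) -> float | None:
        return self.lh

    @property
    def end(self) -> float | None:
        for t in (self.rf, self.rh, self.lf, self.lh):
            if t is not None:
                return t
        return None


# ---------------------------------------------------------------------------
# pod frames and angles
# ---------------------------------------------------------------------------

_AREA_TOL = 1e-9


def pod_frame(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    front: int = 0,
    up: np.ndarray = (0.0, 0.0, 1.0),
    prev_normal: np.ndarray | None = None,
) -> LocalFrame:
    """Local frame of one marker triad.

    Origin = centroid.  The perpendicular axis is the unit normal of the
    marker plane, signed toward ``up`` (or toward ``prev_normal`` when
    tracking continuity over frames).  The anterior axis is the in-plane
    unit direction from the centroid to the designated front marker; the
    medial-lateral axis completes a right-handed set.
    """
    pts = np.asarray([p1, p2, p3], float)
    if np.isnan(pts).any():
        raise ValueError("pod markers contain missing coordinates")
    origin = pts.mean(axis=0)
    cross = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    norm = np.linalg.norm(cross)
    if norm / 2.0 <= _AREA_TOL:  # triangle area
        raise DegeneratePodError("pod markers are collinear or coincident")
    n = cross / norm
    ref = np.asarray(prev_normal if prev_normal is not None else up, float)
    if float(n @ ref) < 0:
        n = -n
    d = pts[front] - origin
    a = d - (d @ n) * n
    a_norm = np.linalg.norm(a)
    if a_norm <= _AREA_TOL:
        raise DegeneratePodError("front marker coincides with the pod center")
    a = a / a_norm
    ml = np.cross(n, a)  # y = z cross x for a right-handed frame
    return LocalFrame(origin=origin, basis=np.column_stack([a, ml, n]))


def pod_frames(
    series: MarkerSeries, pod: str, front: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame pod frames with normal-sign continuity.

    Returns (origins (n,3), bases (n,3,3), valid mask).  Frames with any
    missing marker are invalid (NaN), and the normal sign is carried across
    them from the last valid frame.
    """
    m1, m2, m3 = series.pod_xyz(pod)
    n = len(m1)
    origins = np.full((n, 3), np.nan)
    bases = np.full((n, 3, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    prev_normal = None
    for i in range(n):
        pts = (m1[i], m2[i], m3[i])
        if any(np.isnan(p).any() for p in pts):
            continue
        frame = pod_frame(*pts, front=front, prev_normal=prev_normal)
        origins[i] = frame.origin
        bases[i] = frame.basis
        prev_normal = frame.basis[:, 2]
        valid[i] = True
    if not valid.any():
        raise ValueError(f"pod {pod!r} has no valid frames")
    return origins, bases, valid


GIMBAL_PITCH_DEG = 85.0


def pod_angles(
    bases: np.ndarray,
    valid: np.ndarray,
    frame_rate: float,
    pod_id: str = "pod",
    reference: np.ndarray | None = None,
) -> AngleSeries:
    """Decompose each frame's rotation from the reference into yaw/pitch/roll.

    The rotation taking the reference basis to the current basis, expressed
    in the reference pod axes (R = B_ref^T B_t), is decomposed as intrinsic
    z-y'-x'' Euler angles: yaw about the base-perpendicular axis, pitch about
    the medial-lateral axis, roll about the anterior axis.  Angles are in
    degrees and unwrapped across valid frames; frames with |pitch| above 85
    degrees are flagged (decomposition ill-conditioned near gimbal lock).
    """
    n = len(bases)
    if reference is None:
        reference = bases[int(np.flatnonzero(valid)[0])]
    yaw = np.full(n, np.nan)
    pitch = np.full(n, np.nan)
    roll = np.full(n, np.nan)
    idx = np.flatnonzero(valid)
    rel = np.einsum("ji,njk->nik", reference, bases[idx])  # B_ref^T @ B_t
    eul = Rotation.from_matrix(rel).as_euler("ZYX", degrees=True)
    eul = np.unwrap(eul, axis=0, period=360.0)
    yaw[idx], pitch[idx], roll[idx] = eul[:, 0], eul[:, 1], eul[:, 2]
    gimbal = np.zeros(n, dtype=bool)
    gimbal[idx] = np.abs(eul[:, 1]) > GIMBAL_PITCH_DEG
    if gimbal.any():
        logger.warning("%d frames near gimbal lock for pod %s", int(gimbal.sum()), pod_id)
    return AngleSeries(yaw=yaw, pitch=pitch, roll=roll, pod_id=pod_id, frame_rate=frame_rate, gimbal=gimbal)


def angle_range(series: AngleSeries, channel: str) -> float:
    """Peak-to-peak (max - min) of one angle channel over valid frames, degrees."""
    v = series.channel(channel)
    if np.isnan(v).all():
        return float("nan")
    return float(np.nanmax(v) - np.nanmin(v))


def mean_velocity(origins: np.ndarray, frame_rate: float) -> tuple[float, float]:
    """(average linear velocity, mean speed) of a pod origin, m/s.

    Average linear velocity is net displacement between the first and last
    valid frames over elapsed time; mean speed is path length over the same
    elapsed time.
    """
    origins = np.asarray(origins, float)
    valid = ~np.isnan(origins).any(axis=1)
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return 0.0, 0.0
    elapsed = (idx[-1] - idx[0]) / frame_rate
    pts = origins[idx]
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    path = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return net / elapsed, path / elapsed


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def lowpass(series: np.ndarray, cutoff: float, frame_rate: float, order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0 (DC gain exactly 1)."""
    if not 0 < cutoff < frame_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    x = np.asarray(series, float)
    sos = signal.butter(order, cutoff, btype="low", fs=frame_rate, output="sos")
    # pad by several filter time constants: the default pad is too short for
    # steep low cutoffs and lets edge transients leak into the output
    padlen = min(x.shape[0] - 1, int(3 * frame_rate / cutoff))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


# ---------------------------------------------------------------------------
# touchdowns and gait cycles
# ---------------------------------------------------------------------------


@dataclass
class TouchdownParams:
    stance_height_frac: float = 0.15  # band above the vertical minimum
    speed_frac: float = 0.10  # of the limb's peak speed
    min_run: int = 2  # frames a stance must persist
    merge_gap: int = 3  # non-stance blips up to this many frames are bridged


def detect_touchdowns(
    positions: np.ndarray,
    frame_rate: float,
    params: TouchdownParams | None = None,
    vertical_axis: int = 2,
) -> np.ndarray:
    """Touchdown times (s) of one leg marker: onsets of stance.

    Stance frames have vertical position within the lowest
    ``stance_height_frac`` of the marker's vertical excursion AND
    forward-difference speed below ``speed_frac`` of the peak speed.  The
    onset of each stance run of >= ``min_run`` frames is a touchdown; a run
    already in stance at the first frame has no observed onset and is
    dropped.
    """
    params = params or TouchdownParams()
    pos = np.asarray(positions, float)
    h = pos[:, vertical_axis]
    if np.isnan(pos).any():
        raise ValueError("touchdown detection requires gap-free leg positions")
    dt = 1.0 / frame_rate
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    speed = np.append(step, step[-1])  # forward difference; last frame repeats
    h_band = h.min() + params.stance_height_frac * np.ptp(h)
    peak = speed.max()
    stance = (h <= h_band) & (speed <= params.speed_frac * peak) if peak > 0 else np.zeros(len(h), bool)
    # debounce: a measurement blip cannot be a real swing phase
    if params.merge_gap > 0:
        gap_start = None
        for i in range(1, len(stance)):
            if not stance[i] and stance[i - 1]:
                gap_start = i
            elif stance[i] and gap_start is not None:
                if i - gap_start <= params.merge_gap:
                    stance[gap_start:i] = True
                gap_start = None
    onsets = []
    i = 0
    n = len(stance)
    while i < n:
        if stance[i]:
            j = i
            while j < n and stance[j]:
                j += 1
            if i > 0 and j - i >= params.min_run:
                onsets.append(i)
            i = j
        else:
            i += 1
    if not onsets:
        logger.warning("no touchdown events detected for this limb")
    return np.asarray(onsets, float) / frame_rate


def detect_all_touchdowns(
    series: MarkerSeries, params: TouchdownParams | None = None, vertical_axis: int = 2
) -> dict[str, np.ndarray]:
    """Touchdown times per limb from the series' limb marker map."""
    out = {}
    for limb in LIMB_ORDER:
        if limb not in series.limbs:
            raise KeyError(f"limb map is missing {limb!r}")
        out[limb] = detect_touchdowns(
            series.xyz(series.limbs[limb]), series.frame_rate, params, vertical_axis
        )
    return out


def segment_gait_cycles(touchdowns: dict[str, np.ndarray]) -> list[GaitCycle]:
    """Greedy left-to-right matching of the LH->LF->RH->RF touchdown pattern.

    Each touchdown is used at most once and cycles do not overlap: within a
    cycle simultaneous touchdowns are taken in pattern order (LH <= LF <= RH
    <= RF), and the next cycle's LH must fall strictly after the previous
    RF.  A trailing partial match is returned with ``complete=False``.
    """
    times = {limb: np.sort(np.asarray(touchdowns.get(limb, []), float)) for limb in LIMB_ORDER}
    ptr = {limb: 0 for limb in LIMB_ORDER}
    cycles: list[GaitCycle] = []
    cursor = -np.inf
    while True:
        picked = {}
        t = cursor
        ok = True
        for k, limb in enumerate(LIMB_ORDER):
            arr = times[limb]
            i = ptr[limb]
            while i < len(arr) and (arr[i] <= t if k == 0 else arr[i] < t):
                i += 1
            if i >= len(arr):
                ok = False
                break
            picked[limb] = (i, arr[i])
            t = arr[i]
        if not ok:
            if picked:
                partial = GaitCycle(complete=False)
                for limb, (_, tt) in picked.items():
                    setattr(partial, limb.lower(), tt)
                cycles.append(partial)
            break
        for limb, (i, _) in picked.items():
            ptr[limb] = i + 1
        cycles.append(
            GaitCycle(
                lh=picked["LH"][1],
                lf=picked["LF"][1],
                rh=picked["RH"][1],
                rf=picked["RF"][1],
                complete=True,
            )
        )
        cursor = picked["RF"][1]
    return cycles


# ---------------------------------------------------------------------------
# whole-trial driver
# ---------------------------------------------------------------------------


@dataclass
class GaitMetrics:
    velocity: float  # average linear velocity, m/s
    mean_speed: float
    ranges: dict[str, dict[str, float]]  # pod -> channel -> degrees
    touchdowns: dict[str, np.ndarray]
    n_cycles: int
    angles: dict[str, AngleSeries] = field(default_factory=dict)


def analyze_gait(
    series: MarkerSeries,
    front: int = 0,
    cutoff: float | None = None,
    velocity_pod: str = "shoulders",
    touchdown_params: TouchdownParams | None = None,
) -> GaitMetrics:
    """Full per-trial kinematic summary.

    ``cutoff`` (Hz), when given, low-pass filters pod markers before frame
    construction (noise suppression); leg markers are analyzed unfiltered
    since touchdown detection thresholds on speed and height bands.
    """
    work = series
    if cutoff is not None:
        filtered = series.data.copy()
        pod_markers = {m for triple in series.pods.values() for m in triple}
        for marker in pod_markers:
            cols = [(marker, ax) for ax in ("x", "y", "z")]
            filtered[cols] = lowpass(filtered[cols].to_numpy(float), cutoff, series.frame_rate)
        work = MarkerSeries(filtered, series.frame_rate, pods=series.pods, limbs=series.limbs)
    ranges: dict[str, dict[str, float]] = {}
    angles: dict[str, AngleSeries] = {}
    for pod in work.pods:
        origins, bases, valid = pod_frames(work, pod, front=front)
        ang = pod_angles(bases, valid, work.frame_rate, pod_id=pod)
        angles[pod] = ang
        ranges[pod] = {ch: angle_range(ang, ch) for ch in ("yaw", "pitch", "roll")}
    # velocity from the raw centroid: net displacement needs no smoothing, and
    # zero-phase filter edge transients would bias the endpoints
    m1, m2, m3 = series.pod_xyz(velocity_pod)
    vel = mean_velocity((m1 + m2 + m3) / 3.0, series.frame_rate)
    touchdowns = detect_all_touchdowns(series, touchdown_params) if series.limbs else {}
    cycles = segment_gait_cycles(touchdowns) if touchdowns else []
    n_complete = sum(c.complete for c in cycles)
    return GaitMetrics(
        velocity=vel[0],
        mean_speed=vel[1],
        ranges=ranges,
        touchdowns=touchdowns,
        n_cycles=n_complete,
        angles=angles,
    )
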