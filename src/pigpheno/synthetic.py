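"""Synthetic generators for all four input streams, with recorded ground truth.

The study's raw recordings are not deposited, so every analysis stage is
exercised on simulated data whose true values are known exactly.  Each
generator is a pure function of (parameters, seed): the same call is
bit-reproducible, and a single global seed fans out to fixed per-stream
substreams so adding a generator never perturbs existing ones.  Each
generator returns ``(data, GroundTruth)`` and the ground truth can be
serialized to YAML next to the data files.

Default parameter sets encode the study's published magnitudes (a ~217 m
session distance scale, 8-9 h nightly sleep, midday activity peak, 1.93 m/s
gait speed, angle ranges of 30/17/12 degrees) so demo outputs resemble the
figures; this is emulation of the data-generating process, not reproduction
of the animals.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_formats import ActivitySeries, EventLog, MarkerSeries, PoseTrack
from .openfield import ArenaGeometry

# fixed substream labels: a global seed spawns one child per stream
_STREAM_KEY = {"openfield": 1, "escapes": 2, "contacts": 3, "retrievals": 4, "actigraphy": 5, "gait": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_KEY[stream]]))


@dataclass
class GroundTruth:
    """True generating values recorded beside each synthetic dataset."""

    stream: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_yaml(self, stream_or_path) -> None:
        text = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        if hasattr(stream_or_path, "write"):
            stream_or_path.write(text)
        else:
            with open(stream_or_path, "w") as fh:
                fh.write(text)

    @classmethod
    def from_yaml(cls, stream_or_path) -> "GroundTruth":
        if hasattr(stream_or_path, "read"):
            raw = yaml.safe_load(stream_or_path.read())
        else:
            with open(stream_or_path) as fh:
                raw = yaml.safe_load(fh)
        return cls(**raw)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# open field
# ---------------------------------------------------------------------------


def simulate_openfield(
    arena: ArenaGeometry | None = None,
    duration: float = 600.0,
    frame_rate: float = 30.0,
    step_scale: float = 0.01,
    door_bias: float = 0.0,
    seed: int = 0,
) -> tuple[PoseTrack, GroundTruth]:
    """Reflected random walk inside the arena, optionally door-biased.

    ``step_scale`` is the per-frame Gaussian step SD in meters.  ``door_bias``
    is the target long-run door-zone occupancy fraction: 0 gives a plain
    reflected walk over the whole arena (long-run uniform); a positive value
    drives a two-state switching walk whose stationary door-zone fraction is
    the given value (door state confined to the door band, away state to its
    complement).  Ground truth records the exact realized path length and
    door-zone frame fraction.
    """
    arena = arena or ArenaGeometry()
    if not 0.0 <= door_bias < 1.0:
        raise ValueError("door_bias must be in [0, 1)")
    rng = _rng(seed, "openfield")
    n = int(round(duration * frame_rate))
    L = arena.side_length
    depth = arena.door_zone_depth
    steps = rng.normal(0.0, step_scale, size=(n, 2)) if step_scale > 0 else np.zeros((n, 2))
    xy = np.empty((n, 2))
    switch_scale = 0.02  # per-frame state-switch rate scale (mean bout ~1/(c p) frames)
    if door_bias == 0.0:
        pos = np.array([L / 2.0, L / 2.0])
        for i in range(n):
            pos = _reflect(pos + steps[i], 0.0, L, 0.0, L)
            xy[i] = pos
    else:
        p = door_bias
        q_exit_door = switch_scale * (1.0 - p)
        q_exit_away = switch_scale * p
        in_door = rng.random() < p
        pos = np.array([arena.door_center, depth / 2.0 if in_door else (L + depth) / 2.0])
        flips = rng.random(n)
        for i in range(n):
            if in_door and flips[i] < q_exit_door:
                in_door = False
                pos = np.array([pos[0], depth + (L - depth) * rng.random()])
            elif not in_door and flips[i] < q_exit_away:
                in_door = True
                pos = np.array([pos[0], depth * rng.random()])
            lo, hi = (0.0, depth) if in_door else (depth, L)
            pos = _reflect(pos + steps[i], 0.0, L, lo, hi)
            xy[i] = pos
    true_path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    true_door_frac = float((xy[:, 1] < depth).mean())
    px = arena.to_px(xy)
    data = pd.DataFrame(
        {
            ("head_back", "x"): px[:, 0],
            ("head_back", "y"): px[:, 1],
            ("head_back", "likelihood"): np.ones(n),
        }
    )
    data.columns = data.columns.set_names(["bodypart", "coord"])
    track = PoseTrack(data, frame_rate=frame_rate, subject_id="sim")
    gt = GroundTruth(
        stream="openfield",
        seed=seed,
        params={
            "duration": duration,
            "frame_rate": frame_rate,
            "step_scale": step_scale,
            "door_bias": door_bias,
            "side_length": L,
            "door_zone_depth": depth,
            "switch_scale": switch_scale,
        },
        truth={"path_length_m": true_path, "door_zone_fraction": true_door_frac, "n_frames": n},
    )
    return track, gt


def _reflect(pos: np.ndarray, x_lo, x_hi, y_lo, y_hi) -> np.ndarray:
    out = pos.copy()
    for k, (lo, hi) in enumerate(((x_lo, x_hi), (y_lo, y_hi))):
        span = hi - lo
        v = (out[k] - lo) % (2 * span)
        out[k] = lo + (v if v <= span else 2 * span - v)
    return out


def simulate_escapes(
    n_bouts: int = 12, mean_duration: float = 4.0, session_length: float = 600.0, seed: int = 0
) -> tuple[EventLog, GroundTruth]:
    """Annotated escape bouts with exponential durations; truth holds the exact sum."""
    rng = _rng(seed, "escapes")
    if n_bouts == 0:
        df = pd.DataFrame({"session_id": [], "label": [], "start": [], "end": []})
        gt = GroundTruth(
            stream="escapes",
            seed=seed,
            params={"n_bouts": 0, "mean_duration": mean_duration},
            truth={"count": 0, "cumulative_s": 0.0},
        )
        return EventLog(df), gt
    durations = rng.exponential(mean_duration, size=n_bouts)
    gap_scale = max((session_length - durations.sum()) / n_bouts, 1.0)
    gaps = rng.exponential(gap_scale, size=n_bouts)
    starts = np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    df = pd.DataFrame(
        {
            "session_id": "sim",
            "label": "escape",
            "start": starts,
            "end": starts + durations,
        }
    )
    gt = GroundTruth(
        stream="escapes",
        seed=seed,
        params={"n_bouts": n_bouts, "mean_duration": mean_duration},
        truth={"count": n_bouts, "cumulative_s": float(durations.sum())},
    )
    return EventLog(df), gt


# ---------------------------------------------------------------------------
# novel object and ball pit
# ---------------------------------------------------------------------------


def simulate_contacts(
    p_novel: float = 0.75,
    n_bouts: int = 40,
    bout_mean: float = 6.0,
    gap_mean: float = 8.0,
    seed: int = 0,
) -> tuple[EventLog, GroundTruth]:
    """Object-contact bouts: each labeled novel with probability ``p_novel``.

    Bout durations and inter-bout gaps are exponential; truth records the
    programmed preference and the realized per-object seconds and counts.
    """
    if not 0.0 <= p_novel <= 1.0:
        raise ValueError("p_novel must be in [0, 1]")
    rng = _rng(seed, "contacts")
    durations = rng.exponential(bout_mean, size=n_bouts)
    gaps = rng.exponential(gap_mean, size=n_bouts)
    novel = rng.random(n_bouts) < p_novel
    starts = np.cumsum(gaps + np.concatenate(([0.0], durations[:-1])))
    df = pd.DataFrame(
        {
            "session_id": "sim",
            "label": np.where(novel, "novel", "familiar"),
            "start": starts,
            "end": starts + durations,
        }
    )
    novel_s = float(durations[novel].sum())
    familiar_s = float(durations[~novel].sum())
    gt = GroundTruth(
        stream="contacts",
        seed=seed,
        params={"p_novel": p_novel, "n_bouts": n_bouts, "bout_mean": bout_mean},
        truth={
            "novel_seconds": novel_s,
            "familiar_seconds": familiar_s,
            "n_novel": int(novel.sum()),
            "n_familiar": int((~novel).sum()),
            "realized_novel_pct": 100.0 * novel_s / (novel_s + familiar_s)
            if novel_s + familiar_s > 0
            else float("nan"),
        },
    )
    return EventLog(df), gt


def default_latency_schedule(start: float = 26.5, stop: float = 7.8, n_weeks: int = 18) -> np.ndarray:
    """Linearly decreasing per-week mean retrieval latency (seconds)."""
    return np.linspace(start, stop, n_weeks)


def simulate_retrievals(
    schedule: np.ndarray | None = None,
    first_week: int = 19,
    noise_sd: float = 0.0,
    n_rewards: int = 6,
    seed: int = 0,
) -> tuple[EventLog, GroundTruth]:
    """Weekly ball-pit trials following a programmed mean-latency schedule.

    Week ``first_week + i`` gets ``n_rewards`` retrievals whose latencies are
    the scheduled mean plus Gaussian noise (floored at 0.5 s).  Truth records
    the schedule, the realized per-trial mean latencies, and the closed-form
    least-squares slope of the schedule against week age.
    """
    schedule = np.asarray(default_latency_schedule() if schedule is None else schedule, float)
    rng = _rng(seed, "retrievals")
    rows = []
    realized = []
    weeks = first_week + np.arange(len(schedule))
    for week, mean in zip(weeks, schedule):
        lat = np.maximum(rng.normal(mean, noise_sd, size=n_rewards), 0.5) if noise_sd > 0 else np.full(n_rewards, mean)
        times = np.cumsum(lat)
        realized.append(float(lat.mean()))
        for t in times:
            rows.append({"session_id": f"week{week}", "label": "retrieval", "start": float(t), "end": np.nan})
    df = pd.DataFrame(rows)
    x = weeks.astype(float)
    dx = x - x.mean()
    slope = float(dx @ (schedule - schedule.mean()) / (dx @ dx))
    gt = GroundTruth(
        stream="retrievals",
        seed=seed,
        params={"first_week": first_week, "noise_sd": noise_sd, "n_rewards": n_rewards},
        truth={
            "schedule": schedule,
            "weeks": weeks,
            "realized_means": realized,
            "schedule_slope": slope,
        },
    )
    return EventLog(df), gt


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------


def _parse_hhmm(t: str) -> float:
    h, m = t.split(":")
    return int(h) + int(m) / 60.0


def simulate_actigraphy(
    wake_time: str = "07:00",
    sleep_time: str = "23:00",
    peak_window: tuple[str, str] = ("12:00", "16:00"),
    day_count: int = 5,
    base_rate: float = 6.0,
    peak_rate: float = 20.0,
    night_bursts: int = 0,
    burst_minutes: int = 30,
    start_date: str = "2024-03-04",
    seed: int = 0,
) -> tuple[ActivitySeries, GroundTruth]:
    """Zero-inflated per-minute step counts with a programmed sleep schedule.

    Steps are Poisson at ``base_rate``/min while awake, ``peak_rate`` inside
    the daily peak window, and zero while asleep (``sleep_time`` to
    ``wake_time`` across midnight).  ``night_bursts`` inserts that many short
    movement bursts (each ``burst_minutes`` long, > 1 h inside the sleep
    bout) per night — noise that a segmentation with min_run of 1 h must
    ignore.  Truth records the per-night onset/wake timestamps and duration.
    """
    wake = _parse_hhmm(wake_time)
    sleep = _parse_hhmm(sleep_time)
    peak_lo, peak_hi = (_parse_hhmm(t) for t in peak_window)
    rng = _rng(seed, "actigraphy")
    t0 = pd.Timestamp(start_date)
    minutes = pd.date_range(t0, t0 + pd.Timedelta(days=day_count), freq="min", inclusive="left")
    hours = minutes.hour + minutes.minute / 60.0
    asleep = (hours >= sleep) | (hours < wake) if sleep > wake else (hours >= sleep) & (hours < wake)
    in_peak = (hours >= peak_lo) & (hours < peak_hi)
    lam = np.where(asleep, 0.0, np.where(in_peak, peak_rate, base_rate))
    steps = rng.poisson(lam)
    # short nocturnal movement bursts, kept > 1 h clear of onset and wake
    nights = []
    for d in range(day_count):
        onset = t0 + pd.Timedelta(days=d, hours=sleep)
        wake_ts = t0 + pd.Timedelta(days=d + (1 if sleep > wake else 0), hours=wake)
        nights.append((onset, wake_ts))
        for _ in range(night_bursts):
            span_min = (wake_ts - onset).total_seconds() / 60.0 - 120.0 - burst_minutes
            if span_min <= 0:
                continue
            b0 = onset + pd.Timedelta(minutes=60.0 + rng.random() * span_min)
            sel = (minutes >= b0) & (minutes < b0 + pd.Timedelta(minutes=burst_minutes))
            steps = np.where(sel & asleep, rng.poisson(3.0, size=len(steps)), steps)
    series = ActivitySeries(pd.DataFrame({"timestamp": minutes, "steps": steps.astype(int)}))
    duration_h = (wake - sleep) % 24.0
    truth_nights = [
        {"date": str(onset.date()), "onset": str(onset), "wake": str(w), "duration_h": duration_h}
        for onset, w in nights
        if w <= minutes[-1] + pd.Timedelta(minutes=1)
    ]
    gt = GroundTruth(
        stream="actigraphy",
        seed=seed,
        params={
            "wake_time": wake_time,
            "sleep_time": sleep_time,
            "peak_window": list(peak_window),
            "day_count": day_count,
            "base_rate": base_rate,
            "peak_rate": peak_rate,
            "night_bursts": night_bursts,
        },
        truth={
            "nights": truth_nights,
            "sleep_duration_h": duration_h,
            "peak_start_minutes": peak_lo * 60.0,
            "peak_end_minutes": peak_hi * 60.0,
        },
    )
    return series, gt


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

# pod marker layout in the pod's own frame (z = 0 plane, front on +x):
# an isoceles triad elongated along the anterior axis, ~24 cm tip to base,
# matching a rigid spine-mounted pod; the long lever arm of the front marker
# keeps the yaw estimate well conditioned against marker noise
_POD_LOCAL = np.array(
    [
        [0.15, 0.0, 0.0],  # front marker (defines the anterior axis)
        [-0.075, 0.09, 0.0],
        [-0.075, -0.09, 0.0],
    ]
)

_POD_OFFSETS = {"head": (0.35, 0.0, 0.55), "shoulders": (0.0, 0.0, 0.50), "rear": (-0.45, 0.0, 0.52)}
# quarter-stride offsets with a small lead-in so the first LH touchdown falls
# strictly inside the trial (an onset at frame 0 is unobservable)
_LIMB_PHASE = {"LH": 0.1, "LF": 0.35, "RH": 0.6, "RF": 0.85}
_LIMB_LATERAL = {"LH": 0.12, "LF": 0.12, "RH": -0.12, "RF": -0.12}
_LIMB_FORWARD = {"LH": -0.4, "LF": 0.35, "RH": -0.4, "RF": 0.35}


def simulate_gait(
    speed: float = 1.93,
    stride_freq: float = 1.0,
    angle_amplitudes: tuple[float, float, float] = (15.0, 8.5, 6.0),
    marker_noise_sd: float = 0.0,
    duration: float = 10.25,
    frame_rate: float = 100.0,
    duty_factor: float = 0.6,
    step_height: float = 0.06,
    sway: float = 0.01,
    seed: int = 0,
) -> tuple[MarkerSeries, GroundTruth]:
    """Three rigid pods plus four limb markers walking down a runway.

    Pods advance at ``speed`` with a small lateral sway and are animated by
    sinusoidal (yaw, pitch, roll) with the given amplitudes in degrees (all
    zero-phase, so the first frame is the natural angle reference; each
    peak-to-peak range is twice its amplitude).  Limb markers follow a
    stance/swing cycle with touchdowns in LH->LF->RH->RF order at quarter-
    stride phase offsets.  ``marker_noise_sd`` is the RMS 3D residual of the
    isotropic Gaussian marker noise in meters (the convention motion-capture
    vendors use for residuals), i.e. each coordinate gets independent noise
    of ``marker_noise_sd / sqrt(3)``.

    At the default 100 frames/s with a 1 Hz stride, sinusoid extrema fall
    exactly on sample instants, so noiseless angle ranges equal 2x amplitude
    to machine precision.
    """
    rng = _rng(seed, "gait")
    n = int(round(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    amp_yaw, amp_pitch, amp_roll = angle_amplitudes
    phase = 2.0 * np.pi * stride_freq * t
    yaw = amp_yaw * np.sin(phase)
    pitch = amp_pitch * np.sin(phase)
    roll = amp_roll * np.sin(phase)
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("ZYX", np.column_stack([yaw, pitch, roll]), degrees=True).as_matrix()
    center = np.column_stack(
        [speed * t, sway * np.sin(phase), np.zeros(n)]
    )
    columns = {}
    pods = {}
    origins_true = {}
    for pod, offset in _POD_OFFSETS.items():
        pod_center = center + np.asarray(offset)
        origins_true[pod] = pod_center
        names = []
        for j in range(3):
            world = pod_center + np.einsum("nij,j->ni", R, _POD_LOCAL[j])
            name = f"{pod}{j + 1}"
            names.append(name)
            for k, ax in enumerate(("x", "y", "z")):
                columns[(name, ax)] = world[:, k]
        pods[pod] = tuple(names)
    T0 = 1.0 / stride_freq
    stride_len = speed * T0
    touchdowns = {}
    limbs = {}
    for limb, phi in _LIMB_PHASE.items():
        u = t / T0 - phi
        k = np.floor(u)
        frac = u - k
        x_stance = _LIMB_FORWARD[limb] + (k + 1) * stride_len  # foothold of cycle k
        in_stance = frac < duty_factor
        prog = np.clip((frac - duty_factor) / (1.0 - duty_factor), 0.0, 1.0)
        # linear swing advance: the foot still moves fast on its final swing
        # sample, so stance onset is a sharp speed drop at the touchdown frame
        x = np.where(
            in_stance,
            x_stance - stride_len,
            x_stance - stride_len + stride_len * prog,
        )
        z = np.where(in_stance, 0.02, 0.02 + step_height * np.sin(np.pi * prog))
        y = np.full(n, _LIMB_LATERAL[limb])
        name = f"leg_{limb}"
        limbs[limb] = name
        columns[(name, "x")] = x
        columns[(name, "y")] = y
        columns[(name, "z")] = z
        # programmed touchdowns strictly inside the trial (onset must be observable)
        events = []
        j = 0
        while True:
            td = (j + phi) * T0
            if td > duration - 2.0 / frame_rate:
                break
            if td > 1e-12:
                events.append(td)
            j += 1
        touchdowns[limb] = np.asarray(events)
    data = pd.DataFrame(columns)
    data.columns = data.columns.set_names(["marker", "axis"])
    if marker_noise_sd > 0:
        noise = rng.normal(0.0, marker_noise_sd / np.sqrt(3.0), size=data.shape)
        data = data + noise
    # a stride is complete when its LH touchdown is followed by the matching
    # RF three quarter-strides later; counted from the programmed schedule
    rf_set = touchdowns["RF"]
    n_cycles = int(
        sum(np.any(np.abs(rf_set - (lh + 0.75 * T0)) < 1e-9) for lh in touchdowns["LH"])
    )
    elapsed = (n - 1) / frame_rate
    origin0 = origins_true["shoulders"]
    true_velocity = float(np.linalg.norm(origin0[-1] - origin0[0]) / elapsed)
    gt = GroundTruth(
        stream="gait",
        seed=seed,
        params={
            "speed": speed,
            "stride_freq": stride_freq,
            "angle_amplitudes": list(angle_amplitudes),
            "marker_noise_sd": marker_noise_sd,
            "duration": duration,
            "frame_rate": frame_rate,
            "duty_factor": duty_factor,
        },
        truth={
            "yaw_range": 2.0 * amp_yaw,
            "pitch_range": 2.0 * amp_pitch,
            "roll_range": 2.0 * amp_roll,
            "velocity": true_velocity,
            "touchdowns": {limb: touchdowns[limb] for limb in touchdowns},
            "n_cycles": n_cycles,
        },
    )
    series = MarkerSeries(data, frame_rate=frame_rate, pods=pods, limbs=limbs)
    return series, gt
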