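"""Gait feature extraction from 2D body-keypoint sequences.

Input is the per-frame output of any 2D pose estimator: 14 named
keypoints in image coordinates with a confidence value each.  The
pipeline mirrors what a clinical gait video needs after pose
estimation:

1. subject tracking — pick one person per frame by nearest Euclidean
   distance to the previous selection (:func:`track_subject`);
2. Kalman smoothing — per-keypoint, per-axis constant-velocity filter
   (:func:`kalman_smooth`), missing detections handled by predict-only
   steps;
3. peak removal and linear interpolation of missing points
   (:func:`remove_peaks_interpolate`);
4. feature computation — spatiotemporal kinematics, five joint
   ("corner") angles, and sigma-lognormal stroke parameters.

Coordinates are in pixels, times in seconds; angles are radians.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sigma_lognormal import SigmaLognormalParams, sigma_lognormal_decompose

__all__ = [
    "KEYPOINT_NAMES",
    "KeypointFrame",
    "KeypointSequence",
    "GaitFeatureSequence",
    "GaitFeatureVector",
    "SigmaLognormalParams",
    "UnrecoverableChannelError",
    "track_subject",
    "kalman_smooth",
    "remove_peaks_interpolate",
    "compute_kinematics",
    "compute_angles",
    "sigma_lognormal_decompose",
    "assemble_feature_vector",
    "extract_features",
    "DEFAULT_LAYOUT",
    "KINEMATIC_CHANNELS",
    "ANGLE_CHANNELS",
    "CONFIDENCE_FLOOR",
]

KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "neck",
    "shoulder_r",
    "elbow_r",
    "wrist_r",
    "shoulder_l",
    "elbow_l",
    "wrist_l",
    "hip_r",
    "knee_r",
    "ankle_r",
    "hip_l",
    "knee_l",
    "ankle_l",
)
N_KEYPOINTS = len(KEYPOINT_NAMES)
_KP_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

# pose-estimator confidence below this is treated as a missing detection
CONFIDENCE_FLOOR = 0.1

KINEMATIC_CHANNELS = ("d", "dx", "dy", "v", "vx", "vy", "a", "ax", "ay", "rho")
ANGLE_CHANNELS = (
    "angle_nose_neck_hip",
    "angle_neck_hip_knee",
    "angle_shoulder_elbow_wrist",
    "angle_hip_knee_ankle",
    "angle_knee_hip_knee",
)


class UnrecoverableChannelError(ValueError):
    """A keypoint channel has no valid sample to interpolate from."""


@dataclass(frozen=True)
class KeypointFrame:
    """One frame: 14 (x, y) pairs, confidences, and an explicit missing mask."""

    coords: np.ndarray  # (14, 2)
    confidence: np.ndarray  # (14,)
    missing: np.ndarray  # (14,) bool

    def __post_init__(self) -> None:
        if self.coords.shape != (N_KEYPOINTS, 2):
            raise ValueError("a frame holds exactly 14 (x, y) keypoints")


@dataclass
class KeypointSequence:
    """Array-backed temporal sequence of keypoint frames for one subject.

    ``xy[t, k]`` is the (x, y) of keypoint k at frame t; missing detections
    are flagged in ``missing`` and their coordinates are NaN, never a silent
    zero.
    """

    xy: np.ndarray  # (T, 14, 2)
    confidence: np.ndarray  # (T, 14)
    missing: np.ndarray  # (T, 14) bool
    dt: float
    subject_id: str = ""
    direction: str = "left_to_right"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.xy) == 0:
            raise ValueError("a sequence needs at least one frame")
        if self.direction not in ("left_to_right", "right_to_left", "both"):
            raise ValueError(f"unknown walking direction {self.direction!r}")

    @property
    def n_frames(self) -> int:
        return len(self.xy)

    def frame(self, t: int) -> KeypointFrame:
        return KeypointFrame(
            coords=self.xy[t], confidence=self.confidence[t], missing=self.missing[t]
        )

    @classmethod
    def from_arrays(
        cls,
        xy: np.ndarray,
        dt: float,
        confidence: np.ndarray | None = None,
        subject_id: str = "",
        direction: str = "left_to_right",
    ) -> "KeypointSequence":
        xy = np.asarray(xy, dtype=float)
        conf = (
            np.ones(xy.shape[:2]) if confidence is None else np.asarray(confidence, float)
        )
        missing = ~np.isfinite(xy).all(axis=2) | (conf < CONFIDENCE_FLOOR)
        xy = xy.copy()
        xy[missing] = np.nan
        return cls(
            xy=xy,
            confidence=conf,
            missing=missing,
            dt=dt,
            subject_id=subject_id,
            direction=direction,
        )


@dataclass
class GaitFeatureSequence:
    """Per-step kinematic channels plus per-frame corner angles, aligned on steps.

    ``channels`` has one row per inter-frame step (T-1 rows): displacement and
    its components, speed and velocity components, acceleration channels, the
    quadrant-aware tangent angle, and the five corner angles evaluated at the
    step's starting frame.
    """

    channels: pd.DataFrame
    dt: float
    slog: SigmaLognormalParams | None = None


@dataclass(frozen=True)
class GaitFeatureVector:
    values: np.ndarray
    layout: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.layout):
            raise ValueError("layout and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# tracking


def track_subject(
    frames: list[np.ndarray],
    initial_coords: np.ndarray,
    dt: float = 1 / 30,
    subject_id: str = "",
    direction: str = "left_to_right",
) -> KeypointSequence:
    """Isolate one subject from multi-person detections frame by frame.

    ``frames[t]`` is an array (n_persons, 14, 2) of candidate skeletons
    (possibly empty).  Starting from the skeleton nearest ``initial_coords``
    in frame 0, each subsequent frame selects the candidate minimizing the
    summed Euclidean distance over jointly available keypoints to the
    previous selection; a frame with no candidates is marked missing and
    tracking resumes from the last good selection.
    """
    if len(frames) == 0:
        raise ValueError("empty detection sequence")
    T = len(frames)
    xy = np.full((T, N_KEYPOINTS, 2), np.nan)
    prev = np.asarray(initial_coords, dtype=float)
    for t in range(T):
        cands = np.asarray(frames[t], dtype=float)
        if cands.size == 0:
            continue  # missing frame; keep comparing against the last selection
        dists = []
        for c in cands:
            valid = np.isfinite(c).all(axis=1) & np.isfinite(prev).all(axis=1)
            if not valid.any():
                dists.append(np.inf)
                continue
            dists.append(
                float(np.linalg.norm(c[valid] - prev[valid], axis=1).sum())
            )
        best = int(np.argmin(dists))
        xy[t] = cands[best]
        sel_valid = np.isfinite(cands[best]).all(axis=1)
        prev = np.where(sel_valid[:, None], cands[best], prev)
    return KeypointSequence.from_arrays(
        xy, dt=dt, subject_id=subject_id, direction=direction
    )


# ---------------------------------------------------------------------------
# smoothing and cleaning


def kalman_smooth(
    seq: KeypointSequence,
    process_var: float = 2.0e5,
    meas_var: float = 25.0,
    gate_sigma: float = 8.0,
) -> KeypointSequence:
    """Constant-velocity Kalman smoother per keypoint and axis.

    State is (position, velocity); the process model is white acceleration
    with spectral density ``process_var`` (px^2/s^4) and measurement noise
    ``meas_var`` (px^2).  A forward filter pass is followed by the
    Rauch-Tung-Striebel backward pass, so the estimate is a true smoother
    with no phase lag on the oscillatory gait channels.  Missing
    measurements become predict-only steps (the filter coasts across
    detection gaps), as do measurements whose innovation exceeds
    ``gate_sigma`` standard deviations — a first line of defence against
    coordinate spikes, ahead of the explicit peak-removal stage.  The
    missing mask is preserved for the downstream interpolation stage.
    """
    if not np.isfinite(seq.xy[~seq.missing]).all():
        raise ValueError("non-finite coordinates outside the missing mask")
    dt = seq.dt
    F = np.array([[1.0, dt], [0.0, 1.0]])
    Q = process_var * np.array(
        [[dt**3 / 3, dt**2 / 2], [dt**2 / 2, dt]]
    )
    H = np.array([1.0, 0.0])
    R = meas_var
    T = seq.n_frames
    out = np.full_like(seq.xy, np.nan)
    for k in range(N_KEYPOINTS):
        for axis in range(2):
            z = seq.xy[:, k, axis]
            obs = ~seq.missing[:, k]
            if not obs.any():
                continue  # all-missing channel; left for the interpolation stage
            first = int(np.argmax(obs))
            x = np.array([z[first], 0.0])
            P = np.diag([meas_var, 1.0e4])
            xs_f = np.zeros((T, 2))
            Ps_f = np.zeros((T, 2, 2))
            xs_p = np.zeros((T, 2))
            Ps_p = np.zeros((T, 2, 2))
            for t in range(first, T):
                if t > first:
                    x = F @ x
                    P = F @ P @ F.T + Q
                xs_p[t], Ps_p[t] = x, P
                if obs[t]:
                    y_res = z[t] - H @ x
                    S = P[0, 0] + R
                    if y_res * y_res <= gate_sigma**2 * S:
                        K = P @ H / S
                        x = x + K * y_res
                        P = P - np.outer(K, H @ P)
                xs_f[t], Ps_f[t] = x, P
            # RTS backward pass
            xs_s = xs_f.copy()
            Ps_s = Ps_f.copy()
            for t in range(T - 2, first - 1, -1):
                G = Ps_f[t] @ F.T @ np.linalg.inv(Ps_p[t + 1])
                xs_s[t] = xs_f[t] + G @ (xs_s[t + 1] - xs_p[t + 1])
                Ps_s[t] = Ps_f[t] + G @ (Ps_s[t + 1] - Ps_p[t + 1]) @ G.T
            out[first:, k, axis] = xs_s[first:, 0]
    return replace(seq, xy=out, missing=seq.missing.copy())


def remove_peaks_interpolate(
    seq: KeypointSequence, spike_factor: float = 5.0
) -> KeypointSequence:
    """Drop coordinate spikes and linearly fill every missing point.

    A frame whose per-step displacement for a keypoint exceeds
    ``spike_factor`` times that keypoint's median step is re-flagged as
    missing; then every missing interior value is replaced by linear
    interpolation between the nearest valid neighbours, and leading or
    trailing gaps take the nearest valid value.
    """
    if spike_factor <= 1:
        raise ValueError("spike_factor must exceed 1")
    T = seq.n_frames
    xy = seq.xy.copy()
    missing = seq.missing.copy()
    t_grid = np.arange(T, dtype=float)
    for k in range(N_KEYPOINTS):
        valid = ~missing[:, k]
        if valid.sum() >= 3:
            steps = np.linalg.norm(np.diff(xy[:, k, :], axis=0), axis=1)
            med = np.nanmedian(steps)
            if np.isfinite(med) and med > 0:
                spike = np.zeros(T, dtype=bool)
                spike[1:] = steps > spike_factor * med
                missing[:, k] |= spike
                xy[spike, k, :] = np.nan
        valid = ~missing[:, k]
        if not valid.any():
            raise UnrecoverableChannelError(
                f"keypoint {KEYPOINT_NAMES[k]!r} has no valid sample"
            )
        for axis in range(2):
            # np.interp fills interior gaps linearly and clamps the edges
            xy[~valid, k, axis] = np.interp(
                t_grid[~valid], t_grid[valid], xy[valid, k, axis]
            )
    filled_missing = np.zeros_like(missing)
    return replace(seq, xy=xy, missing=filled_missing)


# ---------------------------------------------------------------------------
# feature computation


def compute_angles(coords: np.ndarray) -> dict[str, float]:
    """The five corner angles of one frame, in [0, pi].

    Each angle is the interior angle at the middle joint,
    arccos of the normalized dot product of the two limb vectors.  The
    trunk angles use the hip midpoint; the single-sided angles use the
    right limb by default (see :data:`ANGLE_CHANNELS`); degenerate
    zero-length limbs yield NaN.
    """

    def kp(name: str) -> np.ndarray:
        return coords[_KP_INDEX[name]]

    hip_mid = (kp("hip_r") + kp("hip_l")) / 2.0

    def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
        u, v = a - b, c - b
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0 or not (np.isfinite(nu) and np.isfinite(nv)):
            return np.nan
        return float(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))

    return {
        "angle_nose_neck_hip": angle(kp("nose"), kp("neck"), hip_mid),
        "angle_neck_hip_knee": angle(kp("neck"), hip_mid, kp("knee_r")),
        "angle_shoulder_elbow_wrist": angle(kp("shoulder_r"), kp("elbow_r"), kp("wrist_r")),
        "angle_hip_knee_ankle": angle(kp("hip_r"), kp("knee_r"), kp("ankle_r")),
        "angle_knee_hip_knee": angle(kp("knee_r"), hip_mid, kp("knee_l")),
    }


def compute_kinematics(
    seq: KeypointSequence,
    reference_keypoint: str = "neck",
    accel_mode: str = "ratio",
) -> GaitFeatureSequence:
    """Spatiotemporal channels of the reference keypoint trajectory.

    Per inter-frame step i: displacement components ``dx, dy``, displacement
    magnitude ``d = sqrt(dx^2 + dy^2)``, speed ``v = d / dt`` and component
    velocities, acceleration channels, and the tangent angle ``rho``.

    ``accel_mode='ratio'`` uses a = v_i / dt (and component analogues) —
    the printed shortcut this pipeline defaults to; ``'difference'`` uses
    the conventional a_i = (v_{i+1} - v_i) / dt (last step repeated to keep
    the row count).  ``rho`` is the quadrant-aware arctangent atan2(dy, dx),
    so direction reversals along the walking track are not aliased.
    """
    if seq.n_frames < 2:
        raise ValueError("kinematics need at least 2 frames")
    if accel_mode not in ("ratio", "difference"):
        raise ValueError("accel_mode must be 'ratio' or 'difference'")
    ref = seq.xy[:, _KP_INDEX[reference_keypoint], :]
    dt = seq.dt
    dxy = np.diff(ref, axis=0)
    dx, dy = dxy[:, 0], dxy[:, 1]
    d = np.hypot(dx, dy)
    v, vx, vy = d / dt, dx / dt, dy / dt
    if accel_mode == "ratio":
        a, ax, ay = v / dt, vx / dt, vy / dt
    else:
        a = np.gradient(v, dt)
        ax = np.gradient(vx, dt)
        ay = np.gradient(vy, dt)
    rho = np.arctan2(dy, dx)
    table = pd.DataFrame(
        {"d": d, "dx": dx, "dy": dy, "v": v, "vx": vx, "vy": vy,
         "a": a, "ax": ax, "ay": ay, "rho": rho}
    )
    angle_rows = [compute_angles(seq.xy[t]) for t in range(seq.n_frames - 1)]
    angles = pd.DataFrame(angle_rows)
    table = pd.concat([table, angles], axis=1)
    return GaitFeatureSequence(channels=table, dt=dt)


DEFAULT_SUMMARY_KINEMATICS = ("d", "v", "vx", "vy", "a", "ay", "rho")

DEFAULT_LAYOUT: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in DEFAULT_SUMMARY_KINEMATICS for stat in ("mean", "sd")
) + tuple(
    f"{ch}_{stat}" for ch in ANGLE_CHANNELS for stat in ("mean", "sd")
) + (
    "slog_stroke_count",
    "slog_D_mean",
    "slog_mu_mean",
    "slog_sigma_mean",
    "slog_theta_start_mean",
    "slog_theta_end_mean",
)
assert len(DEFAULT_LAYOUT) == 30


def assemble_feature_vector(
    kin: GaitFeatureSequence,
    slog: SigmaLognormalParams,
    layout_config: tuple[str, ...] | None = None,
) -> GaitFeatureVector:
    """Pack per-channel summaries and stroke globals into the length-j template.

    The default 30-slot layout takes mean and standard deviation of seven
    kinematic channels and the five corner angles, plus six sigma-lognormal
    globals (stroke count and per-parameter means).  ``layout_config``
    selects and orders slots; permuting it permutes the values identically.
    """
    layout = tuple(layout_config) if layout_config is not None else DEFAULT_LAYOUT
    pool: dict[str, float] = {}
    for ch in kin.channels.columns:
        col = kin.channels[ch].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        pool[f"{ch}_mean"] = float(col.mean()) if col.size else 0.0
        pool[f"{ch}_sd"] = float(col.std(ddof=0)) if col.size else 0.0
    strokes = slog.strokes
    pool["slog_stroke_count"] = float(len(strokes))
    for attr, slot in (
        ("D", "slog_D_mean"),
        ("mu", "slog_mu_mean"),
        ("sigma", "slog_sigma_mean"),
        ("theta_start", "slog_theta_start_mean"),
        ("theta_end", "slog_theta_end_mean"),
    ):
        vals = [getattr(s, attr) for s in strokes]
        vals = [v for v in vals if np.isfinite(v)]
        pool[slot] = float(np.mean(vals)) if vals else 0.0
    try:
        values = np.array([pool[name] for name in layout])
    except KeyError as exc:
        raise ValueError(f"layout slot {exc.args[0]!r} is not a known feature") from exc
    return GaitFeatureVector(values=values, layout=layout)


def extract_features(
    seq: KeypointSequence,
    spike_factor: float = 5.0,
    process_var: float = 1.0,
    meas_var: float = 25.0,
    max_strokes: int = 8,
) -> tuple[GaitFeatureSequence, SigmaLognormalParams, GaitFeatureVector]:
    """Full pipeline: Kalman smooth, clean, kinematics + angles, strokes, template.

    Convenience wrapper running the cleaning stages in their canonical
    order on an already-tracked sequence and returning the per-step channel
    table, the stroke decomposition of the speed profile, and the packed
    summary template.
    """
    smoothed = kalman_smooth(seq, process_var=process_var, meas_var=meas_var)
    clean = remove_peaks_interpolate(smoothed, spike_factor=spike_factor)
    kin = compute_kinematics(clean)
    t = np.arange(len(kin.channels)) * seq.dt
    slog = sigma_lognormal_decompose(
        kin.channels["v"].to_numpy(), t, tangent_angle=kin.channels["rho"].to_numpy(),
        max_strokes=max_strokes,
    )
    kin.slog = slog
    vec = assemble_feature_vector(kin, slog)
    return kin, slog, vec
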