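"""Kinematic parameter extraction from head-tracking trajectories.

Turns raw per-trial head-position time series (t, x, y, z) into the
dependent variables of the two paradigms:

* whole-body approach-avoidance (AAT): initiation RT, peak velocity,
  step size, and a correct/incorrect/missing direction classification;
* interpersonal distance (IPD): stopping distance at the confirm press
  and peak approach velocity.

The extraction chain is resample -> Savitzky-Golay smoothing -> horizontal
speed -> threshold onset detection -> movement segmentation.  All positions
are in meters and seconds internally; results are reported in ms, m/s, cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

AAT = "AAT"
IPD = "IPD"

APPROACH = "approach"
AVOIDANCE = "avoidance"

CORRECT = "correct"
INCORRECT = "incorrect"
MISSING = "missing"


@dataclass
class TrialTrajectory:
    """One trial's time-stamped head positions plus metadata and events.

    Coordinates: x and z span the horizontal plane, y is vertical.
    ``response_end`` is the rating-onset marker for AAT trials and the
    confirm-press marker for IPD trials.
    """

    trial_id: str
    subject_id: str
    avatar_id: str
    experiment: str  # AAT | IPD
    orientation: str  # gynophilic | androphilic
    avatar_sex: str  # female | male
    direction: Optional[str]  # approach | avoidance (AAT only)
    block: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    stimulus_onset: float
    response_end: float
    avatar_x: float
    avatar_z: float
    start_distance: float
    rating: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValueError(f"trial {self.trial_id}: needs >= 2 samples, got {n}")
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError(f"trial {self.trial_id}: coordinate lengths differ")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"trial {self.trial_id}: timestamps not strictly increasing "
                f"at sample {i + 1}"
            )
        if self.experiment not in (AAT, IPD):
            raise ValueError(f"trial {self.trial_id}: unknown experiment {self.experiment!r}")
        if self.stimulus_onset > self.t[0] + 1e-9:
            raise ValueError(
                f"trial {self.trial_id}: stimulus onset {self.stimulus_onset} "
                f"after first sample {self.t[0]}"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class KinematicConfig:
    """Extraction parameters.

    The 10 cm/s sway cutoff (separating body movement from body sway) and
    the 0.10 m/s movement-onset threshold are numerically identical values
    serving two distinct rules; they are kept as separate keys.
    """

    sg_window: int = 11
    sg_order: int = 2
    sway_cutoff: float = 0.10  # m/s
    onset_threshold: float = 0.10  # m/s
    opposite_direction_limit: float = 0.10  # m
    sustain_samples: int = 3
    resample_rate: float = 85.0  # Hz

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        for name in ("sway_cutoff", "onset_threshold", "opposite_direction_limit",
                     "resample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sustain_samples < 1:
            raise ValueError("sustain_samples must be >= 1")


@dataclass
class KinematicResult:
    """Extracted per-trial kinematics (units: ms, m/s, cm)."""

    trial_id: str
    direction_class: str = MISSING
    initiation_rt: float = np.nan  # ms
    peak_velocity: float = np.nan  # m/s
    step_size: float = np.nan  # cm
    movement_start: float = np.nan  # s
    movement_end: float = np.nan  # s
    ipd: float = np.nan  # cm


# ---------------------------------------------------------------------------
# resampling & smoothing
# ---------------------------------------------------------------------------

def resample_uniform(t: np.ndarray, pos: np.ndarray, rate: float):
    """Linearly interpolate samples onto a uniform grid at ``rate`` Hz.

    The grid spans the original time range, starting at the first
    timestamp.  Returns ``(t_uniform, pos_uniform)``.
    """
    t = np.asarray(t, dtype=float)
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    if pos.shape[0] != t.shape[0]:
        pos = pos.T
    if len(t) < 2:
        raise ValueError("resampling needs >= 2 samples")
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be increasing")
    dt = 1.0 / rate
    n = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    tu = t[0] + np.arange(n) * dt
    out = np.column_stack([np.interp(tu, t, pos[:, j]) for j in range(pos.shape[1])])
    return tu, out


def smooth_trajectory(pos: np.ndarray, config: KinematicConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smooth each coordinate (local LSQ polynomial fit).

    Interior points use the full centered window; within half a window of
    either edge the fit window shrinks symmetrically (degree reduced when
    the window is shorter than ``sg_order + 1``).
    """
    config = config or KinematicConfig()
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    squeeze = False
    if pos.shape[0] == 1 and pos.shape[1] > 1:
        pos = pos.T
        squeeze = True
    n = pos.shape[0]
    w, order = config.sg_window, config.sg_order
    if n < w:
        raise ValueError(
            f"series too short for smoothing: {n} samples, need >= {w}"
        )
    out = savgol_filter(pos, window_length=w, polyorder=order, axis=0)
    h = w // 2
    # shrinking symmetric windows at the edges
    for i in range(h):
        for lo, hi, idx in ((0, 2 * i + 1, i), (n - 2 * i - 1, n, n - 1 - i)):
            m = hi - lo
            deg = min(order, m - 1)
            xs = np.arange(m, dtype=float)
            for j in range(pos.shape[1]):
                coef = np.polyfit(xs, pos[lo:hi, j], deg)
                out[idx, j] = np.polyval(coef, idx - lo)
    return out[:, 0] if squeeze else out


def compute_speed(t: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Horizontal (x, z) speed per sample via finite differences.

    Interior samples use central differences, the endpoints one-sided
    differences.  ``pos`` columns are (x, y, z); y is ignored.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    vx = np.gradient(pos[:, 0], t)
    vz = np.gradient(pos[:, 2], t)
    return np.hypot(vx, vz)


# ---------------------------------------------------------------------------
# onset & movement segmentation
# ---------------------------------------------------------------------------

def detect_onset(t: np.ndarray, speed: np.ndarray, stimulus_onset: float,
                 config: KinematicConfig | None = None) -> Optional[float]:
    """Time of the first sustained crossing of the onset threshold.

    A movement is initiated at the first sample after ``stimulus_onset``
    whose speed exceeds the threshold and stays above it for
    ``sustain_samples`` consecutive samples.  Returns ``None`` (missing)
    when no such crossing exists.
    """
    config = config or KinematicConfig()
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    k = config.sustain_samples
    above = speed > config.onset_threshold
    eligible = t >= stimulus_onset - 1e-12
    n = len(t)
    for i in range(n - k + 1):
        if eligible[i] and above[i:i + k].all():
            return float(t[i])
    return None


def _axis_unit(traj: TrialTrajectory, origin: np.ndarray) -> np.ndarray:
    """Unit vector of the subject->avatar horizontal axis."""
    v = np.array([traj.avatar_x - origin[0], traj.avatar_z - origin[1]])
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError(f"trial {traj.trial_id}: subject starts at avatar position")
    return v / nrm


def extract_movement(traj: TrialTrajectory, t: np.ndarray, pos: np.ndarray,
                     speed: np.ndarray, onset: Optional[float],
                     config: KinematicConfig | None = None):
    """Peak velocity, step size and interval of the first movement segment.

    The segment runs from the onset until speed first drops below the sway
    cutoff again (or to the response-end marker when it never does).  Peak
    velocity is the maximum speed in the segment; step size is the absolute
    net displacement over the segment projected onto the subject->avatar
    horizontal axis, in cm.
    """
    config = config or KinematicConfig()
    if onset is None:
        raise ValueError(f"trial {traj.trial_id}: no movement onset")
    i0 = int(np.searchsorted(t, onset - 1e-12))
    end_mask = speed[i0:] < config.sway_cutoff
    if end_mask.any():
        i1 = i0 + int(np.argmax(end_mask))
    else:
        i1 = len(t) - 1
    peak = float(np.max(speed[i0:i1 + 1]))
    horiz = pos[:, [0, 2]]
    origin = horiz[int(np.searchsorted(t, traj.stimulus_onset - 1e-12))]
    axis = _axis_unit(traj, origin)
    disp = float((horiz[i1] - horiz[i0]) @ axis)
    return peak, abs(disp) * 100.0, (float(t[i0]), float(t[i1]))


def classify_direction(traj: TrialTrajectory, t: np.ndarray, pos: np.ndarray,
                       onset: Optional[float],
                       config: KinematicConfig | None = None) -> str:
    """Classify a trial as correct / incorrect / missing.

    Missing: no onset before the rating-onset marker.  Incorrect: the
    signed displacement from the stimulus-onset position (positive toward
    the avatar) ever reaches the opposite-direction limit against the
    instructed direction.  Correct otherwise.
    """
    config = config or KinematicConfig()
    if traj.direction not in (APPROACH, AVOIDANCE):
        raise ValueError(f"trial {traj.trial_id}: unknown instruction {traj.direction!r}")
    if onset is None or onset >= traj.response_end:
        return MISSING
    horiz = pos[:, [0, 2]]
    origin = horiz[int(np.searchsorted(t, traj.stimulus_onset - 1e-12))]
    axis = _axis_unit(traj, origin)
    within = t <= traj.response_end + 1e-12
    signed = (horiz[within] - origin) @ axis
    limit = config.opposite_direction_limit
    if traj.direction == APPROACH:
        wrong = np.min(signed) <= -limit
    else:
        wrong = np.max(signed) >= limit
    return INCORRECT if wrong else CORRECT


def compute_ipd(traj: TrialTrajectory, t: np.ndarray, pos: np.ndarray,
                speed: np.ndarray) -> tuple[float, float]:
    """IPD (cm) at the confirm press and peak approach velocity (m/s)."""
    if traj.experiment != IPD:
        raise ValueError(f"trial {traj.trial_id}: not an IPD trial")
    if traj.response_end is None or not np.isfinite(traj.response_end):
        raise ValueError(f"trial {traj.trial_id}: confirm-press marker absent")
    i = int(np.searchsorted(t, traj.response_end + 1e-12)) - 1
    i = max(i, 0)
    head = pos[i, [0, 2]]
    ipd = float(np.hypot(head[0] - traj.avatar_x, head[1] - traj.avatar_z)) * 100.0
    within = (t >= traj.stimulus_onset - 1e-12) & (t <= traj.response_end + 1e-12)
    peak = float(np.max(speed[within])) if within.any() else np.nan
    return ipd, peak


# ---------------------------------------------------------------------------
# per-trial driver
# ---------------------------------------------------------------------------

def extract_trial(traj: TrialTrajectory,
                  config: KinematicConfig | None = None) -> KinematicResult:
    """Run the full extraction chain on one trial."""
    config = config or KinematicConfig()
    config.validate()
    traj.validate()
    t, pos = resample_uniform(traj.t, traj.positions, config.resample_rate)
    if len(t) >= config.sg_window:
        pos = smooth_trajectory(pos, config)
    speed = compute_speed(t, pos)
    onset = detect_onset(t, speed, traj.stimulus_onset, config)
    res = KinematicResult(trial_id=traj.trial_id)
    if traj.experiment == AAT:
        res.direction_class = classify_direction(traj, t, pos, onset, config)
        if res.direction_class == MISSING:
            return res
        res.initiation_rt = (onset - traj.stimulus_onset) * 1000.0
        peak, step, interval = extract_movement(traj, t, pos, speed, onset, config)
        res.peak_velocity = peak
        res.step_size = step
        res.movement_start, res.movement_end = interval
    else:
        ipd, peak = compute_ipd(traj, t, pos, speed)
        if onset is None or onset >= traj.response_end:
            res.direction_class = MISSING
            return res
        res.direction_class = CORRECT
        res.initiation_rt = (onset - traj.stimulus_onset) * 1000.0
        res.ipd = ipd
        res.peak_velocity = peak
    return res


def trials_to_table(trajectories, results, include_rating: bool = True):
    """Tidy per-trial table of conditions plus extracted DVs (TrialTable)."""
    import pandas as pd

    by_id = {r.trial_id: r for r in results}
    rows = []
    for traj in trajectories:
        r = by_id[traj.trial_id]
        rows.append({
            "trial_id": traj.trial_id,
            "subject_id": traj.subject_id,
            "avatar_id": traj.avatar_id,
            "experiment": traj.experiment,
            "orientation": traj.orientation,
            "avatar_sex": traj.avatar_sex,
            "direction": traj.direction,
            "block": traj.block,
            "rating": traj.rating if include_rating else None,
            "direction_class": r.direction_class,
            "initiation_rt": r.initiation_rt,
            "peak_velocity": r.peak_velocity,
            "step_size": r.step_size,
            "ipd": r.ipd,
        })
    return pd.DataFrame(rows)
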