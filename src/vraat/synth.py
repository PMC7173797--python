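"""Synthetic cohorts of VR approach-avoidance and proxemics trials.

Generates head-tracking trajectories with the statistical structure the
analysis assumes: a cohort of gynophilic and androphilic male subjects, a
set of male and female avatars, a latent sexual-attraction value per
subject-avatar pair (high when the avatar's sex matches the subject's
preferred sex), and per-trial step movements whose onset latency,
amplitude and peak velocity are linear functions of condition codes,
attraction, and crossed subject/avatar random effects.

Trajectories are pre-onset postural sway (low-pass filtered Gaussian
jitter, kept well below the 10 cm/s body-sway cutoff), followed by a
minimum-jerk step with a bell-shaped velocity profile, followed by sway
until the rating-onset (AAT) or confirm-press (IPD) marker.  The full
ground truth of every trial is exported for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import butter, filtfilt

from .kinematics import (AAT, APPROACH, AVOIDANCE, IPD, TrialTrajectory)

GYNOPHILIC = "gynophilic"
ANDROPHILIC = "androphilic"
FEMALE = "female"
MALE = "male"

# effect codes used both by the generator and the default models
ORIENTATION_CODE = {GYNOPHILIC: -0.5, ANDROPHILIC: 0.5}
AVATAR_SEX_CODE = {FEMALE: 0.5, MALE: -0.5}
DIRECTION_CODE = {APPROACH: 0.5, AVOIDANCE: -0.5}

PREFERRED_SEX = {GYNOPHILIC: FEMALE, ANDROPHILIC: MALE}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study design: who is simulated and how often.

    Defaults reproduce the reference design: 72 subjects (48 gynophilic,
    24 androphilic), 20 avatars (10 male, 10 female), 160 AAT trials
    (20 avatars x 2 directions x 4 repetitions) and 40 IPD trials
    (20 avatars x 2 repetitions) per subject, sampled at ~85 Hz.
    """

    n_gynophilic: int = 48
    n_androphilic: int = 24
    n_male_avatars: int = 10
    n_female_avatars: int = 10
    aat_reps_per_mapping: int = 4
    ipd_reps: int = 2
    sample_rate: float = 85.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_gynophilic", "n_androphilic", "n_male_avatars",
                     "n_female_avatars", "aat_reps_per_mapping", "ipd_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def n_subjects(self) -> int:
        return self.n_gynophilic + self.n_androphilic

    @property
    def n_avatars(self) -> int:
        return self.n_male_avatars + self.n_female_avatars

    @property
    def aat_trials_per_subject(self) -> int:
        return self.n_avatars * 2 * self.aat_reps_per_mapping

    @property
    def ipd_trials_per_subject(self) -> int:
        return self.n_avatars * self.ipd_reps


@dataclass
class DVScales:
    """Per-dependent-variable dispersions (log2 ms, cm, m/s, cm)."""

    log2_rt: float
    step: float
    peak_vel: float
    ipd: float

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"dispersion {name} must be >= 0")


@dataclass
class GenerativeParams:
    """Effect sizes and noise scales of the generative model.

    Onset latency is generated on the log2(ms) scale; step size in cm;
    peak velocity in m/s; stopping distance in cm.  Condition codes are
    the +-0.5 effect codes above, so each effect is the full difference
    between the two coded levels.  Latent attraction lives on the 1-5
    rating scale (grand mean 3) and enters the linear predictors centered
    at 3.  Default signs follow the direction of the reference effects;
    every value is overridable.
    """

    # AAT onset latency, log2(ms)
    baseline_log2_rt: float = 9.206  # ~590 ms
    direction_effect: float = -0.10  # approach faster
    attraction_rt_slope: float = -0.01
    attraction_direction_interaction: float = -0.06
    # AAT step amplitude (cm) and peak velocity (m/s)
    baseline_step: float = 53.0
    step_direction_effect: float = 2.9  # forward steps larger
    attraction_step_slope: float = 1.3
    baseline_peak_vel: float = 0.85
    vel_direction_effect: float = 0.02
    attraction_vel_slope: float = 0.012
    # IPD stopping distance (cm)
    baseline_ipd: float = 97.0
    ipd_sex_effect: float = -6.7  # closer to female avatars
    ipd_orientation_effect: float = -13.0  # androphilic closer overall
    ipd_interaction: float = 0.0  # emerges via attraction mediation
    ipd_attraction_slope: float = -3.5
    # latent attraction (rating-scale units)
    attraction_match_shift: float = 0.7
    attraction_pair_sd: float = 0.6
    attraction_trial_sd: float = 0.3
    rating_cutpoints: tuple = (1.5, 2.5, 3.5, 4.5)
    # shared per-subject approach disposition (standard-normal trait):
    # loads on the direction effect of each AAT variable and on the
    # stopping distance, inducing the cross-paradigm correlations
    approach_trait_rt: float = -0.04  # log2(ms) per trait unit on the direction coef
    approach_trait_step: float = 2.5  # cm
    approach_trait_vel: float = 0.02  # m/s
    approach_trait_ipd: float = -7.0  # cm on the IPD intercept
    # crossed random effects and residual noise
    subject_sd: DVScales = field(default_factory=lambda: DVScales(0.15, 6.0, 0.10, 12.0))
    stimulus_sd: DVScales = field(default_factory=lambda: DVScales(0.03, 1.5, 0.02, 4.0))
    residual_sd: DVScales = field(default_factory=lambda: DVScales(0.22, 7.0, 0.10, 9.0))
    # trajectory nuisance processes
    sway_sd: float = 0.002  # m; keeps smoothed sway speed << 10 cm/s
    sway_cutoff_hz: float = 1.5
    timestamp_jitter_sd: float = 0.0005  # s
    step_duration: float | None = None  # fixed step duration override (s)
    # task non-compliance
    p_wrong_direction: float = 0.035
    p_missing: float = 0.002
    p_anticipation: float = 0.05  # premature starts, mostly under the RT floor
    # geometry
    aat_start_distance: float = 1.5  # m
    ipd_start_distance: float = 2.0  # m
    subject_height: float = 1.70  # m

    def validate(self) -> None:
        self.subject_sd.validate()
        self.stimulus_sd.validate()
        self.residual_sd.validate()
        cp = np.asarray(self.rating_cutpoints, dtype=float)
        if len(cp) != 4 or np.any(np.diff(cp) <= 0):
            raise ValueError("rating_cutpoints must be 4 strictly increasing thresholds")
        for name in ("attraction_pair_sd", "attraction_trial_sd", "sway_sd",
                     "timestamp_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_wrong_direction", "p_missing", "p_anticipation"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, v in vars(self).items():
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Injected truth of a simulated cohort, one record per trial."""

    trials: pd.DataFrame
    subject_effects: pd.DataFrame
    stimulus_effects: pd.DataFrame


# ---------------------------------------------------------------------------
# minimum-jerk step primitives
# ---------------------------------------------------------------------------

def min_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_peak_velocity(amplitude: float, duration: float) -> float:
    """Closed-form peak speed of a minimum-jerk step: 15*D/(8*T)."""
    return 15.0 * abs(amplitude) / (8.0 * duration)


def min_jerk_threshold_crossing(amplitude: float, duration: float,
                                threshold: float) -> float:
    """Time after movement start at which speed first exceeds ``threshold``.

    Solves 30*(A/T)*tau^2*(1-tau)^2 = threshold on the rising flank.
    Raises when the step never reaches the threshold.
    """
    peak = min_jerk_peak_velocity(amplitude, duration)
    if peak <= threshold:
        raise ValueError("step never exceeds the speed threshold")
    c = threshold * duration / (30.0 * abs(amplitude))
    tau = brentq(lambda u: (u * (1 - u))**2 - c, 0.0, 0.5)
    return tau * duration


def synthesize_step(t: np.ndarray, start: float, amplitude: float,
                    onset: float, duration: float) -> np.ndarray:
    """Evaluate a 1-D minimum-jerk step along an axis at times ``t``."""
    tau = (np.asarray(t, dtype=float) - onset) / duration
    return start + amplitude * min_jerk_position(tau)


def make_sway(n: int, rate: float, sd: float, rng: np.random.Generator,
              cutoff_hz: float = 1.5) -> np.ndarray:
    """Low-pass filtered Gaussian positional jitter with SD ``sd`` (m).

    With the default cutoff of 1.5 Hz and sd <= ~3 mm, the smoothed speed
    of the sway stays comfortably below the 10 cm/s body-sway cutoff.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    # pad both ends and trim after filtering: filtfilt edge transients
    # would otherwise inject coherent drifts at trial start
    pad = max(64, n // 4)
    white = rng.standard_normal(n + 2 * pad)
    b, a = butter(2, cutoff_hz, fs=rate)
    white = filtfilt(b, a, white)[pad:pad + n]
    s = white.std()
    if s > 0:
        white = white * (sd / s)
    return white


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, params: GenerativeParams):
    """Build subjects, avatars, and the trial-slot skeleton.

    Returns ``(subjects, avatars, slots)`` DataFrames.  Slots carry one
    row per trial to be simulated (AAT and IPD), with condition labels and
    the pair-level latent attraction.  Latent attraction for a pair is
    high iff the avatar's sex matches the subject's preferred sex, plus
    pair-level noise.
    """
    config.validate()
    params.validate()
    rng = np.random.default_rng(config.seed)

    subj_rows = []
    for i in range(config.n_subjects):
        orient = GYNOPHILIC if i < config.n_gynophilic else ANDROPHILIC
        subj_rows.append({
            "subject_id": f"S{i + 1:03d}",
            "orientation": orient,
            "height": params.subject_height + 0.05 * rng.standard_normal(),
        })
    subjects = pd.DataFrame(subj_rows)

    av_rows = []
    for i in range(config.n_avatars):
        sex = MALE if i < config.n_male_avatars else FEMALE
        av_rows.append({"avatar_id": f"A{i + 1:02d}", "avatar_sex": sex})
    avatars = pd.DataFrame(av_rows)

    def _effects(prefix, ids, scales):
        return pd.DataFrame({
            f"{prefix}_id": ids,
            "u_rt": scales.log2_rt * rng.standard_normal(len(ids)),
            "u_step": scales.step * rng.standard_normal(len(ids)),
            "u_vel": scales.peak_vel * rng.standard_normal(len(ids)),
            "u_ipd": scales.ipd * rng.standard_normal(len(ids)),
        })

    subj_eff = _effects("subject", subjects.subject_id, params.subject_sd)
    subj_eff["trait"] = rng.standard_normal(len(subj_eff))
    stim_eff = _effects("avatar", avatars.avatar_id, params.stimulus_sd)

    # pair-level latent attraction on the rating scale
    pair_rows = []
    for _, s in subjects.iterrows():
        pref = PREFERRED_SEX[s.orientation]
        for _, a in avatars.iterrows():
            match = 1.0 if a.avatar_sex == pref else -1.0
            attraction = (3.0 + params.attraction_match_shift * match
                          + params.attraction_pair_sd * rng.standard_normal())
            pair_rows.append({"subject_id": s.subject_id, "avatar_id": a.avatar_id,
                              "pair_attraction": attraction})
    pairs = pd.DataFrame(pair_rows)

    slot_rows = []
    for _, s in subjects.iterrows():
        k = 0
        for _, a in avatars.iterrows():
            for direction in (APPROACH, AVOIDANCE):
                # block 1: approach-female / avoid-male mapping
                block = 1 if ((a.avatar_sex == FEMALE) == (direction == APPROACH)) else 2
                for rep in range(config.aat_reps_per_mapping):
                    k += 1
                    slot_rows.append({
                        "trial_id": f"{s.subject_id}-AAT-{k:04d}",
                        "subject_id": s.subject_id, "avatar_id": a.avatar_id,
                        "experiment": AAT, "orientation": s.orientation,
                        "avatar_sex": a.avatar_sex, "direction": direction,
                        "block": block, "rep": rep + 1,
                    })
        k = 0
        for _, a in avatars.iterrows():
            for rep in range(config.ipd_reps):
                k += 1
                slot_rows.append({
                    "trial_id": f"{s.subject_id}-IPD-{k:04d}",
                    "subject_id": s.subject_id, "avatar_id": a.avatar_id,
                    "experiment": IPD, "orientation": s.orientation,
                    "avatar_sex": a.avatar_sex, "direction": None,
                    "block": 1, "rep": rep + 1,
                })
    slots = pd.DataFrame(slot_rows)
    slots = slots.merge(pairs, on=["subject_id", "avatar_id"], how="left")
    slots = slots.merge(subjects[["subject_id", "height"]], on="subject_id")
    return subjects, avatars, slots, subj_eff, stim_eff


def _rating_from_latent(a: float, cutpoints) -> int:
    return 1 + int(np.sum(a > np.asarray(cutpoints, dtype=float)))


def _sample_times(duration: float, rate: float, jitter_sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    dt = 1.0 / rate
    n = max(int(np.floor(duration / dt)) + 1, 2)
    t = np.arange(n) * dt
    if jitter_sd > 0:
        jit = np.clip(jitter_sd * rng.standard_normal(n), -0.45 * dt, 0.45 * dt)
        jit[0] = 0.0
        t = t + jit
    return t


def simulate_aat_trial(slot, params: GenerativeParams, rng: np.random.Generator,
                       subj_eff, stim_eff, sample_rate: float = 85.0):
    """Simulate one AAT trial: trajectory, rating, and ground truth.

    The trajectory is pre-onset sway, a minimum-jerk step of signed
    amplitude (forward toward the avatar on approach, backward on
    avoidance) and post-movement sway until the rating-onset marker.
    Onset latency is exp2 of a linear predictor on log2(ms).
    """
    d = DIRECTION_CODE[slot["direction"]]
    a_trial = slot["pair_attraction"] + params.attraction_trial_sd * rng.standard_normal()
    ac = a_trial - 3.0
    se = subj_eff.loc[slot["subject_id"]]
    ae = stim_eff.loc[slot["avatar_id"]]

    g = se.trait
    log2_rt = (params.baseline_log2_rt
               + (params.direction_effect + params.approach_trait_rt * g) * d
               + params.attraction_rt_slope * ac
               + params.attraction_direction_interaction * ac * d
               + se.u_rt + ae.u_rt
               + params.residual_sd.log2_rt * rng.standard_normal())
    rt_s = 2.0 ** log2_rt / 1000.0
    if rng.random() < params.p_anticipation:
        rt_s = rng.uniform(0.12, 0.30)  # premature start before the avatar registers

    step_cm = (params.baseline_step
               + (params.step_direction_effect + params.approach_trait_step * g) * d
               + params.attraction_step_slope * ac + se.u_step + ae.u_step
               + params.residual_sd.step * rng.standard_normal())
    step_cm = max(step_cm, 10.0)
    peak_v = (params.baseline_peak_vel
              + (params.vel_direction_effect + params.approach_trait_vel * g) * d
              + params.attraction_vel_slope * ac + se.u_vel + ae.u_vel
              + params.residual_sd.peak_vel * rng.standard_normal())
    peak_v = max(peak_v, 0.30)
    amp = step_cm / 100.0
    if params.step_duration is not None:
        T = params.step_duration
        peak_v = min_jerk_peak_velocity(amp, T)
    else:
        T = 15.0 * amp / (8.0 * peak_v)

    missing = rng.random() < params.p_missing
    wrong = (not missing) and rng.random() < params.p_wrong_direction
    executed = slot["direction"]
    if wrong:
        executed = AVOIDANCE if executed == APPROACH else APPROACH
    sign = 1.0 if executed == APPROACH else -1.0

    dt_cross = min_jerk_threshold_crossing(amp, T, 0.10)
    rt_s = max(rt_s, dt_cross + 0.05)
    move_start = rt_s - dt_cross
    post_delay = rng.uniform(0.35, 0.65)

    if missing:
        rating_onset = rng.uniform(1.2, 2.0)
    else:
        rating_onset = move_start + T + post_delay
    if not missing and T > rating_onset - move_start:
        raise ValueError("step duration longer than trial window")

    t = _sample_times(rating_onset, sample_rate, params.timestamp_jitter_sd, rng)
    z = np.zeros_like(t)
    if not missing:
        z = synthesize_step(t, 0.0, sign * amp, move_start, T)
    x = np.zeros_like(t)
    z = z + make_sway(len(t), sample_rate, params.sway_sd, rng, params.sway_cutoff_hz)
    x = x + make_sway(len(t), sample_rate, params.sway_sd, rng, params.sway_cutoff_hz)
    y = np.full_like(t, slot["height"])

    rating = _rating_from_latent(a_trial, params.rating_cutpoints)
    traj = TrialTrajectory(
        trial_id=slot["trial_id"], subject_id=slot["subject_id"],
        avatar_id=slot["avatar_id"], experiment=AAT,
        orientation=slot["orientation"], avatar_sex=slot["avatar_sex"],
        direction=slot["direction"], block=int(slot["block"]),
        t=t, x=x, y=y, z=z,
        stimulus_onset=0.0, response_end=float(rating_onset),
        avatar_x=0.0, avatar_z=params.aat_start_distance,
        start_distance=params.aat_start_distance, rating=rating,
    )
    truth = {
        "trial_id": slot["trial_id"], "subject_id": slot["subject_id"],
        "avatar_id": slot["avatar_id"], "experiment": AAT,
        "orientation": slot["orientation"], "avatar_sex": slot["avatar_sex"],
        "direction": slot["direction"], "block": int(slot["block"]),
        "attraction": a_trial, "rating": rating,
        "true_rt_ms": np.nan if missing else rt_s * 1000.0,
        "true_step_cm": np.nan if missing else step_cm,
        "true_peak_vel": np.nan if missing else min_jerk_peak_velocity(amp, T),
        "true_stop_cm": np.nan,
        "executed_direction": None if missing else executed,
        "is_missing": missing,
    }
    return traj, truth


def simulate_ipd_trial(slot, params: GenerativeParams, rng: np.random.Generator,
                       subj_eff, stim_eff, sample_rate: float = 85.0):
    """Simulate one IPD trial: forward walk from 200 cm to a stop distance.

    The stop distance is a linear function of the coded avatar sex,
    orientation, their interaction, latent attraction, and crossed random
    effects; non-positive draws are resampled.  A confirm-press marker
    follows the stop.
    """
    cs = AVATAR_SEX_CODE[slot["avatar_sex"]]
    co = ORIENTATION_CODE[slot["orientation"]]
    a_trial = slot["pair_attraction"] + params.attraction_trial_sd * rng.standard_normal()
    ac = a_trial - 3.0
    se = subj_eff.loc[slot["subject_id"]]
    ae = stim_eff.loc[slot["avatar_id"]]

    start = params.ipd_start_distance
    for _ in range(100):
        stop_cm = (params.baseline_ipd + params.ipd_sex_effect * cs
                   + params.ipd_orientation_effect * co
                   + params.ipd_interaction * cs * co
                   + params.ipd_attraction_slope * ac
                   + params.approach_trait_ipd * se.trait
                   + se.u_ipd + ae.u_ipd
                   + params.residual_sd.ipd * rng.standard_normal())
        if 0.0 < stop_cm < (start - 0.2) * 100.0:
            break
    else:
        raise ValueError("could not sample a positive stop distance")

    walk = start - stop_cm / 100.0
    peak_v = (params.baseline_peak_vel
              + params.attraction_vel_slope * ac + se.u_vel + ae.u_vel
              + params.residual_sd.peak_vel * rng.standard_normal())
    peak_v = max(peak_v, 0.30)
    T = 15.0 * walk / (8.0 * peak_v)
    latency = rng.uniform(0.4, 0.8)
    missing = rng.random() < params.p_missing
    if missing:
        confirm = rng.uniform(1.2, 2.0)
    else:
        confirm = latency + T + rng.uniform(0.6, 1.0)

    t = _sample_times(confirm, sample_rate, params.timestamp_jitter_sd, rng)
    z = np.zeros_like(t)
    if not missing:
        z = synthesize_step(t, 0.0, walk, latency, T)
    x = make_sway(len(t), sample_rate, params.sway_sd, rng, params.sway_cutoff_hz)
    z = z + make_sway(len(t), sample_rate, params.sway_sd, rng, params.sway_cutoff_hz)
    y = np.full_like(t, slot["height"])

    rating = _rating_from_latent(a_trial, params.rating_cutpoints)
    traj = TrialTrajectory(
        trial_id=slot["trial_id"], subject_id=slot["subject_id"],
        avatar_id=slot["avatar_id"], experiment=IPD,
        orientation=slot["orientation"], avatar_sex=slot["avatar_sex"],
        direction=None, block=int(slot["block"]),
        t=t, x=x, y=y, z=z,
        stimulus_onset=0.0, response_end=float(confirm),
        avatar_x=0.0, avatar_z=start, start_distance=start, rating=rating,
    )
    truth = {
        "trial_id": slot["trial_id"], "subject_id": slot["subject_id"],
        "avatar_id": slot["avatar_id"], "experiment": IPD,
        "orientation": slot["orientation"], "avatar_sex": slot["avatar_sex"],
        "direction": None, "block": int(slot["block"]),
        "attraction": a_trial, "rating": rating,
        "true_rt_ms": np.nan, "true_step_cm": np.nan,
        "true_peak_vel": np.nan if missing else min_jerk_peak_velocity(walk, T),
        "true_stop_cm": np.nan if missing else stop_cm,
        "executed_direction": None, "is_missing": missing,
    }
    return traj, truth


def iter_cohort_trials(config: CohortConfig, params: GenerativeParams | None = None):
    """Yield ``(TrialTrajectory, truth dict)`` for every trial slot.

    Each trial draws from its own child random stream, so a parameter
    change that alters one trial's trajectory length cannot perturb the
    draws of later trials.  Trajectories can be consumed one at a time
    (the full default cohort holds several million samples).
    """
    params = params or GenerativeParams()
    subjects, avatars, slots, subj_eff, stim_eff = generate_cohort(config, params)
    seeds = np.random.SeedSequence([config.seed, 1]).spawn(len(slots))
    se = subj_eff.set_index("subject_id")
    ae = stim_eff.set_index("avatar_id")
    for slot, seed in zip(slots.to_dict("records"), seeds):
        rng = np.random.default_rng(seed)
        if slot["experiment"] == AAT:
            yield simulate_aat_trial(slot, params, rng, se, ae,
                                     config.sample_rate)
        else:
            yield simulate_ipd_trial(slot, params, rng, se, ae,
                                     config.sample_rate)


def simulate_cohort(config: CohortConfig, params: GenerativeParams | None = None):
    """Simulate a full cohort.

    Returns ``(trajectories, GroundTruth, subjects, avatars)``.  Seeded
    runs are exactly reproducible.
    """
    params = params or GenerativeParams()
    subjects, avatars, _, subj_eff, stim_eff = generate_cohort(config, params)
    trajectories, truths = [], []
    for traj, truth in iter_cohort_trials(config, params):
        trajectories.append(traj)
        truths.append(truth)
    gt = GroundTruth(trials=pd.DataFrame(truths),
                     subject_effects=subj_eff, stimulus_effects=stim_eff)
    return trajectories, gt, subjects, avatars
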