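from types import SimpleNamespace

import numpy as np
import pytest

from vraat.kinematics import extract_trial, trials_to_table
from vraat.synth import (CohortConfig, DVScales, GenerativeParams,
                         simulate_cohort)


def noise_free_params(**overrides) -> GenerativeParams:
    """Generator parameters with every noise source switched off."""
    base = dict(
        sway_sd=0.0, timestamp_jitter_sd=0.0,
        subject_sd=DVScales(0.0, 0.0, 0.0, 0.0),
        stimulus_sd=DVScales(0.0, 0.0, 0.0, 0.0),
        residual_sd=DVScales(0.0, 0.0, 0.0, 0.0),
        attraction_pair_sd=0.0, attraction_trial_sd=0.0,
        approach_trait_rt=0.0, approach_trait_step=0.0,
        approach_trait_vel=0.0, approach_trait_ipd=0.0,
        p_wrong_direction=0.0, p_missing=0.0, p_anticipation=0.0,
    )
    base.update(overrides)
    return GenerativeParams(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort, simulated and extracted once per session."""
    cfg = CohortConfig(n_gynophilic=6, n_androphilic=3, n_male_avatars=2,
                       n_female_avatars=2, aat_reps_per_mapping=2, ipd_reps=2,
                       seed=42)
    trajs, gt, subjects, avatars = simulate_cohort(cfg, GenerativeParams())
    results = [extract_trial(t) for t in trajs]
    table = trials_to_table(trajs, results)
    return SimpleNamespace(config=cfg, trajectories=trajs, truth=gt,
                           subjects=subjects, avatars=avatars, table=table)


@pytest.fixture(scope="session")
def clean_cohort():
    """A noise-free cohort: extracted kinematics must equal ground truth."""
    cfg = CohortConfig(n_gynophilic=2, n_androphilic=2, n_male_avatars=2,
                       n_female_avatars=2, aat_reps_per_mapping=1, ipd_reps=1,
                       seed=7)
    params = noise_free_params()
    trajs, gt, subjects, avatars = simulate_cohort(cfg, params)
    results = [extract_trial(t) for t in trajs]
    table = trials_to_table(trajs, results)
    merged = table.merge(gt.trials, on="trial_id", suffixes=("", "_truth"))
    return SimpleNamespace(config=cfg, params=params, trajectories=trajs,
                           truth=gt, table=table, merged=merged)
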