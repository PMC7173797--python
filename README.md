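# vraat

Whole-body approach–avoidance and interpersonal-distance kinematics in
virtual reality: a tested, reusable analysis pipeline for head-tracking
experiments, with a synthetic-data generator carrying full ground truth.

## The problem

In VR social-cognition experiments, a subject's motivational stance toward a
virtual person shows up in their body: how quickly they initiate a step
toward or away from an avatar (the approach–avoidance task, AAT), how large
and fast that step is, and how close they choose to stand when walking up for
a conversation (interpersonal distance, IPD). Turning raw ~85 Hz head-position
logs into those conclusions takes a long chain of steps — trajectory
smoothing, movement-onset detection, trial exclusion, hierarchical Bayesian
modeling, posterior summarization, and subject-level bias scores — and each
step has conventions that materially change the numbers. `vraat` implements
that chain as a library with every convention explicit, tested against
closed forms and brute-force oracles, and exercised end to end on synthetic
cohorts whose true parameters are known.

It is aimed at researchers in behavioral kinematics / psychophysics who want
a reference implementation of this analysis, want to power-check or validate
a variant of it on simulated data, or want to reanalyze comparable VR
tracking data.

## What it computes

**Kinematics** (per trial, from t/x/y/z samples): Savitzky–Golay smoothing
(window 11, order 2); horizontal speed; initiation RT at the first sustained
crossing of 0.10 m/s; peak velocity and step size over the first movement
segment (ends when speed falls below the 10 cm/s sway cutoff); correct /
incorrect (≥ 10 cm counter to instruction) / missing classification; IPD at
the confirm press.

**Quality control**: drop missing and wrong-direction trials, Tukey fences
(1.5 × IQR) per subject and dependent variable, a 250 ms RT floor, log2 RT —
per-DV exclusion, with stage-wise counts reported.

**Models**: Gaussian hierarchical linear mixed models with ±0.5 effect coding
and full crossing — e.g. for the AAT,

    log2 RT_i = β₀ + β·(orientation × avatar sex × direction)_i
                + u_subj[ i ] · (1, sex_i, dir_i) + u_avatar[ i ] · (1, dir_i) + ε_i

with Normal(0, 1) priors on population effects, Student-t(3, 0, 1) on the
intercept, LKJ(η = 2) on varying-effect correlations (all scaled to the
outcome), sampled by Hamiltonian Monte Carlo with analytic gradients
(4 chains; 8000-iteration paper-faithful profile or 1000-iteration test
profile; split R-hat < 1.1 required, divergences flagged).

**Summaries**: posterior median b̃, shortest 95% HDI, posterior median
p-value pb̃ (share of draws zero or opposite in sign to the median; flagged
when ≤ 2.50%), standardized effect δt = b/√(Σ variance components), Bayesian
R², and posterior-predictive cell contrasts (approach biases per
orientation × avatar-sex cell).

**Bias scores**: per-subject d = (mean avoidance − mean approach)/pooled SD
on RT, peak velocity and step size toward the preferred avatar sex, plus the
cross-paradigm Pearson correlation table with Fisher-z pb̃ flags.

**Synthetic cohorts**: 72 subjects (48 gynophilic / 24 androphilic),
20 avatars, 160 AAT + 40 IPD trials per subject by default; latent
attraction high for preferred-sex avatars drives ratings and all behavioral
effects; trajectories are minimum-jerk steps (closed-form peak velocity
15A/8T) embedded in sub-threshold postural sway; every injected quantity is
exported for recovery testing. See `docs/methods.md` for the full model.

## Worked example

Simulate a 12-subject cohort, extract, QC, fit the implicit RT model and
report (about two minutes):

```python
from vraat import RunConfig, run_pipeline, CohortConfig

cfg = RunConfig(seed=11, out_dir="demo", models=["aat_implicit_rt"],
                cohort=CohortConfig(n_gynophilic=8, n_androphilic=4,
                                    aat_reps_per_mapping=2, ipd_reps=2))
out = run_pipeline(cfg)
print((out / "report.txt").read_text())
```

Output (abridged):

```
[AAT] trial exclusions
  unextractable: 1 of 960 (0.10%)
  incorrect_direction: 28 of 959 (2.92%)
  rt_total (initiation_rt): 44 of 931 (4.73%)

[aat_implicit_rt] posterior summaries (median [95% HDI], pb)
  b_direction: -0.118 [-0.174; -0.065], pb=0.00% *
  approach_bias[gynophilic,female]: -0.091 [-0.164; -0.019], pb=0.69% *
  approach_bias[androphilic,male]: -0.153 [-0.256; -0.061], pb=0.14% *
  bayes_R2_percent: 23.428 [18.512; 27.820], pb=0.00% *

[correlations] subject-level (r, pb; * = pb<2.50%)
  mean_ipd ~ d_rt: r=-0.52
  d_rt ~ d_step_size: r=-0.53
```

Reading it: about 3% of trials were stepped in the wrong direction and were
excluded. The direction coefficient −0.118 on log2 RT means approach steps
were initiated about 2^0.118 ≈ 8% faster than avoidance steps, with
essentially no posterior mass on the other side of zero (pb = 0.00%). The
negative approach-bias contrasts say the model predicts faster approach than
avoidance within every orientation × avatar-sex cell of this simulated
cohort, and subjects with a stronger RT approach bias (larger d_rt) kept
shorter conversation distances (r = −0.52). With only 12 subjects the
generator's three-way interaction is not yet resolvable — that is what the
full-size run in `scripts/acceptance.py` shows.

The same pipeline is scriptable from a shell, stage by stage or at once:

```bash
vraat all --seed 11 --out-dir demo          # or: vraat simulate / extract / qc / fit ...
vraat all --config my_run.yaml --profile paper_faithful
```

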