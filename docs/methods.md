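# Methods

`vraat` analyzes whole-body approach–avoidance (AAT) and interpersonal-distance
(IPD) behavior recorded as head-position time series in virtual reality, and
ships a synthetic-data generator with known ground truth so that every stage of
the analysis can be validated end to end. This note describes the models and
procedures, the choices made where the design was genuinely open, and what the
synthetic data do and do not establish about real recordings.

## Kinematic extraction

Each trial is a time-stamped head trajectory (t, x, y, z; x/z horizontal, y
vertical) from stimulus onset to the rating-onset marker (AAT) or confirm-press
marker (IPD). The extraction chain:

1. **Resampling.** Hardware timestamps are irregular (nominally ~85 Hz), and
   the smoothing filter assumes uniform spacing, so positions are linearly
   interpolated onto a uniform grid at `resample_rate` (default 85 Hz) spanning
   the original time range.
2. **Smoothing.** Savitzky–Golay filter, window 11 samples, polynomial
   degree 2, applied per coordinate. Within half a window of either edge the
   fit window shrinks symmetrically (degree reduced when fewer points than
   degree + 1 remain); the filter therefore reproduces any quadratic exactly,
   everywhere.
3. **Speed.** Magnitude of the horizontal (x, z) velocity by finite
   differences — central differences at interior samples, one-sided at the
   endpoints. Vertical head bob is ignored: steps are horizontal, and the
   projection used by the original task is not stated, so the horizontal plane
   is the defensible minimal choice.
4. **Onset.** A movement is initiated at the first sample whose smoothed speed
   exceeds `onset_threshold` (0.10 m/s) and stays above it for
   `sustain_samples` (3 samples ≈ 35 ms) consecutive samples. The sustain rule
   is our addition: the source convention states only "surpassing a
   threshold", and a bare first-crossing rule fires on noise spikes.
   Initiation RT is onset minus stimulus onset, in ms.
5. **Movement segment.** From the onset, the segment runs until smoothed speed
   first drops back below `sway_cutoff` (0.10 m/s, the body-sway/movement
   separator — numerically identical to the onset threshold but a distinct
   rule, so both are separate config keys), or to the response-end marker if
   it never does. Peak velocity is the maximum speed in the segment. Step
   size is the absolute net displacement from segment start to segment end
   projected onto the subject→avatar horizontal axis, in cm — net
   displacement, not path length (the source is silent; net displacement
   matches "step size" semantics). When two separated movements occur, only
   the first segment is measured. The movement-end criterion itself is our
   construction; the source does not state one.
6. **Direction classification.** Missing if no onset precedes the rating
   marker; incorrect if the signed projected displacement from the
   stimulus-onset position ever reaches ≥ 0.10 m against the instructed
   direction; correct otherwise.
7. **IPD.** Horizontal Euclidean distance between the head at the
   confirm-press and the avatar position, in cm; peak velocity is the maximum
   speed between stimulus onset and confirm. Trials without a supra-threshold
   forward movement before the confirm are missing.

Step size and peak velocity are invariant under rigid rotation of the
horizontal frame (the subject→avatar axis rotates along), which the suite
asserts.

## Trial quality control

The exclusion cascade, in order:

1. drop unextractable (missing) trials;
2. drop incorrect-direction trials;
3. Tukey fences (Q1 − k·IQR, Q3 + k·IQR, k = 1.5; quartiles by linear
   interpolation between order statistics — the convention is not stated in
   the source, this is numpy's default) applied **per subject and per
   dependent variable** over that subject's remaining trials, pooled across
   the four avatar-sex × direction cells. The pooled reading follows the
   phrase "across all combinations"; a per-cell variant is available via
   `aat_grouping="per_cell"`;
4. RT floor: reaction times under 250 ms are additionally excluded (floor
   applied after the fences were computed, matching the narrative order);
5. log2 transform of the surviving RTs (added as a column; no stage ever
   modifies values, stages only flag rows).

Exclusions are per dependent variable: a trial fenced on RT still contributes
its step size. IPD trials are fenced per subject × avatar-sex cell, separately
for IPD and peak velocity. Reported percentages are of the trials still in
play when a stage runs.

## Hierarchical Bayesian models

All models are Gaussian linear mixed models on the trial level with ±0.5
effect coding (orientation: gynophilic −0.5 / androphilic +0.5; avatar sex:
female +0.5 / male −0.5; direction: approach +0.5 / avoidance −0.5) and full
crossing of the population terms:

* **AAT implicit** (per DV: log2 RT, peak velocity, step size):
  orientation × avatar sex × direction; varying intercept plus crossed
  avatar-sex and direction slopes per subject, varying intercept plus
  direction slope per avatar.
* **AAT explicit**: direction × attractiveness rating (raw 1–5 scale centered
  at the midpoint 3); varying intercept plus direction slope per subject and
  per avatar.
* **IPD implicit**: orientation × avatar sex; varying intercept plus
  avatar-sex slope per subject, varying intercept per stimulus. The source
  sentence places an avatar-sex slope "for every subject and stimulus", but
  avatar sex is constant within a stimulus, making a per-stimulus sex slope
  unidentifiable; it lives in the subject block here.
* **IPD explicit**: avatar sex × standardized attractiveness; varying
  structure as in the IPD implicit model. Ratings are standardized only here
  (the explicit AAT model keeps the raw scale), mirroring the source's usage.

Priors, scaled to the outcome's mean and SD (used unscaled when the outcome is
standardized): Normal(0, sd_y) on population effects, Student-t(3, mean_y,
sd_y) on the intercept, half-t(3, 0, sd_y) on every scale parameter, and an
LKJ(η = 2) prior on the Cholesky factor of each varying-effect block's
correlation matrix. Varying slopes are correlated with their block intercept;
the correlation structure is not stated explicitly in the source, but the
cited η = 2 Cholesky prior implies it.

### Sampler

The posterior is sampled by Hamiltonian Monte Carlo written for exactly this
model family: analytic gradients (the correlation-Cholesky transform is
differentiated by forward-mode duals — blocks have at most a handful of
correlation parameters), non-centered varying effects, jittered leapfrog path
lengths, dual-averaging step-size adaptation (target acceptance 0.8), and a
diagonal mass matrix re-estimated once during warmup. Transitions with an
energy error beyond 500 (or non-finite) count as divergent and are rejected.
Convergence is assessed by split Rubin–Gelman R-hat (threshold 1.1) on all
named parameters plus the divergence count; a failing fit is flagged, never
returned as a silent success. The gradient is verified against finite
differences, the sampler against the conjugate-Normal closed form, R-hat
against an independent implementation, and the whole machinery by a
parameter-recovery study (HDI coverage and sign agreement across replicate
fits).

Two sampling profiles exist: `paper_faithful` (4 chains × 8000 iterations,
10% warmup) and `test` (4 chains × 1000 iterations, 10% warmup), switchable
in the run configuration. The test profile is tuned for the desk-scale
problem sizes used in the suite (hundreds of rows); for full-cohort refits
(~10⁴ rows) the acceptance script uses 4 chains × 1400 iterations with
one-third warmup and up to 56 leapfrog steps, because the intercept-level
coefficients ride a correlated ridge with the subject effects that needs
longer trajectories and a better-adapted mass matrix at that scale. With
those settings every full-cohort fit reaches max R-hat ≤ 1.05 with zero
divergences.

## Posterior summaries

* **b̃**: posterior median, in outcome units.
* **95% HDI**: shortest contiguous interval containing 95% of the draws
  (exhaustive-window definition; verified against a brute-force oracle).
* **pb̃**: percentage of draws that are exactly zero or of sign opposite to
  the median (zeros count against the effect — the conservative reading);
  50% by convention when the median is exactly zero. pb̃ ≤ 2.50% is a
  reporting flag, not a filter.
* **δt**: per-draw b divided by the total outcome scale
  √(Σ varying-effect variances + residual variance), summarized by median and
  HDI. The source cites but does not print the formula; summing all variance
  components is the convention adopted here and recorded as an explicit
  assumption. δt is invariant under rescaling of the outcome, which the suite
  checks with an actual refit.
* **Bayesian R²**: per draw, Var(fitted)/(Var(fitted) + σ²), with fitted
  values including the varying effects.
* **Posterior contrasts**: linear combinations of population coefficients
  under the coding map; the approach-bias contrast in an
  orientation × avatar-sex cell is the direction coefficient plus its
  interactions evaluated at the cell codes. With unit weights the machinery
  reproduces the corresponding main-effect summary exactly.

## d-scores and correlations

Per subject and DV, using only post-QC trials toward the preferred avatar sex
(female for gynophilic, male for androphilic subjects):

    d = (mean(avoidance) − mean(approach)) / SD(pooled trials, n−1)

A subject needs at least two trials per direction and a nonzero pooled SD,
otherwise the d-score is absent. Note the deliberate sign asymmetry of the
printed formula: a stronger approach tendency gives d > 0 on RT (approach
faster) but d < 0 on step size (approach steps larger). Consequently, a
stronger approach bias predicts a *positive* correlation between the step
d-score and the preferred-sex IPD under this formula, whereas the source
prints a negative one while narrating "larger approach steps — shorter
distances". The formula is implemented exactly as printed and the
inconsistency is documented here rather than silently resolved by a sign
flip.

Subject-level variables (mean IPD and mean peak velocity toward the preferred
sex, plus the three d-scores) are correlated pairwise (Pearson,
pairwise-complete, at least 5 complete pairs). The pb̃-style reliability flag
on a correlation uses the Fisher-z posterior approximation
ρ ~ N(atanh r, 1/√(n−3)) — deterministic and dependency-free; the source does
not state how its flags were computed.

## Synthetic-data generator

The generator emulates the study design: 72 male subjects (48 gynophilic, 24
androphilic), 20 avatars (10 male, 10 female), 160 AAT trials per subject
(20 avatars × 2 directions × 4 repetitions; block defined by the
direction↔avatar-sex mapping) and 40 IPD trials (2 repetitions), sampled at
85 Hz with small timestamp jitter (SD 0.5 ms). AAT trials start 1.5 m from
the avatar, IPD trials 2.0 m.

**Latent attraction** lives on the rating scale: a subject–avatar pair draws
3 + 0.7·(match) + Normal(0, 0.6), where match is +1 when the avatar's sex is
the subject's preferred sex and −1 otherwise; each trial adds Normal(0, 0.3).
Ratings discretize the trial latent through fixed cutpoints (1.5, 2.5, 3.5,
4.5). Because ratings are noisy, discretized proxies of the latent value,
slopes estimated on ratings are attenuated relative to the injected latent
slopes — the implicit-model interactions that emerge from attraction
mediation therefore need not match the explicit-model coefficients exactly.

**Trial structure.** Log2 onset latency, step amplitude, peak velocity and
stopping distance are linear in the condition codes, centered attraction,
crossed subject/stimulus random effects, and Gaussian residuals. Defaults take
the directions (and roughly the magnitudes) of the reference effects:
baseline log2 RT 9.206 (~590 ms) with direction effect −0.10; baseline step
53 cm with direction effect +2.9; baseline peak velocity 0.85 m/s; baseline
IPD 97 cm with avatar-sex effect −6.7 and orientation effect −13. The
orientation × avatar-sex IPD interaction is injected as 0 and emerges through
attraction mediation (the −3.5 cm per attraction unit slope combined with the
±0.7 match shift yields ≈ +10 cm, the reported order). A standard-normal
per-subject approach-disposition trait loads on all direction effects
(−0.04 log2 ms, +2.5 cm, +0.02 m/s) and on the IPD intercept (−7 cm),
inducing the cross-paradigm subject-level correlations; without it those
correlations would be noise.

**Trajectories.** A trial is pre-onset postural sway, one minimum-jerk step,
and post-movement sway until the rating/confirm marker. The minimum-jerk
profile s(τ) = A(10τ³ − 15τ⁴ + 6τ⁵) is smooth and bell-shaped in velocity
with closed-form peak 15A/(8T), which pins down the generator–extractor round
trip analytically; the step duration is derived from the sampled amplitude
and peak velocity via T = 15A/(8v) (a fixed `step_duration` override exists
for the low-level synthesizer and tests). The sampled onset latency is
defined as the analytic 0.10 m/s crossing time of the step, so noise-free
extraction recovers it to within one sample period. Sway is low-pass filtered
Gaussian position jitter (2nd-order Butterworth, 1.5 Hz cutoff, SD 2 mm,
generated with padding so filter edge transients never leak into the trial);
at SD ≤ 3 mm its speed stays well below the 10 cm/s cutoff, which the suite
verifies over hundreds of segments. Task non-compliance: 3.5% of AAT trials
execute the wrong direction, 0.2% never move, and 5% start prematurely
(120–300 ms), populating the incorrect/missing/RT-floor branches of the QC
cascade at roughly the reported rates (the source's raw noise levels are not
reported, so exclusion rates are matched in the ballpark, not exactly).

**What the generator does not emulate**: gait and balance dynamics (the step
is a single rigid translation profile), head rotation and vertical bob,
controller trajectories, learning/fatigue across trials, and rating response
times. Passing tests therefore establish that the pipeline recovers what the
generative model injects under realistic noise — not that the extraction
thresholds are optimal for real VR tracking data.

## Numerical and degenerate-input conventions

Duplicate timestamps and non-monotone time are rejected with the trial and
line named; series shorter than the smoothing window raise an error naming
the required length; trials listed in the metadata without samples are
surfaced as missing rather than dropped; fewer than 4 finite values leave the
Tukey mask all-true; constant draw vectors give zero-width HDIs; the
generator resamples non-positive stopping distances. Every artifact embeds
the serialized run configuration, its hash and the master seed; with a fixed
seed the entire pipeline is bit-identical across reruns (per-trial child
random streams keep one trial's parameters from perturbing another's draws).

## Known limitations

* The sampler is specialized to the Gaussian LMM family used here; it is not
  a general-purpose probabilistic-programming backend, and extreme
  hierarchical geometries (near-zero group scales with many groups) mix more
  slowly than a Riemannian or NUTS sampler would.
* The `paper_faithful` profile (4 × 8000 iterations) is provided and
  config-switchable but the shipped tests run the reduced profile; at desk
  scale the reduced profile's Monte-Carlo error dominates well below the
  effect sizes of interest.
* Replication against the originally deposited trial data (an RDS image)
  requires the optional `replicate` extra (`pyreadr`) and a manual download;
  the synthetic pipeline never depends on it.
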