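"""File formats, run configuration, and the pipeline driver.

All tables are delimited text (CSV).  A simulated cohort is stored as a
tracking log (``<stem>_tracking.csv``: trial_id, t, x, y, z with a
commented header stating format version, sample rate, units and
coordinate convention) plus a trial-metadata sidecar
(``<stem>_trials.csv``).  Every pipeline artifact directory embeds the
fully serialized run configuration, its hash and the seed, so reruns
with an identical configuration are bit-identical.

The pipeline stages (simulate -> extract -> qc -> fit -> summarize ->
dscores -> report) each read their inputs from and write their outputs
to the artifact directory, so running stages separately equals running
them all at once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import summaries as summaries_mod
from .kinematics import (AAT, IPD, MISSING, KinematicConfig, KinematicResult,
                         TrialTrajectory, extract_trial, trials_to_table)
from .model import (PAPER_FAITHFUL, TEST_PROFILE, ModelSpec, SamplerConfig,
                    VaryingBlock, build_design, fit_model)
from .qc import QCConfig, apply_aat_cascade, apply_ipd_cascade
from .synth import (AVATAR_SEX_CODE, DIRECTION_CODE, ORIENTATION_CODE,
                    CohortConfig, DVScales, GenerativeParams, simulate_cohort)

log = logging.getLogger("vraat")

FORMAT_VERSION = "1.0"

TRIAL_META_COLS = ["trial_id", "subject_id", "avatar_id", "experiment",
                   "orientation", "avatar_sex", "direction", "block",
                   "stimulus_onset", "response_end", "avatar_x", "avatar_z",
                   "start_distance", "rating"]


# ---------------------------------------------------------------------------
# tracking-log format
# ---------------------------------------------------------------------------

def write_tracking_log(trajectories, out_dir, stem: str = "cohort",
                       sample_rate: float = 85.0) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    track_path = out_dir / f"{stem}_tracking.csv"
    meta_path = out_dir / f"{stem}_trials.csv"
    frames, meta_rows = [], []
    for traj in trajectories:
        frames.append(pd.DataFrame({
            "trial_id": traj.trial_id, "t": traj.t,
            "x": traj.x, "y": traj.y, "z": traj.z}))
        meta_rows.append({
            "trial_id": traj.trial_id, "subject_id": traj.subject_id,
            "avatar_id": traj.avatar_id, "experiment": traj.experiment,
            "orientation": traj.orientation, "avatar_sex": traj.avatar_sex,
            "direction": traj.direction if traj.direction is not None else "",
            "block": traj.block, "stimulus_onset": traj.stimulus_onset,
            "response_end": traj.response_end, "avatar_x": traj.avatar_x,
            "avatar_z": traj.avatar_z, "start_distance": traj.start_distance,
            "rating": traj.rating if traj.rating is not None else ""})
    header = (f"# format_version: {FORMAT_VERSION}\n"
              f"# sample_rate_hz: {sample_rate}\n"
              "# units: meters, seconds\n"
              "# coordinates: x,z horizontal (right-handed), y vertical\n")
    with open(track_path, "w") as fh:
        fh.write(header)
        # %.17g guarantees exact float round trips through the text format
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False,
                                                    float_format="%.17g")
    pd.DataFrame(meta_rows, columns=TRIAL_META_COLS).to_csv(
        meta_path, index=False, float_format="%.17g")
    return track_path, meta_path


def read_tracking_log(track_path, meta_path):
    """Read a tracking log; returns ``(trajectories, missing_trial_ids)``.

    Trials listed in the sidecar but without any samples are surfaced in
    ``missing_trial_ids`` rather than dropped silently.  Schema
    violations, orphan trial ids and non-monotone timestamps raise with
    the offending trial and data line.
    """
    track = pd.read_csv(track_path, comment="#", float_precision="round_trip")
    meta = pd.read_csv(meta_path, dtype={"direction": "string", "rating": "Int64"},
                       float_precision="round_trip")
    for col in ("trial_id", "t", "x", "y", "z"):
        if col not in track.columns:
            raise ValueError(f"{track_path}: missing column {col!r}")
    for col in TRIAL_META_COLS:
        if col not in meta.columns:
            raise ValueError(f"{meta_path}: missing column {col!r}")
    known = set(meta.trial_id)
    orphan = set(track.trial_id) - known
    if orphan:
        raise ValueError(f"{track_path}: orphan trial_id(s) {sorted(orphan)[:5]!r}")
    # first data line of each trial for error reporting (header=4 comment
    # lines + 1 column line, 1-based)
    track = track.reset_index().rename(columns={"index": "_row"})
    grouped = {tid: g for tid, g in track.groupby("trial_id", sort=False)}
    trajectories, missing = [], []
    for m in meta.itertuples(index=False):
        g = grouped.get(m.trial_id)
        if g is None or len(g) == 0:
            missing.append(m.trial_id)
            continue
        t = g.t.to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(g._row.iloc[bad[0] + 1]) + 6
            raise ValueError(f"{track_path}: non-monotone timestamp for trial "
                             f"{m.trial_id} at line {line}")
        direction = None if pd.isna(m.direction) or m.direction == "" else str(m.direction)
        rating = None if pd.isna(m.rating) else int(m.rating)
        traj = TrialTrajectory(
            trial_id=m.trial_id, subject_id=m.subject_id, avatar_id=m.avatar_id,
            experiment=m.experiment, orientation=m.orientation,
            avatar_sex=m.avatar_sex, direction=direction, block=int(m.block),
            t=t, x=g.x.to_numpy(), y=g.y.to_numpy(), z=g.z.to_numpy(),
            stimulus_onset=float(m.stimulus_onset),
            response_end=float(m.response_end),
            avatar_x=float(m.avatar_x), avatar_z=float(m.avatar_z),
            start_distance=float(m.start_distance), rating=rating)
        traj.validate()
        trajectories.append(traj)
    return trajectories, missing


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_MODELS = ["aat_implicit_rt", "aat_explicit_rt",
                  "ipd_implicit_ipd", "ipd_explicit_ipd"]


@dataclass
class RunConfig:
    seed: int = 1
    profile: str = "test"  # test | paper_faithful
    out_dir: str = "vraat_out"
    models: list = field(default_factory=lambda: list(DEFAULT_MODELS))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    params: GenerativeParams = field(default_factory=GenerativeParams)
    kinematics: KinematicConfig = field(default_factory=KinematicConfig)
    qc: QCConfig = field(default_factory=QCConfig)

    def validate(self) -> None:
        if self.profile not in ("test", "paper_faithful"):
            raise ValueError(f"unknown profile {self.profile!r}")
        self.cohort.validate()
        self.params.validate()
        self.kinematics.validate()
        self.qc.validate()
        for m in self.models:
            make_model_spec(m)  # raises on unknown names

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where artifacts land is not part of the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data)}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)!r} for {cls.__name__}")
    kwargs = {}
    for k, v in data.items():
        ftype = fields[k].type
        if k in ("cohort", "params", "kinematics", "qc"):
            sub = {"cohort": CohortConfig, "params": GenerativeParams,
                   "kinematics": KinematicConfig, "qc": QCConfig}[k]
            kwargs[k] = _from_dict(sub, v)
        elif isinstance(v, dict) and k in ("subject_sd", "stimulus_sd", "residual_sd"):
            kwargs[k] = _from_dict(DVScales, v)
        elif k == "rating_cutpoints":
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

OUTCOME_DVS = {"rt": ("initiation_rt", "log2_rt"),
               "peak_velocity": ("peak_velocity", "peak_velocity"),
               "step_size": ("step_size", "step_size"),
               "ipd": ("ipd", "ipd")}


def make_model_spec(name: str, profile: str = "test", seed: int = 0) -> ModelSpec:
    """Build one of the named model specifications.

    Names: ``{aat_implicit,aat_explicit}_{rt,peak_velocity,step_size}``
    and ``{ipd_implicit,ipd_explicit}_{ipd,peak_velocity}``.
    """
    parts = name.split("_")
    exp, kind, short = parts[0], parts[1], "_".join(parts[2:])
    sampler = dataclasses.replace(
        PAPER_FAITHFUL if profile == "paper_faithful" else TEST_PROFILE,
        seed=seed)
    if exp == "aat" and short in ("rt", "peak_velocity", "step_size"):
        dv, outcome = OUTCOME_DVS[short]
        if kind == "implicit":
            return ModelSpec(
                name=name, outcome=outcome,
                factors={"orientation": ORIENTATION_CODE,
                         "avatar_sex": AVATAR_SEX_CODE,
                         "direction": DIRECTION_CODE},
                varying=[VaryingBlock("subject_id", slopes=("avatar_sex", "direction")),
                         VaryingBlock("avatar_id", slopes=("direction",))],
                sampler=sampler)
        if kind == "explicit":
            return ModelSpec(
                name=name, outcome=outcome,
                factors={"direction": DIRECTION_CODE},
                covariates={"rating": ("centered", 3.0)},
                varying=[VaryingBlock("subject_id", slopes=("direction",)),
                         VaryingBlock("avatar_id", slopes=("direction",))],
                sampler=sampler)
    if exp == "ipd" and short in ("ipd", "peak_velocity"):
        dv, outcome = OUTCOME_DVS[short]
        if kind == "implicit":
            return ModelSpec(
                name=name, outcome=outcome,
                factors={"orientation": ORIENTATION_CODE,
                         "avatar_sex": AVATAR_SEX_CODE},
                varying=[VaryingBlock("subject_id", slopes=("avatar_sex",)),
                         VaryingBlock("avatar_id")],
                sampler=sampler)
        if kind == "explicit":
            return ModelSpec(
                name=name, outcome=outcome,
                factors={"avatar_sex": AVATAR_SEX_CODE},
                covariates={"rating": "standardized"},
                varying=[VaryingBlock("subject_id", slopes=("avatar_sex",)),
                         VaryingBlock("avatar_id")],
                sampler=sampler)
    raise ValueError(f"unknown model name {name!r}")


def model_table(name: str, aat_table: pd.DataFrame,
                ipd_table: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for a named model (per-DV keep flags honored)."""
    parts = name.split("_")
    exp, short = parts[0], "_".join(parts[2:])
    dv, outcome = OUTCOME_DVS[short]
    t = aat_table if exp == "aat" else ipd_table
    keep_col = f"keep_{dv}"
    if keep_col in t.columns:
        t = t[t[keep_col]]
    return t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def write_provenance(cfg: RunConfig) -> None:
    out = _out(cfg)
    d = cfg.to_dict()
    d.pop("out_dir", None)  # self-evident, and kept out of the hash
    with open(out / "run_config.json", "w") as fh:
        json.dump({"config": d, "config_hash": cfg.config_hash(),
                   "seed": cfg.seed}, fh, indent=2, default=str)


def stage_simulate(cfg: RunConfig) -> None:
    cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
    trajs, gt, subjects, avatars = simulate_cohort(cohort, cfg.params)
    out = _out(cfg)
    write_tracking_log(trajs, out, "cohort", cohort.sample_rate)
    gt.trials.to_csv(out / "ground_truth.csv", index=False)
    gt.subject_effects.to_csv(out / "ground_truth_subject_effects.csv", index=False)
    gt.stimulus_effects.to_csv(out / "ground_truth_stimulus_effects.csv", index=False)
    subjects.to_csv(out / "subjects.csv", index=False)
    avatars.to_csv(out / "avatars.csv", index=False)
    log.info("simulate: %d trials written", len(trajs))


def stage_extract(cfg: RunConfig) -> None:
    out = _out(cfg)
    trajs, missing = read_tracking_log(out / "cohort_tracking.csv",
                                       out / "cohort_trials.csv")
    results = [extract_trial(tr, cfg.kinematics) for tr in trajs]
    table = trials_to_table(trajs, results)
    if missing:
        meta = pd.read_csv(out / "cohort_trials.csv")
        gone = meta[meta.trial_id.isin(missing)]
        stub = pd.DataFrame({"trial_id": gone.trial_id,
                             "subject_id": gone.subject_id,
                             "avatar_id": gone.avatar_id,
                             "experiment": gone.experiment,
                             "orientation": gone.orientation,
                             "avatar_sex": gone.avatar_sex,
                             "direction": gone.direction,
                             "block": gone.block, "rating": gone.rating,
                             "direction_class": MISSING})
        table = pd.concat([table, stub], ignore_index=True)
    table.to_csv(out / "trial_table_raw.csv", index=False)
    log.info("extract: %d trials (%d with no samples)", len(table), len(missing))


def stage_qc(cfg: RunConfig) -> None:
    out = _out(cfg)
    raw = pd.read_csv(out / "trial_table_raw.csv")
    aat_raw = raw[raw.experiment == AAT]
    ipd_raw = raw[raw.experiment == IPD]
    aat, rep_a = apply_aat_cascade(aat_raw, cfg.qc)
    ipd, rep_i = apply_ipd_cascade(ipd_raw, cfg.qc)
    aat.to_csv(out / "aat_table.csv", index=False)
    ipd.to_csv(out / "ipd_table.csv", index=False)
    with open(out / "exclusions.json", "w") as fh:
        json.dump({"AAT": rep_a.to_dict(), "IPD": rep_i.to_dict()}, fh, indent=2)
    for rep in (rep_a, rep_i):
        for st in rep.stages:
            log.info("qc %s %s/%s: %d of %d (%.2f%%)", rep.experiment,
                     st["stage"], st["dv"], st["excluded"], st["of"], st["percent"])


def _draws_frame(post) -> pd.DataFrame:
    """Named posterior draws plus per-draw fitted variance, long over
    chain x draw (the persisted posterior artifact)."""
    named = post.population + post.sd_labels + post.cor_labels + ["sigma"]
    c, n, _ = post.array.shape
    data = {"chain": np.repeat(np.arange(c), n),
            "draw": np.tile(np.arange(n), c)}
    for lab in named:
        data[lab] = post.get(lab).reshape(-1)
    data["fitted_variance"] = post.fitted_variance_draws()
    return pd.DataFrame(data)


def stage_fit(cfg: RunConfig) -> None:
    out = _out(cfg)
    aat = pd.read_csv(out / "aat_table.csv")
    ipd = pd.read_csv(out / "ipd_table.csv")
    for i, name in enumerate(cfg.models):
        spec = make_model_spec(name, cfg.profile, seed=cfg.seed * 100 + i)
        table = model_table(name, aat, ipd)
        design = build_design(table, spec)
        post = fit_model(design, spec)
        _draws_frame(post).to_csv(out / f"draws_{name}.csv", index=False)
        conv = {"model": name, "n_rows": design.n,
                "divergences": int(post.divergences.sum()),
                "max_rhat": float(post.convergence.rhat.max()),
                "converged": bool(post.converged),
                "mean_accept": float(post.accept.mean())}
        with open(out / f"convergence_{name}.json", "w") as fh:
            json.dump(conv, fh, indent=2)
        if not post.converged:
            log.warning("fit %s: NOT converged (max R-hat %.3f, %d divergences)",
                        name, conv["max_rhat"], conv["divergences"])
        else:
            log.info("fit %s: converged (max R-hat %.3f)", name, conv["max_rhat"])


def summarize_draws_frame(draws: pd.DataFrame, model_name: str) -> pd.DataFrame:
    """Effect summaries, Bayesian R^2 and (for implicit AAT models) the
    four approach-bias cell contrasts, from a persisted draws table."""
    pop = [c for c in draws.columns if c.startswith("b_")]
    sds = [c for c in draws.columns if c.startswith("sd_")]
    tot = np.sqrt(sum(draws[c].to_numpy() ** 2 for c in sds)
                  + draws["sigma"].to_numpy() ** 2)
    rows = [summaries_mod.summarize_draws(draws[c].to_numpy(), c, tot).to_dict()
            for c in pop]
    if model_name.startswith("aat_implicit"):
        for olab, oc in ORIENTATION_CODE.items():
            for slab, sc in AVATAR_SEX_CODE.items():
                w = {"b_direction": 1.0, "b_orientation:direction": oc,
                     "b_avatar_sex:direction": sc,
                     "b_orientation:avatar_sex:direction": oc * sc}
                d = sum(v * draws[k].to_numpy() for k, v in w.items()
                        if k in draws.columns)
                rows.append(summaries_mod.summarize_draws(
                    d, f"approach_bias[{olab},{slab}]", tot).to_dict())
    r2 = draws["fitted_variance"].to_numpy() / (
        draws["fitted_variance"].to_numpy() + draws["sigma"].to_numpy() ** 2)
    rows.append(summaries_mod.summarize_draws(100.0 * r2, "bayes_R2_percent").to_dict())
    df = pd.DataFrame(rows)
    df.insert(0, "model", model_name)
    return df


def stage_summarize(cfg: RunConfig) -> None:
    out = _out(cfg)
    frames = []
    for name in cfg.models:
        draws = pd.read_csv(out / f"draws_{name}.csv")
        frames.append(summarize_draws_frame(draws, name))
    pd.concat(frames, ignore_index=True).to_csv(out / "effect_summaries.csv",
                                                index=False)


def stage_dscores(cfg: RunConfig) -> None:
    out = _out(cfg)
    aat = pd.read_csv(out / "aat_table.csv")
    ipd = pd.read_csv(out / "ipd_table.csv")
    ds = bias_mod.subject_dscores(aat)
    ag = bias_mod.subject_aggregates(ipd)
    ds.to_csv(out / "dscores.csv", index=False)
    ag.to_csv(out / "ipd_aggregates.csv", index=False)
    merged = ag.merge(ds, on="subject_id", how="outer")
    cols = merged[["subject_id", "mean_ipd", "mean_peak_velocity",
                   "d_rt", "d_peak_velocity", "d_step_size"]]
    bias_mod.correlation_table(cols).to_csv(out / "correlations.csv", index=False)


def stage_report(cfg: RunConfig) -> None:
    out = _out(cfg)
    lines = [f"vraat pipeline report (profile={cfg.profile}, seed={cfg.seed}, "
             f"config={cfg.config_hash()})", ""]
    with open(out / "exclusions.json") as fh:
        excl = json.load(fh)
    for exp, rep in excl.items():
        lines.append(f"[{exp}] trial exclusions")
        for st in rep["stages"]:
            dv = f" ({st['dv']})" if st["dv"] else ""
            lines.append(f"  {st['stage']}{dv}: {st['excluded']} of {st['of']} "
                         f"({st['percent']:.2f}%)")
        lines.append("")
    summ = pd.read_csv(out / "effect_summaries.csv")
    for name, sub in summ.groupby("model", sort=False):
        lines.append(f"[{name}] posterior summaries (median [95% HDI], pb)")
        for r in sub.itertuples(index=False):
            star = " *" if r.flagged else ""
            lines.append(f"  {r.parameter}: {r.median:.3f} "
                         f"[{r.hdi_low:.3f}; {r.hdi_high:.3f}], "
                         f"pb={r.pb_percent:.2f}%{star}")
        lines.append("")
    corr = pd.read_csv(out / "correlations.csv")
    lines.append("[correlations] subject-level (r, pb; * = pb<2.50%)")
    for r in corr.itertuples(index=False):
        star = " *" if r.flagged else ""
        rtxt = "NA" if not np.isfinite(r.r) else f"{r.r:.2f}"
        lines.append(f"  {r.var_a} ~ {r.var_b}: r={rtxt}{star}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


STAGES = {"simulate": stage_simulate, "extract": stage_extract,
          "qc": stage_qc, "fit": stage_fit, "summarize": stage_summarize,
          "dscores": stage_dscores, "report": stage_report}


def run_pipeline(cfg: RunConfig, stages=None) -> Path:
    """Run the pipeline (all stages by default); returns the artifact dir.

    A stage failure aborts with the stage name; artifacts written by
    earlier stages are preserved.
    """
    cfg.validate()
    write_provenance(cfg)
    for name in (stages or list(STAGES)):
        try:
            STAGES[name](cfg)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    return _out(cfg)


def read_s1_data(path):
    """Ingest the deposited trial-level dataframes (RDS image) for a
    replication run.  Requires the optional ``pyreadr`` extra; never used
    by the synthetic pipeline or the tests."""
    try:
        import pyreadr
    except ImportError as exc:
        raise ImportError(
            "reading the deposited RDS data requires the 'replicate' extra "
            "(pip install vraat[replicate])") from exc
    return pyreadr.read_r(str(path))
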