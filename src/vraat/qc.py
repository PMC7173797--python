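"""Trial quality control: exclusion cascade and transforms.

The cascade mirrors the analysis conventions of the whole-body
approach-avoidance literature: drop unextractable trials, drop trials
initiated in the wrong direction, fence outliers per subject and
dependent variable with the Tukey criterion, apply an RT floor, and
log2-transform reaction times.  Exclusions are per-DV: a trial fenced on
RT stays available for step size and peak velocity.  Stages never modify
values, they only flag rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import CORRECT, INCORRECT, MISSING

AAT_DVS = ("initiation_rt", "peak_velocity", "step_size")
IPD_DVS = ("ipd", "peak_velocity")


@dataclass
class QCConfig:
    tukey_k: float = 1.5
    rt_floor_ms: float = 250.0
    aat_grouping: str = "pooled_within_subject"  # or "per_cell"
    ipd_grouping: str = "subject_by_avatar_sex"
    log2_rt: bool = True

    def validate(self) -> None:
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be > 0")
        if self.rt_floor_ms < 0:
            raise ValueError("rt_floor_ms must be >= 0")
        if self.aat_grouping not in ("pooled_within_subject", "per_cell"):
            raise ValueError(f"unknown aat_grouping {self.aat_grouping!r}")
        if self.ipd_grouping != "subject_by_avatar_sex":
            raise ValueError(f"unknown ipd_grouping {self.ipd_grouping!r}")


@dataclass
class ExclusionReport:
    """Stage-wise exclusion counts; percentages are of the trials still in
    play when the stage runs (matching the convention 'x% of the
    remaining trials')."""

    experiment: str
    stages: list = field(default_factory=list)

    def add(self, stage: str, dv: str | None, excluded: int, remaining_before: int):
        pct = 100.0 * excluded / remaining_before if remaining_before else 0.0
        self.stages.append({
            "stage": stage, "dv": dv, "excluded": int(excluded),
            "of": int(remaining_before), "percent": pct,
        })

    def to_dict(self) -> dict:
        return {"experiment": self.experiment, "stages": self.stages}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def tukey_mask(values, k: float = 1.5) -> np.ndarray:
    """Keep-mask under the Tukey fence criterion.

    Keep iff Q1 - k*IQR <= v <= Q3 + k*IQR, quartiles by linear
    interpolation between order statistics.  Fewer than 4 values: all
    kept.  Non-finite values are rejected with an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size and not np.all(np.isfinite(v)):
        raise ValueError("tukey_mask requires finite values")
    if v.size < 4:
        return np.ones(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


def _tukey_flag(df: pd.DataFrame, dv: str, group_cols: list, k: float) -> pd.Series:
    keep = pd.Series(True, index=df.index)
    for _, idx in df.groupby(group_cols, sort=False).groups.items():
        keep.loc[idx] = tukey_mask(df.loc[idx, dv].to_numpy(), k)
    return keep


def apply_aat_cascade(table: pd.DataFrame, config: QCConfig | None = None):
    """Run the AAT exclusion cascade.

    Order: drop missing -> drop incorrect-direction -> per subject and DV,
    Tukey fences across that subject's remaining trials (pooled over the
    four avatar-sex x direction cells by default) -> RT floor (RT only)
    -> add a log2 RT column.  Returns ``(TrialTable, ExclusionReport)``
    where the table keeps one row per surviving trial with per-DV
    ``keep_<dv>`` flags.
    """
    config = config or QCConfig()
    config.validate()
    for dv in AAT_DVS:
        if dv not in table.columns:
            raise ValueError(f"missing dependent variable column {dv!r}")
    report = ExclusionReport(experiment="AAT")
    n0 = len(table)

    t = table[table.direction_class != MISSING].copy()
    report.add("unextractable", None, n0 - len(t), n0)

    n1 = len(t)
    t = t[t.direction_class == CORRECT].copy()
    report.add("incorrect_direction", None, n1 - len(t), n1)

    n2 = len(t)
    if config.aat_grouping == "pooled_within_subject":
        groups = ["subject_id"]
    else:
        groups = ["subject_id", "avatar_sex", "direction"]
    for dv in AAT_DVS:
        t[f"keep_{dv}"] = _tukey_flag(t, dv, groups, config.tukey_k)
        report.add("tukey", dv, int((~t[f"keep_{dv}"]).sum()), n2)

    floor_hits = t.keep_initiation_rt & (t.initiation_rt < config.rt_floor_ms)
    t.loc[floor_hits, "keep_initiation_rt"] = False
    report.add("rt_floor", "initiation_rt", int(floor_hits.sum()), n2)
    report.add("rt_total", "initiation_rt",
               int((~t.keep_initiation_rt).sum()), n2)

    if config.log2_rt:
        t["log2_rt"] = np.log2(t.initiation_rt)
    return t, report


def apply_ipd_cascade(table: pd.DataFrame, config: QCConfig | None = None):
    """Run the IPD exclusion cascade.

    Drop trials without a forward movement, then Tukey-fence IPD and peak
    velocity separately for each subject and level of avatar sex.
    """
    config = config or QCConfig()
    config.validate()
    for dv in IPD_DVS:
        if dv not in table.columns:
            raise ValueError(f"missing dependent variable column {dv!r}")
    report = ExclusionReport(experiment="IPD")
    n0 = len(table)

    t = table[table.direction_class != MISSING].copy()
    report.add("unextractable", None, n0 - len(t), n0)

    n1 = len(t)
    for dv in IPD_DVS:
        t[f"keep_{dv}"] = _tukey_flag(t, dv, ["subject_id", "avatar_sex"],
                                      config.tukey_k)
        report.add("tukey", dv, int((~t[f"keep_{dv}"]).sum()), n1)
    return t, report
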