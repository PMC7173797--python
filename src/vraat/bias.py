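"""Approach-bias d-scores and the cross-paradigm correlation table.

A d-score standardizes, per subject and dependent variable, the
difference between avoidance and approach trials toward the subject's
preferred avatar sex: d = (mean(avoidance) - mean(approach)) / SD of the
pooled trials.  Subject-level d-scores from the approach-avoidance task
are then correlated with the subject's mean interpersonal distance and
mean approach peak velocity toward the preferred sex.

Note on the sign convention: the formula is implemented exactly as
stated (avoidance minus approach).  For RT a positive d means faster
approach than avoidance; for step size a positive d means *smaller*
approach steps -- so a stronger approach tendency raises d on RT but
lowers it on step size.  This asymmetry is deliberate and covered by a
regression test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinematics import APPROACH, AVOIDANCE
from .synth import PREFERRED_SEX

PB_FLAG_THRESHOLD = 2.50

AAT_DSCORE_DVS = {"rt": "initiation_rt", "peak_velocity": "peak_velocity",
                  "step_size": "step_size"}


def d_score(approach_values, avoidance_values) -> float:
    """(mean(avoidance) - mean(approach)) / pooled sample SD.

    Returns NaN when either side has fewer than 2 trials or the pooled
    SD is zero.
    """
    a = np.asarray(approach_values, dtype=float)
    b = np.asarray(avoidance_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return np.nan
    pooled = np.concatenate([a, b])
    sd = pooled.std(ddof=1)
    if sd == 0:
        return np.nan
    return float((b.mean() - a.mean()) / sd)


def subject_dscores(aat_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject d-scores on RT, peak velocity and step size.

    Uses only post-QC trials toward the subject's preferred avatar sex
    (female for gynophilic, male for androphilic subjects), honoring the
    per-DV keep flags.
    """
    rows = []
    for subject, sub in aat_table.groupby("subject_id", sort=True):
        pref = PREFERRED_SEX[sub.orientation.iloc[0]]
        sub = sub[sub.avatar_sex == pref]
        row = {"subject_id": subject, "orientation": sub.orientation.iloc[0] if len(sub) else None}
        for short, dv in AAT_DSCORE_DVS.items():
            keep = sub[f"keep_{dv}"] if f"keep_{dv}" in sub else pd.Series(True, index=sub.index)
            vals = sub[keep]
            row[f"d_{short}"] = d_score(
                vals.loc[vals.direction == APPROACH, dv],
                vals.loc[vals.direction == AVOIDANCE, dv])
        rows.append(row)
    return pd.DataFrame(rows)


def subject_aggregates(ipd_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean IPD and mean peak velocity toward the preferred sex
    (post-QC trials only; subjects with no eligible trials are absent)."""
    rows = []
    for subject, sub in ipd_table.groupby("subject_id", sort=True):
        pref = PREFERRED_SEX[sub.orientation.iloc[0]]
        sub = sub[sub.avatar_sex == pref]
        if not len(sub):
            continue
        keep_i = sub["keep_ipd"] if "keep_ipd" in sub else pd.Series(True, index=sub.index)
        keep_v = sub["keep_peak_velocity"] if "keep_peak_velocity" in sub else pd.Series(True, index=sub.index)
        if not keep_i.any() and not keep_v.any():
            continue
        rows.append({
            "subject_id": subject,
            "mean_ipd": sub.loc[keep_i, "ipd"].mean() if keep_i.any() else np.nan,
            "mean_peak_velocity": (sub.loc[keep_v, "peak_velocity"].mean()
                                   if keep_v.any() else np.nan),
        })
    return pd.DataFrame(rows)


def correlation_pb(r: float, n: int) -> float:
    """pb (percent) of a Pearson r via the Fisher-z posterior
    approximation: rho ~ N(atanh(r), 1/sqrt(n-3))."""
    if n <= 3 or not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    z = np.arctanh(r)
    return 100.0 * float(norm.cdf(-abs(z) * np.sqrt(n - 3)))


def correlation_table(subject_vars: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Pairwise Pearson correlations with the pb reliability flag.

    Pairwise-complete observations; a pair with fewer than ``min_n``
    complete rows or a constant column yields an absent (NaN) r.
    """
    cols = [c for c in subject_vars.columns if c != "subject_id"
            and pd.api.types.is_numeric_dtype(subject_vars[c])]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = subject_vars[[a, b]].dropna()
            n = len(sub)
            if n < min_n or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r = np.nan
            else:
                r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            pb = correlation_pb(r, n)
            rows.append({"var_a": a, "var_b": b, "n": n, "r": r,
                         "pb_percent": pb,
                         "flagged": bool(pb < PB_FLAG_THRESHOLD)
                         if np.isfinite(pb) else False})
    return pd.DataFrame(rows)
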