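"""Posterior summaries: median, 95% HDI, posterior median p-value (pb),
standardized effect size (delta_t), Bayesian R^2, and posterior-predictive
cell contrasts.

pb is the percentage of posterior draws that are zero or of sign opposite
to the posterior median -- the Bayesian analogue of a two-sided p-value;
effects with pb <= 2.5% are flagged as reliable (a reporting flag, never a
hard filter).  delta_t standardizes a coefficient by the total outcome
scale, sqrt(sum of varying-effect variances + residual variance), making
it comparable to Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws

PB_FLAG_THRESHOLD = 2.50  # percent


@dataclass
class EffectSummary:
    label: str
    median: float
    hdi_low: float
    hdi_high: float
    pb: float  # percent
    delta_t_median: float = np.nan
    delta_t_low: float = np.nan
    delta_t_high: float = np.nan

    @property
    def flagged(self) -> bool:
        return self.pb <= PB_FLAG_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "parameter": self.label, "median": self.median,
            "hdi_low": self.hdi_low, "hdi_high": self.hdi_high,
            "pb_percent": self.pb, "delta_t": self.delta_t_median,
            "delta_t_low": self.delta_t_low, "delta_t_high": self.delta_t_high,
            "flagged": self.flagged,
        }


def pb_value(draws) -> float:
    """Posterior median p-value in percent.

    The share of draws that are exactly zero or of sign opposite to the
    sign of the posterior median; 50 by convention when the median is 0.
    """
    v = np.asarray(draws, dtype=float)
    if v.size == 0:
        raise ValueError("pb_value needs at least one draw")
    med = np.median(v)
    if med == 0:
        return 50.0
    if med > 0:
        return 100.0 * float(np.mean(v <= 0))
    return 100.0 * float(np.mean(v >= 0))


def hdi95(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the draws."""
    v = np.sort(np.asarray(draws, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("hdi95 needs draws")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(v[0]), float(v[-1])
    widths = v[m - 1:] - v[:n - m + 1]
    i = int(np.argmin(widths))
    return float(v[i]), float(v[i + m - 1])


def delta_t(effect_draws, total_sd_draws) -> np.ndarray:
    """Standardized-effect draws: b / total outcome SD, per draw."""
    b = np.asarray(effect_draws, dtype=float)
    s = np.asarray(total_sd_draws, dtype=float)
    if b.shape != s.shape:
        raise ValueError("effect and scale draws must be aligned")
    if np.any(s <= 0):
        raise ValueError("total SD draws must be positive")
    return b / s


def summarize_draws(draws, label: str = "",
                    total_sd_draws=None) -> EffectSummary:
    v = np.asarray(draws, dtype=float)
    lo, hi = hdi95(v)
    out = EffectSummary(label=label, median=float(np.median(v)),
                        hdi_low=lo, hdi_high=hi, pb=pb_value(v))
    if total_sd_draws is not None:
        dt = delta_t(v, total_sd_draws)
        dlo, dhi = hdi95(dt)
        out.delta_t_median = float(np.median(dt))
        out.delta_t_low, out.delta_t_high = dlo, dhi
    return out


def effect_summaries(post: PosteriorDraws) -> pd.DataFrame:
    """EffectSummary table for every population-level parameter."""
    tot = post.total_sd_draws()
    rows = [summarize_draws(post.stacked(lab), lab, tot).to_dict()
            for lab in post.population]
    return pd.DataFrame(rows)


def bayes_r2(post: PosteriorDraws) -> np.ndarray:
    """Per-draw Bayesian R^2: Var(fitted) / (Var(fitted) + sigma^2)."""
    var_fit = post.fitted_variance_draws()
    sig2 = post.stacked("sigma") ** 2
    return var_fit / (var_fit + sig2)


def posterior_contrast(post: PosteriorDraws, weights: dict,
                       label: str = "contrast") -> EffectSummary:
    """Summary of a linear combination of population coefficients.

    ``weights`` maps population-term names (as in the design, e.g.
    "direction" or "orientation:avatar_sex") to contrast weights.
    """
    unknown = [k for k in weights
               if f"b_{k}" not in post.population and k not in post.population]
    if unknown:
        raise ValueError(f"contrast references absent term(s) {unknown!r}")
    draws = np.zeros(post.array.shape[0] * post.array.shape[1])
    for k, w in weights.items():
        lab = k if k in post.population else f"b_{k}"
        draws = draws + w * post.stacked(lab)
    return summarize_draws(draws, label, post.total_sd_draws())


def approach_bias_contrast(post: PosteriorDraws, orientation_code: float,
                           avatar_sex_code: float,
                           label: str = "") -> EffectSummary:
    """Approach-avoidance difference predicted within one
    orientation x avatar-sex cell (an approach-bias), from the implicit
    model's fully crossed coefficients.

    With +-0.5 direction coding the approach-minus-avoidance difference in
    a cell equals the direction coefficient plus its interactions
    evaluated at the cell's codes.
    """
    w = {
        "direction": 1.0,
        "orientation:direction": orientation_code,
        "avatar_sex:direction": avatar_sex_code,
        "orientation:avatar_sex:direction": orientation_code * avatar_sex_code,
    }
    w = {k: v for k, v in w.items() if f"b_{k}" in post.population}
    return posterior_contrast(post, w, label or "approach_bias")


def plot_posterior_densities(draw_sets: dict, path=None):
    """Density plots with 95% HDI bars; the draws opposite in sign to the
    median are shaded red (a visual pb).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, axes = plt.subplots(len(draw_sets), 1,
                             figsize=(6, 2.2 * len(draw_sets)), squeeze=False)
    for ax, (name, draws) in zip(axes[:, 0], draw_sets.items()):
        v = np.asarray(draws, dtype=float)
        kde = gaussian_kde(v)
        xs = np.linspace(v.min(), v.max(), 400)
        ys = kde(xs)
        med = np.median(v)
        ax.plot(xs, ys, color="black")
        opp = xs <= 0 if med > 0 else xs >= 0
        ax.fill_between(xs[opp], ys[opp], color="red", alpha=0.6)
        ax.fill_between(xs[~opp], ys[~opp], color="0.7", alpha=0.6)
        lo, hi = hdi95(v)
        ax.errorbar([med], [ys.max() * 1.05], xerr=[[med - lo], [hi - med]],
                    fmt="o", color="black", capsize=3)
        ax.set_title(name, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
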