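"""Bayesian hierarchical linear mixed models for trial-level kinematics.

Design matrices use +-0.5 effect coding on categorical predictors with
full crossing of all population terms.  The model family is the Gaussian
linear mixed model

    y_i = x_i' beta + sum_g s_gi' u_g[j(i)] + eps_i,   eps_i ~ N(0, sigma)

with crossed varying-effect blocks (e.g., per-subject intercepts plus
avatar-sex and direction slopes, per-avatar intercepts plus direction
slopes), weakly-informative priors scaled to the outcome -- Normal(0, 1)
on population effects, Student-t(3, 0, 1) on the intercept, half-t(3)
on all scale parameters, and an LKJ(eta=2) prior on the Cholesky factor
of each block's correlation matrix -- and a non-centered
parameterization of the varying effects.

Sampling is Hamiltonian Monte Carlo with analytic gradients, jittered
path lengths, dual-averaging step-size adaptation and a diagonal mass
matrix estimated during warmup.  Convergence is assessed by split R-hat
(threshold 1.1) and divergent-transition counts; a non-converged fit is
flagged, never silently returned as success.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    chains: int = 4
    iterations: int = 1000  # total per chain, including warmup
    warmup_frac: float = 0.10
    seed: int = 0
    max_leapfrog: int = 24
    target_accept: float = 0.8

    def validate(self) -> None:
        if self.chains < 1 or self.iterations < 20:
            raise ValueError("need >= 1 chain and >= 20 iterations")
        if not 0 < self.warmup_frac < 1:
            raise ValueError("warmup_frac must be in (0, 1)")

    @property
    def warmup(self) -> int:
        return max(int(round(self.iterations * self.warmup_frac)), 10)


#: paper-faithful sampling profile (4 chains x 8000 iterations, 10% warmup)
PAPER_FAITHFUL = SamplerConfig(chains=4, iterations=8000, warmup_frac=0.10)
#: reduced test profile (4 chains x 1000 iterations, 10% warmup)
TEST_PROFILE = SamplerConfig(chains=4, iterations=1000, warmup_frac=0.10)


@dataclass
class VaryingBlock:
    """A varying-effects block: grouping column, slope terms, correlation."""

    group: str
    slopes: tuple = ()
    intercept: bool = True
    correlated: bool = True


@dataclass
class ModelSpec:
    """Declarative model description.

    ``factors`` maps each categorical predictor to its level->code map
    (+-0.5 effect coding); ``covariates`` maps each numeric predictor to
    a transform: "raw", "standardized", or ("centered", c).  With
    ``full_crossing`` the population matrix contains the intercept, all
    coded main effects and every interaction product.
    """

    outcome: str
    factors: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    varying: list = field(default_factory=list)
    full_crossing: bool = True
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    standardize_outcome: bool = False
    fixed_sigma: Optional[float] = None
    intercept_prior: str = "student_t"  # or "normal"
    name: str = "model"


@dataclass
class BlockDesign:
    name: str
    S: np.ndarray  # n x q varying-effect regressors
    idx: np.ndarray  # group index per row
    groups: list  # group labels, length J
    terms: list  # regressor labels, length q
    correlated: bool

    @property
    def q(self) -> int:
        return self.S.shape[1]

    @property
    def J(self) -> int:
        return len(self.groups)


@dataclass
class Design:
    X: np.ndarray
    terms: list
    y: np.ndarray
    blocks: list
    y_mean: float
    y_sd: float

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _code_column(table: pd.DataFrame, name: str, coding: dict) -> np.ndarray:
    vals = table[name]
    unseen = set(vals.unique()) - set(coding)
    if unseen:
        raise ValueError(f"unseen level(s) {sorted(unseen)!r} for factor {name!r}")
    return vals.map(coding).to_numpy(dtype=float)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the population design matrix and varying-effect blocks."""
    if spec.outcome not in table.columns:
        raise ValueError(f"outcome column {spec.outcome!r} not in table")
    main = {}
    for name, coding in spec.factors.items():
        main[name] = _code_column(table, name, coding)
    for name, transform in spec.covariates.items():
        v = table[name].to_numpy(dtype=float)
        if transform == "standardized":
            v = (v - v.mean()) / v.std(ddof=1)
        elif isinstance(transform, (tuple, list)) and transform[0] == "centered":
            v = v - float(transform[1])
        elif transform != "raw":
            raise ValueError(f"unknown covariate transform {transform!r}")
        main[name] = v

    names = list(main)
    cols = [np.ones(len(table))]
    terms = ["Intercept"]
    for name in names:
        cols.append(main[name])
        terms.append(name)
    if spec.full_crossing and len(names) > 1:
        for r in range(2, len(names) + 1):
            for combo in itertools.combinations(names, r):
                cols.append(np.prod([main[c] for c in combo], axis=0))
                terms.append(":".join(combo))
    X = np.column_stack(cols)

    y = table[spec.outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"outcome {spec.outcome!r} contains non-finite values")
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if spec.standardize_outcome:
        y = (y - y_mean) / y_sd

    blocks = []
    for vb in spec.varying:
        if vb.group not in table.columns:
            raise ValueError(f"grouping column {vb.group!r} not in table")
        codes, groups = pd.factorize(table[vb.group], sort=True)
        scols, sterms = [], []
        if vb.intercept:
            scols.append(np.ones(len(table)))
            sterms.append("Intercept")
        for s in vb.slopes:
            if s not in main:
                raise ValueError(f"varying slope {s!r} is not a model term")
            scols.append(main[s])
            sterms.append(s)
        if not scols:
            raise ValueError(f"varying block {vb.group!r} has no terms")
        blocks.append(BlockDesign(
            name=vb.group, S=np.column_stack(scols),
            idx=codes.astype(np.int64), groups=list(groups),
            terms=sterms, correlated=vb.correlated and len(sterms) > 1))
    return Design(X=X, terms=terms, y=y, blocks=blocks, y_mean=y_mean, y_sd=y_sd)


# ---------------------------------------------------------------------------
# log posterior with analytic gradients
# ---------------------------------------------------------------------------

_NU = 3.0  # df of the t priors


def _chol_corr_dual(ycor: np.ndarray, q: int, eta: float = 2.0):
    """Cholesky factor of a correlation matrix from unconstrained params.

    Uses the canonical-partial-correlation construction (z = tanh(y)).
    Returns ``(L, DL, logp, dlogp)`` where ``DL[m]`` is dL/dy_m and
    ``logp`` bundles the LKJ(eta) log density with the transform's
    log-Jacobian, ``dlogp`` its gradient w.r.t. y.  Forward-mode duals
    are cheap because q <= a handful.
    """
    m = len(ycor)
    z = np.tanh(ycor)
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    DL = np.zeros((m, q, q))
    logp = 0.0
    dlogp = np.zeros(m)
    k = 0
    for i in range(1, q):
        ssum = 0.0
        dsum = np.zeros(m)
        for j in range(i):
            w = math.sqrt(max(1.0 - ssum, 1e-12))
            dw = -dsum / (2.0 * w)
            L[i, j] = z[k] * w
            DL[:, i, j] = z[k] * dw
            DL[k, i, j] += (1.0 - z[k] ** 2) * w
            # log-Jacobian: log(1 - z^2) from tanh, log w from the chain
            logp += math.log(max(1.0 - z[k] ** 2, 1e-300)) + math.log(w)
            dlogp += dw / w
            dlogp[k] += -2.0 * z[k]
            ssum += L[i, j] ** 2
            dsum = dsum + 2.0 * L[i, j] * DL[:, i, j]
            k += 1
        L[i, i] = math.sqrt(max(1.0 - ssum, 1e-12))
        DL[:, i, i] = -dsum / (2.0 * L[i, i])
        expo = q - i - 1.0 + 2.0 * (eta - 1.0)
        logp += expo * math.log(L[i, i])
        dlogp += expo * DL[:, i, i] / L[i, i]
    return L, DL, logp, dlogp


class _Posterior:
    """Unconstrained-space log posterior and gradient for one model."""

    def __init__(self, design: Design, spec: ModelSpec):
        self.d = design
        self.spec = spec
        self.prior_scale = 1.0 if spec.standardize_outcome else max(design.y_sd, 1e-8)
        self.prior_loc = 0.0 if spec.standardize_outcome else design.y_mean
        # layout
        off = design.p
        self.slices = {}
        for b in design.blocks:
            z0 = off
            off += b.J * b.q
            t0 = off
            off += b.q
            c0, m = off, (b.q * (b.q - 1)) // 2 if b.correlated else 0
            off += m
            self.slices[b.name] = (z0, t0, c0, m)
        self.sigma_off = off if spec.fixed_sigma is None else None
        self.dim = off + (1 if spec.fixed_sigma is None else 0)

    # ----- initialization ---------------------------------------------------
    def init_theta(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        d = self.d
        theta = np.zeros(self.dim)
        XtX = d.X.T @ d.X + 1e-6 * np.eye(d.p)
        beta = np.linalg.solve(XtX, d.X.T @ d.y)
        theta[:d.p] = beta
        resid = d.y - d.X @ beta
        rsd = max(float(resid.std()), 1e-3)
        for b in d.blocks:
            z0, t0, c0, m = self.slices[b.name]
            theta[t0:t0 + b.q] = math.log(max(0.3 * rsd, 1e-3))
        if self.sigma_off is not None:
            theta[self.sigma_off] = math.log(rsd)
        theta += jitter * self.init_scales() * rng.standard_normal(self.dim)
        return theta

    def init_scales(self) -> np.ndarray:
        """Rough per-parameter posterior scale guesses (for mass matrix)."""
        d = self.d
        s = np.empty(self.dim)
        s[:d.p] = 0.3 * self.prior_scale / math.sqrt(max(d.n, 1)) * 10 + 1e-3
        for b in d.blocks:
            z0, t0, c0, m = self.slices[b.name]
            s[z0:z0 + b.J * b.q] = 1.0
            s[t0:t0 + b.q] = 0.5
            s[c0:c0 + m] = 0.5
        if self.sigma_off is not None:
            s[self.sigma_off] = 0.1
        return s

    # ----- log density ------------------------------------------------------
    def logp_grad(self, theta: np.ndarray):
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e6:
            return -np.inf, np.zeros_like(theta)
        d, spec = self.d, self.spec
        n = d.n
        grad = np.zeros_like(theta)
        beta = theta[:d.p]
        mu = d.X @ beta

        cache = []
        for b in d.blocks:
            z0, t0, c0, m = self.slices[b.name]
            Z = theta[z0:z0 + b.J * b.q].reshape(b.J, b.q)
            # exponent clipped to avoid overflow far in the tails; such
            # points have vanishing posterior mass and get rejected anyway
            tau = np.exp(np.clip(theta[t0:t0 + b.q], -80.0, 80.0))
            if m:
                L, DL, lkj_logp, lkj_grad = _chol_corr_dual(theta[c0:c0 + m], b.q)
            else:
                L, DL, lkj_logp, lkj_grad = np.eye(b.q), None, 0.0, None
            ZLt = Z @ L.T
            U = ZLt * tau
            mu = mu + np.einsum("ij,ij->i", U[b.idx], b.S)
            cache.append((b, Z, tau, L, DL, lkj_logp, lkj_grad, ZLt))

        if spec.fixed_sigma is not None:
            sigma = float(spec.fixed_sigma)
        else:
            sigma = math.exp(min(theta[self.sigma_off], 80.0))
        sig2 = sigma * sigma
        r = d.y - mu
        ssr = float(r @ r)
        logp = -0.5 * ssr / sig2 - n * math.log(sigma)
        w = r / sig2

        # population priors
        s0 = self.prior_scale
        if spec.intercept_prior == "student_t":
            dev = beta[0] - self.prior_loc
            logp += -0.5 * (_NU + 1) * math.log1p(dev * dev / (_NU * s0 * s0))
            g0 = -(_NU + 1) * dev / (_NU * s0 * s0 + dev * dev)
        else:
            dev = beta[0] - self.prior_loc
            logp += -0.5 * dev * dev / (s0 * s0)
            g0 = -dev / (s0 * s0)
        rest = beta[1:]
        logp += -0.5 * float(rest @ rest) / (s0 * s0)
        grad[:d.p] = d.X.T @ w
        grad[0] += g0
        grad[1:d.p] += -rest / (s0 * s0)

        for (b, Z, tau, L, DL, lkj_logp, lkj_grad, ZLt) in cache:
            z0, t0, c0, m = self.slices[b.name]
            G = np.empty((b.J, b.q))
            for k in range(b.q):
                G[:, k] = np.bincount(b.idx, weights=w * b.S[:, k], minlength=b.J)
            Gt = G * tau
            grad[z0:z0 + b.J * b.q] = (Gt @ L - Z).ravel()
            logp += -0.5 * float((Z * Z).sum())
            # scales: half-t(3, 0, s0) with log-Jacobian
            ht = -(_NU + 1) * tau / (_NU * s0 * s0 + tau * tau)
            grad[t0:t0 + b.q] = (tau * np.einsum("jk,jk->k", G, ZLt)
                                 + ht * tau + 1.0)
            logp += float(np.sum(-0.5 * (_NU + 1)
                                 * np.log1p(tau * tau / (_NU * s0 * s0))
                                 + np.log(tau)))
            if m:
                gradL = Gt.T @ Z  # (q, q); lower triangle is what L uses
                gy = np.einsum("mij,ij->m", DL, gradL)
                grad[c0:c0 + m] = gy + lkj_grad
                logp += lkj_logp

        if self.sigma_off is not None:
            ht = -(_NU + 1) * sigma / (_NU * s0 * s0 + sig2)
            grad[self.sigma_off] = -n + ssr / sig2 + ht * sigma + 1.0
            logp += (-0.5 * (_NU + 1) * math.log1p(sig2 / (_NU * s0 * s0))
                     + math.log(sigma))
        return logp, grad

    # ----- constrained draws ------------------------------------------------
    def labels(self):
        d = self.d
        labs = [f"b_{t}" for t in d.terms]
        for b in d.blocks:
            labs += [f"sd_{b.name}__{t}" for t in b.terms]
            if b.correlated:
                for k1, k2 in itertools.combinations(range(b.q), 2):
                    labs.append(f"cor_{b.name}__{b.terms[k1]}__{b.terms[k2]}")
        labs.append("sigma")
        for b in d.blocks:
            for g in b.groups:
                labs += [f"r_{b.name}[{g},{t}]" for t in b.terms]
        return labs

    def constrain(self, theta: np.ndarray) -> np.ndarray:
        d = self.d
        out = [theta[:d.p]]
        tail = []
        for b in d.blocks:
            z0, t0, c0, m = self.slices[b.name]
            Z = theta[z0:z0 + b.J * b.q].reshape(b.J, b.q)
            tau = np.exp(theta[t0:t0 + b.q])
            if m:
                L, _, _, _ = _chol_corr_dual(theta[c0:c0 + m], b.q)
            else:
                L = np.eye(b.q)
            out.append(tau)
            if b.correlated:
                C = L @ L.T
                out.append(np.array([C[k1, k2] for k1, k2
                                     in itertools.combinations(range(b.q), 2)]))
            U = (Z @ L.T) * tau
            tail.append(U.ravel())
        sigma = (self.spec.fixed_sigma if self.sigma_off is None
                 else math.exp(theta[self.sigma_off]))
        out.append(np.array([sigma]))
        return np.concatenate(out + tail)


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

def _leapfrog(post, theta, p, eps, n_steps, inv_mass):
    logp, grad = post.logp_grad(theta)
    p = p + 0.5 * eps * grad
    for s in range(n_steps):
        theta = theta + eps * inv_mass * p
        logp, grad = post.logp_grad(theta)
        if not np.isfinite(logp):
            return theta, p, -np.inf, grad
        p = p + (eps if s < n_steps - 1 else 0.5 * eps) * grad
    return theta, p, logp, grad


def _find_initial_eps(post, theta, inv_mass, rng):
    eps = 0.1
    logp0, _ = post.logp_grad(theta)
    p0 = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = -logp0 + 0.5 * float(p0 * p0 @ inv_mass)
    _, p1, logp1, _ = _leapfrog(post, theta, p0.copy(), eps, 1, inv_mass)
    h1 = -logp1 + 0.5 * float(p1 * p1 @ inv_mass)
    ratio = math.exp(min(h0 - h1, 0.0)) if np.isfinite(h1) else 0.0
    direction = 1 if ratio > 0.5 else -1
    for _ in range(40):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(post, theta, p0.copy(), eps, 1, inv_mass)
        h1 = -logp1 + 0.5 * float(p1 * p1 @ inv_mass) if np.isfinite(logp1) else np.inf
        ratio = math.exp(min(h0 - h1, 0.0)) if np.isfinite(h1) else 0.0
        if (direction == 1 and ratio < 0.5) or (direction == -1 and ratio > 0.5):
            break
    return max(eps, 1e-8)


def _run_chain(post: _Posterior, cfg: SamplerConfig, chain: int):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919, chain]))
    theta = post.init_theta(rng)
    warmup = cfg.warmup
    n_keep = cfg.iterations - warmup
    inv_mass = post.init_scales() ** 2

    eps = _find_initial_eps(post, theta, inv_mass, rng)
    mu_da = math.log(10.0 * eps)
    log_eps, log_eps_bar, h_bar = math.log(eps), 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    w_lo, w_hi = int(0.3 * warmup), int(0.8 * warmup)
    window = []
    draws = np.empty((n_keep, len(post.labels())))
    divergences = 0
    accepts = []
    logp, _ = post.logp_grad(theta)

    for it in range(cfg.iterations):
        p0 = rng.standard_normal(post.dim) / np.sqrt(inv_mass)
        h0 = -logp + 0.5 * float((p0 * p0) @ inv_mass)
        n_steps = int(rng.integers(1, cfg.max_leapfrog + 1))
        step = math.exp(log_eps) if it < warmup else math.exp(log_eps_bar)
        theta_new, p_new, logp_new, _ = _leapfrog(post, theta.copy(), p0, step,
                                                  n_steps, inv_mass)
        if np.isfinite(logp_new):
            h1 = -logp_new + 0.5 * float((p_new * p_new) @ inv_mass)
            delta = h0 - h1
        else:
            delta = -np.inf
        divergent = (not np.isfinite(delta)) or delta < -500.0
        a_prob = 0.0 if divergent else min(1.0, math.exp(min(delta, 0.0)))
        if not divergent and math.log(rng.random() + 1e-300) < delta:
            theta, logp = theta_new, logp_new

        if it < warmup:
            da_iter += 1
            h_bar = ((1.0 - 1.0 / (da_iter + t0)) * h_bar
                     + (cfg.target_accept - a_prob) / (da_iter + t0))
            log_eps = mu_da - math.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            if w_lo <= it < w_hi:
                window.append(theta.copy())
            if it == w_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                k = len(window)
                inv_mass = (k / (k + 5.0)) * var + (5.0 / (k + 5.0)) * post.init_scales() ** 2
                inv_mass = np.maximum(inv_mass, 1e-10)
                eps = _find_initial_eps(post, theta, inv_mass, rng)
                mu_da = math.log(10.0 * eps)
                log_eps, h_bar, da_iter = math.log(eps), 0.0, 0
        else:
            if divergent:
                divergences += 1
            accepts.append(a_prob)
            draws[it - warmup] = post.constrain(theta)
    return draws, divergences, float(np.mean(accepts)) if accepts else 0.0


@dataclass
class PosteriorDraws:
    """Labeled posterior sample array (chains x draws x parameters)."""

    array: np.ndarray
    labels: list
    population: list
    sd_labels: list
    cor_labels: list
    divergences: np.ndarray
    accept: np.ndarray
    spec: ModelSpec
    design: Design
    convergence: Optional[pd.DataFrame] = None
    converged: Optional[bool] = None

    def get(self, label: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, draws)."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown parameter {label!r}") from None
        return self.array[:, :, j]

    def stacked(self, label: str) -> np.ndarray:
        return self.get(label).reshape(-1)

    def total_sd_draws(self) -> np.ndarray:
        """Per-draw sqrt(sum of varying-effect variances + residual variance)."""
        tot = self.stacked("sigma") ** 2
        for lab in self.sd_labels:
            tot = tot + self.stacked(lab) ** 2
        return np.sqrt(tot)

    def fitted_variance_draws(self, chunk: int = 200) -> np.ndarray:
        """Per-draw variance of the fitted values (for Bayesian R^2)."""
        d = self.design
        flat = self.array.reshape(-1, self.array.shape[-1])
        bcols = [self.labels.index(f"b_{t}") for t in d.terms]
        out = np.empty(flat.shape[0])
        r_start = len(self.population) + len(self.sd_labels) + len(self.cor_labels) + 1
        for lo in range(0, flat.shape[0], chunk):
            sub = flat[lo:lo + chunk]
            mu = sub[:, bcols] @ d.X.T  # (c, n)
            off = r_start
            for b in d.blocks:
                U = sub[:, off:off + b.J * b.q].reshape(len(sub), b.J, b.q)
                mu += np.einsum("cnk,nk->cn", U[:, b.idx, :], b.S)
                off += b.J * b.q
            out[lo:lo + chunk] = mu.var(axis=1)
        return out


def split_rhat(chains: np.ndarray) -> float:
    """Split Rubin-Gelman R-hat for one parameter, chains shape (C, N)."""
    c, n = chains.shape
    if c < 2:
        raise ValueError("split R-hat needs >= 2 chains")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n2 = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def check_convergence(post: PosteriorDraws, rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Per-parameter split R-hat and overall divergence count.

    The overall pass requires all R-hat below the threshold and zero
    divergent transitions.
    """
    if post.array.shape[0] < 2:
        raise ValueError("convergence check needs >= 2 chains")
    named = post.population + post.sd_labels + post.cor_labels + ["sigma"]
    rows = [{"parameter": lab, "rhat": split_rhat(post.get(lab))} for lab in named]
    df = pd.DataFrame(rows)
    df.attrs["divergences"] = int(post.divergences.sum())
    df.attrs["pass"] = bool((df.rhat < rhat_threshold).all()
                            and post.divergences.sum() == 0)
    return df


def fit_model(design: Design, spec: ModelSpec) -> PosteriorDraws:
    """Fit the hierarchical model by HMC; attaches a convergence report."""
    spec.sampler.validate()
    post = _Posterior(design, spec)
    labels = post.labels()
    all_draws, divs, accs = [], [], []
    for chain in range(spec.sampler.chains):
        draws, d, a = _run_chain(post, spec.sampler, chain)
        all_draws.append(draws)
        divs.append(d)
        accs.append(a)
    arr = np.asarray(all_draws)
    n_pop = design.p
    sd_labels = [l for l in labels if l.startswith("sd_")]
    cor_labels = [l for l in labels if l.startswith("cor_")]
    out = PosteriorDraws(
        array=arr, labels=labels,
        population=labels[:n_pop], sd_labels=sd_labels, cor_labels=cor_labels,
        divergences=np.asarray(divs), accept=np.asarray(accs),
        spec=spec, design=design)
    if spec.sampler.chains >= 2:
        out.convergence = check_convergence(out)
        out.converged = bool(out.convergence.attrs["pass"])
    return out


def simulate_outcome(design: Design, beta: np.ndarray, block_sds: list,
                     sigma: float, rng: np.random.Generator,
                     block_cors: Optional[list] = None) -> np.ndarray:
    """Draw an outcome vector from the model with known parameters.

    ``block_sds[g]`` gives the varying-effect SDs of block g;
    ``block_cors[g]`` an optional correlation matrix.  Used by
    parameter-recovery simulations.
    """
    y = design.X @ np.asarray(beta, dtype=float)
    for g, b in enumerate(design.blocks):
        sds = np.asarray(block_sds[g], dtype=float)
        C = np.eye(b.q) if block_cors is None else np.asarray(block_cors[g])
        cov = np.outer(sds, sds) * C
        u = rng.multivariate_normal(np.zeros(b.q), cov, size=b.J)
        y = y + np.einsum("ij,ij->i", u[b.idx], b.S)
    return y + sigma * rng.standard_normal(design.n)
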