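"""Location-scale (double hierarchical) model: CVp, correlations,
convergence diagnostics and calibration of the Gibbs sampler."""

import numpy as np
import pytest

import pentrack as pt
from pentrack.dhglm import PriorSpec


def tiny_settings(seed=5, n_iter=1600, burn_in=800, thin=2):
    return pt.MCMCSettings(n_chains=2, n_iter=n_iter, burn_in=burn_in,
                           thin=thin, seed=seed)


@pytest.fixture(scope="module")
def univariate_fit(small_metric_table, short_mcmc):
    spec = pt.DHGLMSpec(responses=("trait",), re_structure="independent")
    return pt.fit_dhglm(small_metric_table.table, spec, short_mcmc)


class TestCvpTransform:
    def test_zero_dispersion_variance_gives_zero(self):
        assert np.sqrt(np.expm1(0.0)) == 0.0

    def test_log_two_gives_one(self):
        fit = _fit_with_fixed_omega2(np.log(2.0))
        est = pt.compute_cvp(fit)
        assert est.cvp == pytest.approx(1.0, abs=1e-12)

    def test_paper_scale_value(self):
        fit = _fit_with_fixed_omega2(0.2151)
        assert pt.compute_cvp(fit).cvp == pytest.approx(0.49, abs=0.005)

    def test_monotone_and_matches_lognormal_cv(self):
        # CVp must equal the Monte-Carlo CV of lognormal individual SDs
        rng = np.random.default_rng(0)
        for w2 in (0.05, 0.2, 0.6):
            sd = np.exp(rng.normal(0, np.sqrt(w2), 400_000))
            assert np.sqrt(np.expm1(w2)) == pytest.approx(
                sd.std() / sd.mean(), rel=0.02)


def _fit_with_fixed_omega2(w2):
    """A DHGLMFit shell holding degenerate draws, for transform tests."""
    spec = pt.DHGLMSpec(responses=("trait",))
    return pt.DHGLMFit(draws={"omega2[trait]": np.full((2, 10), w2)},
                       individual_effects=None, spec=spec,
                       settings=tiny_settings(), response_scale={})


class TestUnivariateFit:
    def test_draw_count_contract(self, univariate_fit, short_mcmc):
        arr = univariate_fit.draws["omega2[trait]"]
        assert arr.shape == (short_mcmc.n_chains,
                             (short_mcmc.n_iter - short_mcmc.burn_in)
                             // short_mcmc.thin)
        assert (univariate_fit.draws["v_ind[trait]"] > 0).all()

    def test_recovers_generator_truth(self, univariate_fit, small_metric_table):
        truth_vind = small_metric_table.intercepts.var(ddof=1)
        truth_w2 = small_metric_table.dispersion_effects.var(ddof=1)
        s = univariate_fit.summary().set_index("parameter")
        assert s.loc["v_ind[trait]", "mean"] == pytest.approx(
            truth_vind, abs=3 * s.loc["v_ind[trait]", "sd"])
        assert s.loc["omega2[trait]", "mean"] == pytest.approx(
            truth_w2, abs=3 * s.loc["omega2[trait]", "sd"])

    def test_seeded_reproducibility(self, small_metric_table):
        spec = pt.DHGLMSpec(responses=("trait",))
        a = pt.fit_dhglm(small_metric_table.table, spec, tiny_settings(3))
        b = pt.fit_dhglm(small_metric_table.table, spec, tiny_settings(3))
        c = pt.fit_dhglm(small_metric_table.table, spec, tiny_settings(4))
        assert np.array_equal(a.draws["omega2[trait]"],
                              b.draws["omega2[trait]"])
        assert not np.array_equal(a.draws["omega2[trait]"],
                                  c.draws["omega2[trait]"])

    def test_null_dispersion_recovery(self):
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=60, n_units=12, v_ind=0.5, v_res=0.5,
            omega2_id=0.0, seed=21))
        fit = pt.fit_dhglm(res.table,
                           pt.DHGLMSpec(responses=("trait",)),
                           tiny_settings(6))
        est = pt.compute_cvp(fit)
        assert est.cvp < 0.12
        assert est.cri_low < 0.06

    def test_matches_reml_when_dispersion_flat(self, small_metric_table):
        # mean-submodel-only: posterior variance ratio ~ REML repeatability
        table = small_metric_table.table
        spec = pt.DHGLMSpec(responses=("trait",), dispersion_random=False)
        fit = pt.fit_dhglm(table, spec, tiny_settings(7))
        v_ind = fit.stacked("v_ind[trait]")
        v_res = np.exp(2 * fit.stacked("b_disp[trait,intercept]"))
        r_post = float((v_ind / (v_ind + v_res)).mean())
        r_reml = pt.adjusted_repeatability(pt.fit_lmm_reml(
            table, pt.LMMSpec("trait", ()))).r
        assert r_post == pytest.approx(r_reml, abs=0.05)

    def test_requires_repeated_measures(self, small_metric_table):
        single = small_metric_table.table.groupby("individual_id").head(1)
        with pytest.raises(ValueError):
            pt.fit_dhglm(single, pt.DHGLMSpec(responses=("trait",)),
                         tiny_settings())


class TestCorrelatedStructures:
    def test_type_riiv_correlation_recovery(self):
        C = np.array([[1.0, 0.58], [0.58, 1.0]])
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=60, n_units=12, v_ind=0.4, v_res=0.2,
            omega2_id=0.2, re_correlation=C, seed=22))
        fit = pt.fit_dhglm(res.table,
                           pt.DHGLMSpec(responses=("trait",),
                                        re_structure="correlated"),
                           tiny_settings(8, n_iter=2400, burn_in=1200))
        rep = pt.extract_correlations(fit, "type-riiv")
        assert len(rep.rows) == 1
        assert rep.rows["mean"].iloc[0] == pytest.approx(0.58, abs=0.2)
        assert rep.rows["decisive"].iloc[0]

    def test_independent_fit_has_no_correlation_blocks(self, univariate_fit):
        with pytest.raises(ValueError, match="re_structure"):
            pt.extract_correlations(univariate_fit, "type-riiv")

    def test_bivariate_intercept_correlation_recovery(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.59
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=60, n_units=12, v_ind=0.5, v_res=0.5,
            omega2_id=0.0, re_correlation=C, n_traits=2, seed=23))
        fit = pt.fit_mv_dhglm(res.table, ["trait_1", "trait_2"],
                              tiny_settings(9, n_iter=2400, burn_in=1200),
                              dispersion_random=False)
        rep = pt.extract_correlations(fit, "type-type")
        assert rep.rows["mean"].iloc[0] == pytest.approx(0.59, abs=0.2)
        assert rep.rows["decisive"].iloc[0]
        # residual correlation truth is zero
        res_corr = fit.stacked("res_corr[trait_1|trait_2]")
        assert abs(res_corr.mean()) < 0.15

    def test_null_cross_correlation_covered(self):
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=50, n_units=8, v_ind=0.5, v_res=0.5,
            omega2_id=0.0, n_traits=2, seed=24))
        fit = pt.fit_mv_dhglm(res.table, ["trait_1", "trait_2"],
                              tiny_settings(10), dispersion_random=False)
        row = pt.extract_correlations(fit, "type-type").rows.iloc[0]
        assert row["cri_low"] < 0.0 < row["cri_high"]

    def test_permuted_labels_collapse_correlation(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.7
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=50, n_units=8, v_ind=0.5, v_res=0.5,
            omega2_id=0.0, re_correlation=C, n_traits=2, seed=25))
        table = res.table.copy()
        # destroy the individual linkage of trait_2 by permuting its
        # values across individuals within each unit
        rng = np.random.default_rng(0)
        for u, idx in table.groupby("unit_index").groups.items():
            table.loc[idx, "trait_2"] = rng.permutation(
                table.loc[idx, "trait_2"].to_numpy())
        fit = pt.fit_mv_dhglm(table, ["trait_1", "trait_2"],
                              tiny_settings(11), dispersion_random=False)
        row = pt.extract_correlations(fit, "type-type").rows.iloc[0]
        assert abs(row["mean"]) < 0.25
        assert not row["decisive"]

    def test_five_trait_fit_exposes_45_correlations(self):
        res = pt.simulate_metric_table(pt.MetricSimConfig(
            n_individuals=15, n_units=4, v_ind=0.5, v_res=0.5,
            omega2_id=0.1, n_traits=5, seed=26))
        fit = pt.fit_mv_dhglm(
            res.table, [f"trait_{i}" for i in range(1, 6)],
            pt.MCMCSettings(n_chains=1, n_iter=220, burn_in=120, thin=2,
                            seed=1))
        rep = pt.extract_correlations(fit, "all")
        assert len(rep.rows) == 45  # C(10, 2) from the 10x10 matrix
        assert set(rep.rows["kind"]) == {"type-type", "type-riiv",
                                         "riiv-riiv"}
        assert len(rep.rows[rep.rows.kind == "type-type"]) == 10
        assert len(rep.rows[rep.rows.kind == "riiv-riiv"]) == 10
        assert len(rep.rows[rep.rows.kind == "type-riiv"]) == 25


class TestDiagnostics:
    def test_rhat_near_one_for_iid_chains(self, univariate_fit):
        diag = pt.convergence_diagnostics(univariate_fit)
        w2 = diag.set_index("parameter").loc["omega2[trait]"]
        assert w2["rhat"] < 1.05
        assert not w2["non_converged"]

    def test_offset_chain_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500))
        draws[1] += 10.0
        fit = pt.DHGLMFit(draws={"omega2[trait]": draws ** 2 + 1},
                          individual_effects=None,
                          spec=pt.DHGLMSpec(responses=("trait",)),
                          settings=tiny_settings(), response_scale={})
        diag = pt.convergence_diagnostics(fit)
        assert diag["rhat"].iloc[0] > 1.5
        assert diag["non_converged"].iloc[0]

    def test_ess_matches_ar1_closed_form(self):
        # ESS/N for an AR(1) chain with lag-1 correlation phi is
        # (1 - phi) / (1 + phi); phi = 0.5 -> 1/3
        import arviz as az

        rng = np.random.default_rng(2)
        phi, n = 0.5, 40_000
        chains = np.empty((4, n))
        for c in range(4):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for i in range(1, n):
                x[i] = phi * x[i - 1] + e[i]
            chains[c] = x
        ratio = float(az.ess(chains, method="mean")) / (4 * n)
        assert ratio == pytest.approx(1 / 3, rel=0.15)

    def test_raftery_lewis_iid_near_minimum(self):
        rng = np.random.default_rng(3)
        rl = pt.raftery_lewis(rng.standard_normal(20_000))
        assert rl["n_min"] == 3746  # q=0.025, r=0.005, s=0.95
        assert rl["dependence_factor"] == pytest.approx(1.0, abs=0.3)

    def test_raftery_lewis_dependent_chain_needs_more(self):
        rng = np.random.default_rng(4)
        x = np.empty(20_000)
        x[0] = 0.0
        for i in range(1, len(x)):
            x[i] = 0.9 * x[i - 1] + rng.standard_normal()
        rl = pt.raftery_lewis(x)
        assert rl["dependence_factor"] > 2.0


class TestCalibration:
    def test_simulation_based_calibration_of_omega2(self):
        """Posterior ranks of the true dispersion variance should be
        uniform when the generator draws its parameters from the model's
        own priors (reduced 20 x 6 design)."""
        # proper moderate priors used for BOTH generation and fitting:
        # scalar variances ~ IG(3, 0.4), fixed effects ~ N(0, 1)
        priors = PriorSpec(beta_sd=1.0, iw_df_offset=5.0, iw_scale=0.8)
        rng = np.random.default_rng(100)
        ranks = []
        n_rep = 20
        for rep in range(n_rep):
            w2 = 0.4 / rng.gamma(3.0)       # IG(3, 0.4) draw
            v_ind = 0.4 / rng.gamma(3.0)
            beta0 = rng.normal(0, 1.0)
            beta_d0 = rng.normal(0, 1.0)
            # generator baseline log-SD is 0.5*log(v_res) - w2; invert so
            # the realized dispersion intercept equals beta_d0
            v_res = np.exp(2 * (beta_d0 + w2))
            res = pt.simulate_metric_table(pt.MetricSimConfig(
                n_individuals=20, n_units=6, v_ind=v_ind, v_res=v_res,
                omega2_id=w2, beta0=beta0, seed=int(rng.integers(2**31))))
            fit = pt.fit_dhglm(
                res.table, pt.DHGLMSpec(responses=("trait",)),
                pt.MCMCSettings(n_chains=1, n_iter=700, burn_in=300,
                                thin=4, seed=int(rng.integers(2**31))),
                priors=priors)
            draws = fit.stacked("omega2[trait]")
            ranks.append((draws < w2).mean())
        ranks = np.asarray(ranks)
        # crude uniformity checks (low power by design, catches gross
        # miscalibration): mean near 0.5, no pile-up at the extremes
        assert abs(ranks.mean() - 0.5) < 0.25
        assert ((ranks < 0.02).sum() + (ranks > 0.98).sum()) <= 3
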