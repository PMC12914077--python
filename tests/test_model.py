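"""Joint likelihood, priors and the overdispersion check."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln

from hrrmap import model as mod
from hrrmap import spatial, strata
from hrrmap.model import ModelParameters, PriorSpec


def _rand_params(rng, n_areas, n_gamma=3):
    u = rng.normal(0, 0.3, n_areas)
    u -= u.mean()
    return ModelParameters(
        mu=rng.normal(-3, 0.3),
        beta=rng.normal(0, 0.3, 9),
        gamma=rng.normal(0, 0.3, n_gamma),
        u=u,
        v=rng.normal(0, 0.2, n_areas),
        delta1=rng.normal(0, 0.1),
        delta2=rng.normal(0, 0.1),
        tau_u2=0.5,
        tau_v2=0.1,
    )


def brute_force_individual_loglik(params, records, z, n_periods=3):
    """Per-record oracle computed straight from the model formula."""
    defn = strata.default_strata()
    X = strata.stratum_design_matrix(defn)
    total = 0.0
    for _, row in records.iterrows():
        k = defn.index_of(
            tuple(
                list(defn.levels(name)).index(row[name]) for name, _ in defn.covariates
            )
        )
        c = row["period"] - (n_periods + 1) / 2
        eta = (
            params.mu
            + X[k] @ params.beta
            + (z.loc[row["area_id"]].to_numpy() @ params.gamma if z is not None else 0.0)
            + params.u[row["area_id"]]
            + params.v[row["area_id"]]
            + params.delta1 * c
            + params.delta2 * c**2
        )
        p = expit(eta)
        total += np.log(p) if row["outcome"] == 1 else np.log(1 - p)
    return total


class TestIndividualLoglik:
    def test_single_record_even_odds(self, tiny_records):
        rec = tiny_records.iloc[[0]].copy()
        rec["outcome"] = 1
        cells = mod.build_cells(rec, None, n_areas=2, n_periods=2)
        params = ModelParameters.null(9, 0, 2)
        assert mod.individual_loglik(params, cells) == pytest.approx(np.log(0.5))

    def test_null_parameters_give_n_log_half(self, tiny_records):
        cells = mod.build_cells(tiny_records, None, n_areas=2, n_periods=2)
        params = ModelParameters.null(9, 0, 2)
        assert mod.individual_loglik(params, cells) == pytest.approx(10 * np.log(0.5))

    def test_matches_per_record_enumeration(self, tiny_records):
        rng = np.random.default_rng(4)
        z = pd.DataFrame(
            {"z0": [0.3, -0.2], "z1": [1.0, 0.0], "z2": [0.0, 1.0]}, index=[0, 1]
        )
        params = _rand_params(rng, n_areas=2)
        cells = mod.build_cells(tiny_records, z, n_areas=2, n_periods=2)
        oracle = brute_force_individual_loglik(params, tiny_records, z, n_periods=2)
        assert mod.individual_loglik(params, cells) == pytest.approx(oracle, abs=1e-9)

    def test_nonbinary_outcomes_rejected(self, tiny_records):
        bad = tiny_records.copy()
        bad.loc[0, "outcome"] = 2
        with pytest.raises(ValueError, match="binary"):
            mod.build_cells(bad, None, n_areas=2, n_periods=2)


class TestAggregateLoglik:
    def test_single_record_cell_equals_bernoulli(self, tiny_records):
        rec = tiny_records.iloc[[3]].copy()
        cells = mod.build_cells(rec, None, n_areas=2, n_periods=2)
        rng = np.random.default_rng(0)
        params = _rand_params(rng, n_areas=2, n_gamma=0)
        params.gamma = np.zeros(0)
        # Binomial(1, p) is Bernoulli(p): the two levels coincide exactly
        assert mod.aggregate_loglik(params, cells, "binomial") == pytest.approx(
            mod.individual_loglik(params, cells), abs=1e-12
        )

    def test_poisson_binomial_agree_for_rare_outcomes(self, small_cells):
        rng = np.random.default_rng(1)
        params = _rand_params(rng, n_areas=12)
        params.mu = -3.5  # risks comfortably below 5%
        lb = mod.aggregate_loglik(params, small_cells, "binomial")
        lp = mod.aggregate_loglik(params, small_cells, "poisson")
        # compare the data-dependent parts per cell via total magnitude
        assert abs(lp - lb) / abs(lb) < 0.03

    def test_deaths_exceeding_at_risk_rejected(self, small_cells):
        import copy

        bad = copy.copy(small_cells)
        bad.y_jt = small_cells.y_jt.copy()
        bad.y_jt[0] = small_cells.n_jt[0] + 1
        params = ModelParameters.null(9, 3, 12)
        with pytest.raises(ValueError, match="exceed"):
            mod.aggregate_loglik(params, bad)

    def test_unknown_family_rejected(self, small_cells):
        params = ModelParameters.null(9, 3, 12)
        with pytest.raises(ValueError, match="family"):
            mod.aggregate_loglik(params, small_cells, "negbin")


class TestJointLoglik:
    def test_additivity(self, small_cells):
        rng = np.random.default_rng(2)
        params = _rand_params(rng, n_areas=12)
        assert mod.joint_loglik(params, small_cells) == pytest.approx(
            mod.individual_loglik(params, small_cells)
            + mod.aggregate_loglik(params, small_cells),
            abs=1e-10,
        )

    def test_record_order_irrelevant(self, small_registry):
        rng = np.random.default_rng(3)
        params = _rand_params(rng, n_areas=12)
        recs = small_registry.records
        shuffled = recs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = mod.build_cells(recs, small_registry.z, n_areas=12, n_periods=3)
        b = mod.build_cells(shuffled, small_registry.z, n_areas=12, n_periods=3)
        assert mod.joint_loglik(params, a) == pytest.approx(
            mod.joint_loglik(params, b), abs=1e-9
        )


class TestLogPrior:
    def test_beta_quadratic_increment(self):
        adj, _ = __import__("hrrmap.synthetic", fromlist=["generate_lattice"]).generate_lattice(2, 2)
        prior = PriorSpec()
        p1 = ModelParameters.null(9, 0, 4)
        p2 = ModelParameters.null(9, 0, 4)
        p1.beta[3] = 0.7
        p2.beta[3] = 1.4
        delta = mod.log_prior(p2, prior, adj) - mod.log_prior(p1, prior, adj)
        assert delta == pytest.approx(-0.725 * (1.4**2 - 0.7**2) / 2, abs=1e-10)

    def test_zero_effects_zero_quadratic_terms(self):
        from hrrmap.synthetic import generate_lattice

        adj, _ = generate_lattice(2, 2)
        prior = PriorSpec()
        params = ModelParameters.null(9, 0, 4)
        base = mod.log_prior(params, prior, adj)
        # moving u off the constant surface must only subtract the ICAR term
        params2 = ModelParameters.null(9, 0, 4)
        params2.u = np.array([0.5, -0.5, 0.0, 0.0])
        shift = mod.log_prior(params2, prior, adj) - base
        assert shift == pytest.approx(
            spatial.icar_logdensity_unnorm(params2.u, adj, 1.0), abs=1e-12
        )

    def test_icar_term_matches_dense_quadratic_form(self):
        from hrrmap.synthetic import generate_lattice

        adj, _ = generate_lattice(3, 3)
        rng = np.random.default_rng(6)
        u = rng.normal(size=9)
        u -= u.mean()
        prior = PriorSpec()
        pa = ModelParameters.null(9, 0, 9)
        pb = ModelParameters.null(9, 0, 9)
        pb.u = u
        got = mod.log_prior(pb, prior, adj) - mod.log_prior(pa, prior, adj)
        oracle = -0.5 * u @ adj.laplacian() @ u / 1.0
        assert got == pytest.approx(oracle, abs=1e-10)


class TestPriorPrecision:
    def test_published_interval_gives_0_725(self):
        assert round(mod.prior_precision_from_or_range(0.1, 10, 0.95), 3) == 0.725

    def test_unit_sd_interval(self):
        prec = mod.prior_precision_from_or_range(np.exp(-1.959964), np.exp(1.959964), 0.95)
        assert prec == pytest.approx(1.0, abs=1e-6)

    def test_matches_numeric_quantile_inversion(self):
        from scipy.optimize import brentq
        from scipy.stats import norm

        # oracle: solve P(|logOR| < ln 2) = 0.95 for the normal sd numerically
        def central_mass(sd):
            return norm.cdf(np.log(2), scale=sd) - norm.cdf(-np.log(2), scale=sd) - 0.95

        sd = brentq(central_mass, 1e-6, 10)
        assert mod.prior_precision_from_or_range(0.5, 2, 0.95) == pytest.approx(
            1 / sd**2, rel=1e-6
        )

    def test_asymmetric_range_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            mod.prior_precision_from_or_range(0.2, 10, 0.95)


class TestOverdispersion:
    def test_null_poisson_not_flagged(self):
        rng = np.random.default_rng(7)
        n = np.full(200, 80.0)
        p = np.full(200, 0.05)
        y = rng.poisson(n * p)
        ratio, flag = mod.overdispersion_statistic(y, n, p, "poisson", rng=rng)
        assert 0.7 < ratio < 1.3
        assert not flag

    def test_doubled_variance_flagged(self):
        rng = np.random.default_rng(8)
        n = np.full(150, 100.0)
        p = np.full(150, 0.06)
        m = n * p  # negative binomial with variance 2 * mean
        y = rng.negative_binomial(n=m, p=0.5)
        ratio, flag = mod.overdispersion_statistic(y, n, p, "poisson", rng=rng)
        assert ratio > 1.3
        assert flag

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            mod.overdispersion_statistic(
                np.array([3.0]), np.array([50.0]), np.array([0.05])
            )


class TestKernelConsistency:
    def test_kernel_deviance_matches_python_loglik(self, small_registry, small_cells):
        """The compiled sampler and the reference implementation must score
        identical parameter values identically."""
        from hrrmap import mcmc

        cfg = mcmc.SamplerConfig(
            n_iterations=300, burn_in=100, n_chains=1, thin=50, seed=123
        )
        samples = mcmc.run_mcmc(small_cells, small_registry.adjacency, cfg)
        for d in range(samples.n_draws):
            fx = samples.fixed[0, d]
            params = ModelParameters(
                mu=fx[0],
                beta=fx[small_cells.beta_slice],
                gamma=fx[small_cells.gamma_slice],
                u=samples.u[0, d],
                v=samples.v[0, d],
                delta1=fx[small_cells.time_slice.start],
                delta2=fx[small_cells.time_slice.start + 1],
            )
            dev = -2.0 * mod.joint_loglik(params, small_cells, "binomial")
            assert samples.deviance[0, d] == pytest.approx(dev, rel=1e-9)

    def test_kernel_deviance_matches_python_loglik_poisson(self, small_registry, small_cells):
        from hrrmap import mcmc

        cfg = mcmc.SamplerConfig(
            n_iterations=200, burn_in=100, n_chains=1, thin=50, seed=9, family="poisson"
        )
        samples = mcmc.run_mcmc(small_cells, small_registry.adjacency, cfg)
        for d in range(samples.n_draws):
            fx = samples.fixed[0, d]
            params = ModelParameters(
                mu=fx[0],
                beta=fx[small_cells.beta_slice],
                gamma=fx[small_cells.gamma_slice],
                u=samples.u[0, d],
                v=samples.v[0, d],
                delta1=fx[small_cells.time_slice.start],
                delta2=fx[small_cells.time_slice.start + 1],
            )
            dev = -2.0 * mod.joint_loglik(params, small_cells, "poisson")
            assert samples.deviance[0, d] == pytest.approx(dev, rel=1e-9)
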