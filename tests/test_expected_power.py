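import warnings

import numpy as np
import pytest

from crthybrid import (
    BetaPrior,
    DesignAssumptions,
    GammaPrior,
    HybridSpec,
    PointMassPrior,
    TruncatedNormalPrior,
    VarianceComponents,
    ep_icc_only,
    ep_icc_sd,
    ep_monte_carlo,
    expected_power,
    make_pg_design,
    power_pg,
)
from conftest import random_hybrid_spec


def surr_spec(surr, surr_design, icc_prior, sd_prior):
    return HybridSpec(design=surr_design, da=surr.da, icc_prior=icc_prior, sd_prior=sd_prior)


class TestICCOnly:
    def test_point_mass_prior_recovers_frequentist_power(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, PointMassPrior(0.1), PointMassPrior(7.5))
        freq = power_pg(surr_design, VarianceComponents(7.5, 0.1), surr.da).power
        res = ep_icc_only(spec)
        assert res.ep == pytest.approx(freq, abs=1e-10)
        assert res.est_error == 0.0

    def test_uniform_icc_prior_matches_monte_carlo(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, BetaPrior(1, 1), PointMassPrior(7.5))
        quad = ep_icc_only(spec)
        mc = ep_monte_carlo(spec, draws=100_000, seed=11)
        assert abs(quad.ep - mc.ep) < 3 * mc.mc_se

    def test_tight_prior_stays_near_plug_in_power(self, surr, surr_design):
        spec = surr_spec(
            surr, surr_design, TruncatedNormalPrior(m=0.1, s=0.01), PointMassPrior(7.5)
        )
        freq = power_pg(surr_design, VarianceComponents(7.5, 0.1), surr.da).power
        assert abs(ep_icc_only(spec).ep - freq) < 0.005

    def test_requires_point_mass_sd(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, BetaPrior(1, 1), GammaPrior(75, 10))
        with pytest.raises(ValueError, match="point-mass"):
            ep_icc_only(spec)


class TestICCAndSD:
    def test_double_point_mass_is_frequentist_power(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, PointMassPrior(0.1), PointMassPrior(7.5))
        freq = power_pg(surr_design, VarianceComponents(7.5, 0.1), surr.da).power
        assert ep_icc_sd(spec).ep == pytest.approx(freq, abs=1e-10)

    def test_sd_prior_lowers_ep_for_pg_fixture(self, surr, surr_design):
        """Adding SD uncertainty weighs in low-power large-sigma scenarios."""
        icc = TruncatedNormalPrior(m=0.1, s=0.01)
        with_sd = ep_icc_sd(surr_spec(surr, surr_design, icc, GammaPrior(75, 10))).ep
        icc_only = ep_icc_only(surr_spec(surr, surr_design, icc, PointMassPrior(7.5))).ep
        assert with_sd < icc_only

    def test_tiny_sd_variance_converges_to_icc_only(self, surr, surr_design):
        icc = TruncatedNormalPrior(m=0.1, s=0.01)
        # Gamma with mean 7.5 and sd 1e-3
        sd = 1e-3
        k = (7.5 / sd) ** 2
        tight = GammaPrior(k=k, theta=k / 7.5)
        with_sd = ep_icc_sd(surr_spec(surr, surr_design, icc, tight)).ep
        icc_only = ep_icc_only(surr_spec(surr, surr_design, icc, PointMassPrior(7.5))).ep
        assert with_sd == pytest.approx(icc_only, abs=1e-4)

    def test_joint_quadrature_matches_monte_carlo(self, surr, surr_design):
        spec = surr_spec(
            surr, surr_design, TruncatedNormalPrior(m=0.1, s=0.05), GammaPrior(75, 10)
        )
        quad = ep_icc_sd(spec)
        mc = ep_monte_carlo(spec, draws=100_000, seed=5)
        assert abs(quad.ep - mc.ep) < max(3 * mc.mc_se, 1e-3)


class TestMonteCarlo:
    def test_point_mass_priors_exact(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, PointMassPrior(0.1), PointMassPrior(7.5))
        res = ep_monte_carlo(spec, draws=2000, seed=1)
        freq = power_pg(surr_design, VarianceComponents(7.5, 0.1), surr.da).power
        assert res.ep == pytest.approx(freq, abs=1e-12)
        assert res.mc_se <= 1e-15  # all draws identical up to summation roundoff

    def test_seed_stability(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, BetaPrior(2, 8), GammaPrior(75, 10))
        r1 = ep_monte_carlo(spec, draws=100_000, seed=1)
        r2 = ep_monte_carlo(spec, draws=100_000, seed=2)
        assert abs(r1.ep - r2.ep) < 6 * max(r1.mc_se, r2.mc_se)

    def test_minimum_draws_enforced(self, surr, surr_design):
        spec = surr_spec(surr, surr_design, BetaPrior(2, 8), GammaPrior(75, 10))
        with pytest.raises(ValueError):
            ep_monte_carlo(spec, draws=10, seed=1)


class TestEPProperties:
    def test_ep_nondecreasing_in_clusters(self, surr):
        """More clusters never reduce expected power (basis of the search)."""
        icc = TruncatedNormalPrior(m=0.1, s=0.05)
        eps = []
        for C in range(2, 101, 2):
            d = make_pg_design(C, surr.n)
            spec = HybridSpec(design=d, da=surr.da, icc_prior=icc, sd_prior=PointMassPrior(7.5))
            eps.append(ep_icc_only(spec).ep)
        assert np.all(np.diff(eps) >= -1e-12)

    def test_ep_approaches_one_for_large_c(self, surr):
        d = make_pg_design(10_000, surr.n)
        spec = HybridSpec(
            design=d,
            da=surr.da,
            icc_prior=TruncatedNormalPrior(m=0.1, s=0.05),
            sd_prior=GammaPrior(75, 10),
        )
        assert ep_icc_sd(spec).ep > 0.999

    def test_quadrature_oracle_agreement_random_specs(self, rng):
        """Deterministic quadrature matches Monte Carlo on 20 random specs."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for i in range(20):
                spec = random_hybrid_spec(rng)
                quad = expected_power(spec)
                mc = ep_monte_carlo(spec, draws=100_000, seed=1000 + i)
                assert abs(quad.ep - mc.ep) < max(3 * mc.mc_se, 1e-3), spec

    def test_degenerate_prior_identity_random_configs(self, rng):
        """Point-mass priors reduce EP to frequentist power on random designs."""
        from crthybrid import power_sw, make_sw_design

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(10):
                spec = random_hybrid_spec(rng, families=("point",), sd_families=("point",))
                rho = spec.icc_prior.value
                sigma = spec.sd_prior.value
                vc = VarianceComponents(sigma, rho)
                if spec.design.__class__.__name__ == "PGDesign":
                    freq = power_pg(spec.design, vc, spec.da).power
                else:
                    freq = power_sw(spec.design, vc, spec.da).power
                assert expected_power(spec).ep == pytest.approx(freq, abs=1e-10)

    def test_tn_and_beta_matched_moments_give_similar_ep(self, surr, surr_design):
        """Moment-matched TN and Beta ICC priors yield nearly identical EP."""
        tn = TruncatedNormalPrior(m=0.1, s=0.05)
        mean, var = tn.moments()
        # Beta by method of moments
        t = mean * (1 - mean) / var - 1
        beta = BetaPrior(a=mean * t, b=(1 - mean) * t)
        ep_tn = ep_icc_only(surr_spec(surr, surr_design, tn, PointMassPrior(7.5))).ep
        ep_beta = ep_icc_only(surr_spec(surr, surr_design, beta, PointMassPrior(7.5))).ep
        assert abs(ep_tn - ep_beta) < 0.01
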