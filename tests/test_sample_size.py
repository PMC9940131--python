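import math
import warnings

import numpy as np
import pytest
from scipy import stats

from crthybrid import (
    DesignAssumptions,
    GammaPrior,
    PointMassPrior,
    TruncatedNormalPrior,
    VarianceComponents,
    make_pg_design,
    make_sw_design,
    min_cluster_size,
    min_clusters_freq,
    min_clusters_hybrid,
    power_pg,
    power_sw,
)
from crthybrid.sample_size import SampleSizeError


class TestMinClustersFrequentist:
    def test_pg_motivating_trial(self, surr):
        """Closed-form inversion gives 47.76 clusters, rounded up to even 48."""
        res = min_clusters_freq("pg", surr.n, None, surr.vc, surr.da)
        assert res.C == 48
        assert res.achieved >= 0.9
        # minimality: two fewer clusters fails the target
        d = make_pg_design(46, surr.n)
        assert power_pg(d, surr.vc, surr.da).power < 0.9

    def test_pg_actual_trial_size_passes(self, surr, surr_design):
        assert power_pg(surr_design, surr.vc, surr.da).power >= 0.9

    def test_unclustered_matches_textbook_formula(self):
        vc = VarianceComponents(1.0, 0.0)
        da = DesignAssumptions(delta=0.5, alpha=0.025, beta=0.1)
        res = min_clusters_freq("pg", 1, None, vc, da)
        z = stats.norm.ppf
        exact = 4 * (z(0.975) + z(0.9)) ** 2 / 0.5**2
        expected = 2 * math.ceil(exact / 2)
        assert res.C == expected

    def test_sw_motivating_trial(self, ogrady):
        res = min_clusters_freq("sw", ogrady.n, ogrady.T, ogrady.vc, ogrady.da)
        assert res.C <= 30  # the trial used 30 clinics
        assert res.C % (ogrady.T - 1) == 0
        assert power_sw(
            make_sw_design(30, ogrady.T, ogrady.n), ogrady.vc, ogrady.da
        ).power >= 0.8

    def test_minimality_of_returned_count(self, ogrady):
        res = min_clusters_freq("sw", ogrady.n, ogrady.T, ogrady.vc, ogrady.da)
        step = ogrady.T - 1
        if res.C > step:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                smaller = power_sw(
                    make_sw_design(res.C - step, ogrady.T, ogrady.n), ogrady.vc, ogrady.da
                ).power
            assert smaller < 0.8

    def test_unreachable_target_raises(self):
        vc = VarianceComponents(10.0, 0.5)
        da = DesignAssumptions(delta=0.01, alpha=0.025, beta=0.1)
        with pytest.raises(SampleSizeError):
            min_clusters_freq("pg", 2, None, vc, da, c_max=1000)


class TestMinClustersHybrid:
    def test_point_mass_priors_reproduce_frequentist(self, surr):
        freq = min_clusters_freq("pg", surr.n, None, surr.vc, surr.da)
        hyb = min_clusters_hybrid(
            "pg", surr.n, None, surr.da, PointMassPrior(0.1), PointMassPrior(7.5)
        )
        assert hyb.C == freq.C
        assert hyb.achieved == pytest.approx(freq.achieved, abs=1e-10)

    def test_point_mass_coincidence_random_configs(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 15))
            sigma = float(rng.uniform(0.5, 3))
            rho = float(rng.uniform(0.01, 0.3))
            da = DesignAssumptions(
                delta=float(rng.uniform(0.3, 0.8)) * sigma, alpha=0.025, beta=0.1
            )
            vc = VarianceComponents(sigma, rho)
            freq = min_clusters_freq("pg", n, None, vc, da)
            hyb = min_clusters_hybrid(
                "pg", n, None, da, PointMassPrior(rho), PointMassPrior(sigma)
            )
            assert hyb.C == freq.C

    def test_tight_icc_prior_lowers_required_clusters(self, surr):
        """A small-variance ICC prior needs no more clusters than frequentist."""
        freq = min_clusters_freq("pg", surr.n, None, surr.vc, surr.da)
        hyb = min_clusters_hybrid(
            "pg", surr.n, None, surr.da,
            TruncatedNormalPrior(m=0.1, s=0.01), PointMassPrior(7.5),
        )
        assert hyb.C <= freq.C

    def test_sd_prior_requires_at_least_icc_only_clusters(self, surr):
        icc = TruncatedNormalPrior(m=0.1, s=0.01)
        icc_only = min_clusters_hybrid("pg", surr.n, None, surr.da, icc, PointMassPrior(7.5))
        with_sd = min_clusters_hybrid("pg", surr.n, None, surr.da, icc, GammaPrior(75, 10))
        assert with_sd.C >= icc_only.C

    def test_raising_ep_target_never_decreases_c(self, surr):
        icc = TruncatedNormalPrior(m=0.1, s=0.05)
        counts = []
        for gamma in (0.2, 0.1, 0.05):
            da = DesignAssumptions(delta=surr.da.delta, alpha=surr.da.alpha,
                                   beta=surr.da.beta, gamma=gamma)
            counts.append(
                min_clusters_hybrid("pg", surr.n, None, da, icc, PointMassPrior(7.5)).C
            )
        assert counts == sorted(counts)


class TestMinClusterSize:
    def test_pg_motivating_trial_size(self, surr):
        res = min_cluster_size("pg", 50, None, surr.vc, surr.da)
        assert res.n <= 11  # the trial used 11 per cluster
        assert power_pg(make_pg_design(50, res.n), surr.vc, surr.da).power >= 0.9
        if res.n > 1:
            assert power_pg(make_pg_design(50, res.n - 1), surr.vc, surr.da).power < 0.9

    def test_unclustered_formula(self):
        vc = VarianceComponents(1.0, 0.0)
        da = DesignAssumptions(delta=0.5, alpha=0.025, beta=0.1)
        res = min_cluster_size("pg", 2, None, vc, da)
        z = stats.norm.ppf
        exact = 4 * (z(0.975) + z(0.9)) ** 2 / (2 * 0.5**2)
        assert res.n == math.ceil(exact)

    def test_pg_power_asymptote_reported(self):
        """At fixed C the PG power is bounded; the bound is reported on failure."""
        vc = VarianceComponents(2.0, 0.5)
        da = DesignAssumptions(delta=0.5, alpha=0.025, beta=0.1)
        C = 4
        limit = stats.norm.cdf(
            0.5 * math.sqrt(C / (4 * 0.5 * 4.0)) - stats.norm.ppf(0.975)
        )
        with pytest.raises(SampleSizeError, match="bounded") as exc:
            min_cluster_size("pg", C, None, vc, da, n_max=10**6)
        reported = float(str(exc.value).split("bounded at ")[1].split(" ")[0])
        assert reported == pytest.approx(limit, abs=1e-3)

    def test_hybrid_size_search_with_point_priors(self, surr):
        freq = min_cluster_size("pg", 50, None, surr.vc, surr.da)
        hyb = min_cluster_size(
            "pg", 50, None, None, surr.da,
            framework="hybrid", icc_prior=PointMassPrior(0.1), sd_prior=PointMassPrior(7.5),
        )
        assert hyb.n == freq.n

    def test_sw_size_search(self, ogrady):
        res = min_cluster_size("sw", ogrady.C, ogrady.T, ogrady.vc, ogrady.da)
        assert res.n <= ogrady.n
        assert res.achieved >= 0.8


class TestResultInvariants:
    def test_total_n_accounting(self, surr, ogrady):
        pg = min_clusters_freq("pg", surr.n, None, surr.vc, surr.da)
        assert pg.total_N == pg.C * pg.n
        sw = min_clusters_freq("sw", ogrady.n, ogrady.T, ogrady.vc, ogrady.da)
        assert sw.total_N == sw.C * sw.n * ogrady.T

    def test_pg_count_is_even(self, surr):
        res = min_clusters_freq("pg", surr.n, None, surr.vc, surr.da)
        assert res.C % 2 == 0
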