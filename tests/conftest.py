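import numpy as np
import pytest

from crthybrid import (
    DesignAssumptions,
    HybridSpec,
    PointMassPrior,
    VarianceComponents,
    make_pg_design,
    make_sw_design,
)
from crthybrid.fixtures import get_fixture


@pytest.fixture(scope="session")
def surr():
    """PG motivating trial: 50 care homes of 11, delta 3, SD 7.5, ICC 0.1."""
    return get_fixture("surr")


@pytest.fixture(scope="session")
def ogrady():
    """SW motivating trial: 30 clinics, 7 periods, 132 per clinic-period."""
    return get_fixture("ogrady")


@pytest.fixture(scope="session")
def surr_design(surr):
    return make_pg_design(surr.C, surr.n)


@pytest.fixture(scope="session")
def ogrady_design(ogrady):
    return make_sw_design(ogrady.C, ogrady.T, ogrady.n)


@pytest.fixture
def rng():
    return np.random.default_rng(20220901)


def random_hybrid_spec(rng, families=("tn", "beta", "point"), sd_families=("gamma", "point")):
    """Draw a random small design with random ICC/SD priors (test helper)."""
    from crthybrid import BetaPrior, GammaPrior, TruncatedNormalPrior

    kind = rng.choice(["pg", "sw"])
    if kind == "pg":
        design = make_pg_design(int(2 * rng.integers(2, 16)), int(rng.integers(2, 20)))
    else:
        T = int(rng.integers(3, 7))
        design = make_sw_design(int((T - 1) * rng.integers(1, 6)), T, int(rng.integers(2, 20)))
    sigma = float(rng.uniform(0.5, 5.0))
    da = DesignAssumptions(
        delta=float(rng.uniform(0.2, 1.0)) * sigma,
        alpha=float(rng.uniform(0.005, 0.05)),
        beta=0.1,
    )
    fam = rng.choice(families)
    if fam == "tn":
        icc = TruncatedNormalPrior(m=float(rng.uniform(0.02, 0.4)), s=float(rng.uniform(0.01, 0.3)))
    elif fam == "beta":
        icc = BetaPrior(a=float(rng.uniform(0.5, 5)), b=float(rng.uniform(2, 30)))
    else:
        icc = PointMassPrior(float(rng.uniform(0.01, 0.4)))
    sd_fam = rng.choice(sd_families)
    if sd_fam == "gamma":
        k = float(rng.uniform(3, 80))
        sd = GammaPrior(k=k, theta=k / sigma)  # mean at sigma
    else:
        sd = PointMassPrior(sigma)
    return HybridSpec(design=design, da=da, icc_prior=icc, sd_prior=sd)
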