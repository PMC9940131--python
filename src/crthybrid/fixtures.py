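"""Built-in parameter sets for the two motivating trials.

``surr`` — a parallel-group CRT of Dementia Care Mapping to reduce agitation
in care-home residents: 50 care homes, 11 participants each, powered at 90%
(one-sided alpha 0.025) for a 3-point difference with SD 7.5 and assumed
ICC 0.1.

``ogrady`` — a stepped-wedge CRT improving outpatient substance-use-disorder
treatment: 30 clinics over 7 periods (5 clinics start the intervention at
each of periods 2-7), 132 participants per clinic-period, powered at 80%
(one-sided alpha 0.005) for delta 0.0278 with SD 0.426 and assumed ICC 0.2.

The attached priors are the "correctly specified" choices: a truncated
Normal on the ICC with mode at the point estimate and scale 0.01, and a
Gamma on the SD — Gamma(75, rate 10) for the PG trial and Gamma(17.32, rate
40) for the SW trial, stored verbatim.  (The latter has mode 0.408, slightly
off the point estimate 0.426; see docs/methods.md.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .power import DesignAssumptions, VarianceComponents
from .priors import GammaPrior, Prior, TruncatedNormalPrior

__all__ = ["Fixture", "FIXTURES", "get_fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str  # "pg" | "sw"
    C: int
    n: float
    T: int | None
    vc: VarianceComponents
    da: DesignAssumptions
    icc_prior: Prior = field(repr=False)
    sd_prior: Prior = field(repr=False)


FIXTURES: dict[str, Fixture] = {
    "surr": Fixture(
        name="surr",
        kind="pg",
        C=50,
        n=11,
        T=None,
        vc=VarianceComponents(sigma=7.5, rho=0.1),
        da=DesignAssumptions(delta=3.0, alpha=0.025, beta=0.1),
        icc_prior=TruncatedNormalPrior(m=0.1, s=0.01),
        sd_prior=GammaPrior(k=75.0, theta=10.0),
    ),
    "ogrady": Fixture(
        name="ogrady",
        kind="sw",
        C=30,
        n=132,
        T=7,
        vc=VarianceComponents(sigma=0.426, rho=0.2),
        da=DesignAssumptions(delta=0.0278, alpha=0.005, beta=0.2),
        icc_prior=TruncatedNormalPrior(m=0.2, s=0.01),
        sd_prior=GammaPrior(k=17.32, theta=40.0),
    ),
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
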