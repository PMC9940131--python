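"""Minimal-design search under frequentist power or expected-power control.

Both the frequentist power and the expected power are non-decreasing in the
number of clusters ``C`` (and in the cluster(-period) size ``n`` for the
stepped wedge), so the smallest admissible design can be found by geometric
bracketing followed by bisection over the admissible step lattice:

* PG designs step in 2s (exact 1:1 allocation),
* standard SW designs step in ``T - 1`` (equal clusters per step) unless
  ``allow_unequal`` permits step 1 with the remainder rule.

For a parallel-group design at fixed ``C`` the power is *bounded* as the
cluster size grows — with ICC ``rho > 0`` the variance tends to
``4 rho sigma^2 / C`` — so a per-cluster-size search can fail no matter how
large ``n`` becomes; that failure is reported with the asymptotic power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

from scipy import stats

from .designs import make_pg_design, make_sw_design
from .expected_power import HybridSpec, expected_power
from .power import DesignAssumptions, VarianceComponents, power_pg, power_sw
from .priors import PointMassPrior, Prior

__all__ = [
    "SampleSizeResult",
    "SampleSizeError",
    "min_clusters_freq",
    "min_clusters_hybrid",
    "min_cluster_size",
]

C_MAX_DEFAULT = 10**6
N_MAX_DEFAULT = 10**7


class SampleSizeError(RuntimeError):
    """Raised when no design within the search range attains the target."""


@dataclass(frozen=True)
class SampleSizeResult:
    C: int
    n: float
    achieved: float
    target: float
    framework: str  # "frequentist" | "hybrid"
    design_kind: str  # "pg" | "sw"
    total_N: float

    def __post_init__(self) -> None:
        if self.achieved < self.target:
            raise ValueError("returned design does not meet the target (internal error)")


def _search_min(
    achieved: Callable[[int], float],
    target: float,
    step: int,
    start: int,
    upper: int,
    what: str,
) -> tuple[int, float]:
    """Smallest multiple-of-step count >= start with achieved(count) >= target.

    Monotonicity of ``achieved`` is relied on: geometric doubling brackets the
    answer, bisection on the step lattice pins it down, and minimality is
    confirmed directly against the next-smaller admissible count.
    """
    c = start
    val = achieved(c)
    if val >= target:
        return c, val
    lo = c  # fails
    while True:
        c = min(2 * c, upper + step)
        if c > upper:
            raise SampleSizeError(
                f"{what}: target {target:.4f} not reached below {upper} "
                f"(supremum over range {achieved(upper - (upper % step) or step):.4f})"
            )
        val = achieved(c)
        if val >= target:
            hi = c
            break
        lo = c
    # bisect on multiples of step in (lo, hi]
    while hi - lo > step:
        mid = lo + ((hi - lo) // (2 * step)) * step
        if mid == lo:
            mid += step
        if achieved(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi, achieved(hi)


def _freq_power_fn(
    kind: str,
    n: float,
    T: int | None,
    vc: VarianceComponents,
    da: DesignAssumptions,
    allow_unequal: bool,
) -> Callable[[int], float]:
    if kind == "pg":
        def fn(C: int) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                d = make_pg_design(C, n)
                return power_pg(d, vc, da, force_unequal=allow_unequal).power
        return fn
    if kind == "sw":
        if T is None:
            raise ValueError("T is required for a stepped-wedge search")
        def fn(C: int) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                d = make_sw_design(C, T, n)
                return power_sw(d, vc, da).power
        return fn
    raise ValueError(f"unknown design kind {kind!r}")


def min_clusters_freq(
    kind: str,
    n: float,
    T: int | None,
    vc: VarianceComponents,
    da: DesignAssumptions,
    *,
    c_max: int = C_MAX_DEFAULT,
    allow_unequal: bool = False,
) -> SampleSizeResult:
    """Smallest cluster count with frequentist power >= 1 - beta.

    PG searches ascend in steps of 2 (1:1 allocation); SW searches in steps
    of ``T - 1`` (standard equal wedge) unless ``allow_unequal`` enables
    step 1 with remainder clusters assigned to the earliest steps.
    """
    if da.delta <= 0:
        raise ValueError("a power target needs delta > 0")
    step = 2 if kind == "pg" else (1 if allow_unequal else T - 1)
    start = 2 if kind == "pg" else max(T - 1, step)
    fn = _freq_power_fn(kind, n, T, vc, da, allow_unequal)
    C, achieved = _search_min(fn, da.target_power, step, start, c_max, f"{kind} frequentist search")
    total = C * n * (T if kind == "sw" else 1)
    return SampleSizeResult(C=C, n=n, achieved=achieved, target=da.target_power,
                            framework="frequentist", design_kind=kind, total_N=total)


def min_clusters_hybrid(
    kind: str,
    n: float,
    T: int | None,
    da: DesignAssumptions,
    icc_prior: Prior,
    sd_prior: Prior,
    *,
    c_max: int = C_MAX_DEFAULT,
    allow_unequal: bool = False,
) -> SampleSizeResult:
    """Smallest cluster count with expected power >= 1 - gamma."""
    if da.delta <= 0:
        raise ValueError("a power target needs delta > 0")
    step = 2 if kind == "pg" else (1 if allow_unequal else T - 1)
    start = 2 if kind == "pg" else max(T - 1, step)

    def fn(C: int) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            if kind == "pg":
                d = make_pg_design(C, n)
            else:
                d = make_sw_design(C, T, n)
        spec = HybridSpec(design=d, da=da, icc_prior=icc_prior, sd_prior=sd_prior)
        return expected_power(spec).ep

    C, achieved = _search_min(fn, da.target_ep, step, start, c_max, f"{kind} hybrid search")
    total = C * n * (T if kind == "sw" else 1)
    return SampleSizeResult(C=C, n=n, achieved=achieved, target=da.target_ep,
                            framework="hybrid", design_kind=kind, total_N=total)


def min_cluster_size(
    kind: str,
    C: int,
    T: int | None,
    vc: VarianceComponents | None,
    da: DesignAssumptions,
    *,
    framework: str = "frequentist",
    icc_prior: Prior | None = None,
    sd_prior: Prior | None = None,
    n_max: int = N_MAX_DEFAULT,
    allow_unequal: bool = False,
) -> SampleSizeResult:
    """Smallest integer cluster(-period) size meeting the target at fixed ``C``.

    Raises :class:`SampleSizeError` with the asymptotic power when the target
    is unreachable however large ``n`` grows (PG designs with ``rho > 0``
    have power bounded by ``Phi(delta * sqrt(C / (4 rho sigma^2)) - z)``).
    """
    if da.delta <= 0:
        raise ValueError("a power target needs delta > 0")
    if framework == "frequentist":
        if vc is None:
            raise ValueError("frequentist search needs VarianceComponents")
        target = da.target_power

        def achieved(n: int) -> float:
            return _freq_power_fn(kind, n, T, vc, da, allow_unequal)(C)
    elif framework == "hybrid":
        if icc_prior is None or sd_prior is None:
            raise ValueError("hybrid search needs both priors")
        target = da.target_ep

        def achieved(n: int) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                d = make_pg_design(C, n) if kind == "pg" else make_sw_design(C, T, n)
            return expected_power(
                HybridSpec(design=d, da=da, icc_prior=icc_prior, sd_prior=sd_prior)
            ).ep
    else:
        raise ValueError(f"unknown framework {framework!r}")

    n = 1
    val = achieved(n)
    if val < target:
        lo = n
        while True:
            n *= 2
            if n > n_max:
                # near-asymptotic power at an effectively infinite cluster size
                sup = achieved(10**12)
                raise SampleSizeError(
                    f"{kind} size search at C={C}: power is bounded at "
                    f"{sup:.4f} < target {target:.4f} as n grows"
                )
            val = achieved(n)
            if val >= target:
                hi = n
                break
            lo = n
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if achieved(mid) >= target:
                hi = mid
            else:
                lo = mid
        n, val = hi, achieved(hi)
    total = C * n * (T if kind == "sw" else 1)
    return SampleSizeResult(C=C, n=n, achieved=val, target=target,
                            framework=framework, design_kind=kind, total_N=total)
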