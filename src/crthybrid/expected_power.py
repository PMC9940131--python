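"""Expected power: frequentist power averaged over design-parameter priors.

The expected power (EP) of a design is the prior-weighted average of its
frequentist power, taken over the ICC alone,

    EP = \\int_0^1 P(delta, n, X, alpha, sigma, rho) psi_ICC(rho) d rho,

or jointly over the ICC and the outcome SD,

    EP = \\int_0^inf \\int_0^1 P(...) psi_ICC(rho) psi_SD(sigma) d rho d sigma.

Integrals are computed by quantile-transform Gauss-Legendre quadrature:
substituting ``rho = Q_ICC(v)`` (and ``sigma = Q_SD(t)``) turns each prior
integral into an integral over the unit probability scale, which copes with
Beta endpoint singularities and the Gamma's unbounded support with no domain
cutoff.  Convergence is checked by doubling the node count; a Monte-Carlo
estimator over joint prior draws serves as an independent stochastic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .designs import PGDesign, SWDesign
from .power import (
    DesignAssumptions,
    normal_power_value,
    pg_variance_value,
    sw_variance_value,
)
from .priors import PointMassPrior, Prior

__all__ = [
    "HybridSpec",
    "EPResult",
    "QuadratureError",
    "ep_icc_only",
    "ep_icc_sd",
    "ep_monte_carlo",
    "expected_power",
]

DEFAULT_NODES = 129
DEFAULT_TOL = 1e-6
MAX_NODES = 4129


class QuadratureError(RuntimeError):
    """Raised when the EP quadrature fails its convergence check."""


@dataclass(frozen=True)
class HybridSpec:
    """A design plus the priors describing uncertainty in its ICC and SD.

    ``sd_prior`` may be a :class:`~crthybrid.priors.PointMassPrior`, in which
    case the SD is treated as known and the ICC-only formula applies.
    """

    design: PGDesign | SWDesign
    da: DesignAssumptions
    icc_prior: Prior
    sd_prior: Prior

    def __post_init__(self) -> None:
        lo, hi = self.icc_prior.support
        if lo < 0 or hi > 1:
            raise ValueError("ICC prior support must lie within [0, 1]")
        if self.sd_prior.support[0] < 0 or (
            isinstance(self.sd_prior, PointMassPrior) and self.sd_prior.value <= 0
        ):
            raise ValueError("SD prior support must lie within (0, inf)")

    @property
    def sd_is_point(self) -> bool:
        return isinstance(self.sd_prior, PointMassPrior)


@dataclass(frozen=True)
class EPResult:
    ep: float
    nodes_rho: int
    nodes_sigma: int
    est_error: float
    method: str  # "quadrature" | "monte_carlo"
    mc_se: float | None = None


def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights shifted to (0, 1)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def power_function(spec: HybridSpec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Vectorised ``(rho, sigma) -> power`` for a HybridSpec's design."""
    d = spec.design
    da = spec.da
    if isinstance(d, PGDesign):
        def fn(rho, sigma):
            return normal_power_value(da.delta, pg_variance_value(d.C, d.n, rho, sigma), da.alpha)
    else:
        s = d.summaries
        def fn(rho, sigma):
            var = sw_variance_value(d.C, d.T, d.n, s.U, s.W, s.V, rho, sigma)
            return normal_power_value(da.delta, var, da.alpha)
    return fn


def _quad_1d(fn, icc_prior: Prior, sigma: float, nodes: int) -> float:
    v, w = _gauss_legendre_01(nodes)
    rho = np.asarray(icc_prior.ppf(v), dtype=float)
    return float(np.dot(w, fn(rho, sigma)))


def _quad_2d(fn, icc_prior: Prior, sd_prior: Prior, nodes: int) -> float:
    v, w = _gauss_legendre_01(nodes)
    rho = np.asarray(icc_prior.ppf(v), dtype=float)
    sigma = np.asarray(sd_prior.ppf(v), dtype=float)
    vals = fn(rho[None, :], sigma[:, None])  # (sigma, rho) grid
    return float(w @ vals @ w)


def _converge(evaluate, nodes: int, tol: float, what: str) -> tuple[float, int, float]:
    """Double the node count until two successive estimates agree within tol."""
    prev = evaluate(nodes)
    while True:
        nodes2 = 2 * nodes
        cur = evaluate(nodes2)
        err = abs(cur - prev)
        if err < tol:
            return cur, nodes2, err
        if nodes2 > MAX_NODES:
            raise QuadratureError(
                f"{what} quadrature failed to converge: |Delta|={err:.3e} at "
                f"{nodes2} nodes (tol {tol:.1e})"
            )
        prev, nodes = cur, nodes2


def ep_icc_only(
    spec: HybridSpec,
    *,
    nodes: int = DEFAULT_NODES,
    tol: float = DEFAULT_TOL,
) -> EPResult:
    """EP with a prior on the ICC and the SD held fixed (point mass)."""
    if not spec.sd_is_point:
        raise ValueError("ep_icc_only requires a point-mass SD prior")
    sigma = spec.sd_prior.value
    fn = power_function(spec)
    if isinstance(spec.icc_prior, PointMassPrior):
        ep = float(np.asarray(fn(np.asarray(spec.icc_prior.value), sigma)))
        return EPResult(ep=ep, nodes_rho=1, nodes_sigma=1, est_error=0.0, method="quadrature")
    ep, used, err = _converge(
        lambda k: _quad_1d(fn, spec.icc_prior, sigma, k), nodes, tol, "ICC-only EP"
    )
    return EPResult(ep=min(max(ep, 0.0), 1.0), nodes_rho=used, nodes_sigma=1,
                    est_error=err, method="quadrature")


def ep_icc_sd(
    spec: HybridSpec,
    *,
    nodes: int = DEFAULT_NODES,
    tol: float = DEFAULT_TOL,
) -> EPResult:
    """EP with joint (independent) priors on the ICC and the SD."""
    if spec.sd_is_point:
        return ep_icc_only(spec, nodes=nodes, tol=tol)
    fn = power_function(spec)
    if isinstance(spec.icc_prior, PointMassPrior):
        rho0 = spec.icc_prior.value
        ep, used, err = _converge(
            lambda k: _sd_only(fn, rho0, spec.sd_prior, k), nodes, tol, "SD-only EP"
        )
        return EPResult(ep=min(max(ep, 0.0), 1.0), nodes_rho=1, nodes_sigma=used,
                        est_error=err, method="quadrature")
    ep, used, err = _converge(
        lambda k: _quad_2d(fn, spec.icc_prior, spec.sd_prior, k), nodes, tol, "ICC+SD EP"
    )
    return EPResult(ep=min(max(ep, 0.0), 1.0), nodes_rho=used, nodes_sigma=used,
                    est_error=err, method="quadrature")


def _sd_only(fn, rho0: float, sd_prior: Prior, nodes: int) -> float:
    v, w = _gauss_legendre_01(nodes)
    sigma = np.asarray(sd_prior.ppf(v), dtype=float)
    return float(np.dot(w, fn(np.full_like(sigma, rho0), sigma)))


def expected_power(spec: HybridSpec, **kwargs) -> EPResult:
    """Dispatch to the ICC-only or joint formula based on the SD prior."""
    if spec.sd_is_point:
        return ep_icc_only(spec, **kwargs)
    return ep_icc_sd(spec, **kwargs)


def ep_monte_carlo(spec: HybridSpec, draws: int = 100_000, seed: int = 0) -> EPResult:
    """Monte-Carlo EP over joint prior draws; stochastic oracle for the quadrature."""
    if draws < 1000:
        raise ValueError(f"draws must be >= 1000, got {draws}")
    rng = np.random.default_rng(seed)
    rho = np.asarray(spec.icc_prior.rvs(draws, rng), dtype=float)
    sigma = np.asarray(spec.sd_prior.rvs(draws, rng), dtype=float)
    vals = power_function(spec)(rho, sigma)
    ep = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(draws))
    return EPResult(ep=ep, nodes_rho=draws, nodes_sigma=draws, est_error=3 * se,
                    method="monte_carlo", mc_se=se)
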