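"""Closed-form variances and one-sided frequentist power for cluster trials.

Both designs are analysed with a linear mixed model: a random cluster
intercept with variance ``sigma_c^2 = rho * sigma^2`` and residual variance
``sigma_e^2 = (1 - rho) * sigma^2``, where ``rho`` is the intra-cluster
correlation (ICC) and ``sigma`` the total outcome SD.  The stepped-wedge
model additionally carries fixed period effects.

The treatment effect ``mu`` is tested one-sided (H0: mu <= 0), rejecting when
``Z = mu_hat / sqrt(Var(mu_hat)) > z_{1-alpha}``, so power at a target
difference ``delta`` is ``Phi(delta / sqrt(Var) - z_{1-alpha})``.

``Var(mu_hat)`` has well-known closed forms:

* PG, 1:1 allocation:  ``4 {1 + (n-1) rho} sigma^2 / (C n)``
* SW (Hussey-Hughes):
  ``C sigma^2 (1-rho) [1 + rho(nT-1)] /
  ( n { [1 + rho(nT-1)] (CU - W) + n rho (U^2 - CV) } )``

with ``U``, ``W``, ``V`` the design summaries of the treatment matrix.
:func:`gls_oracle_var` re-derives both variances from the generalized
least-squares information matrix on cluster(-period) means and is used as an
independent numerical check of the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .designs import DesignError, PGDesign, SWDesign, compute_summaries

__all__ = [
    "VarianceComponents",
    "DesignAssumptions",
    "PowerResult",
    "var_pg",
    "var_sw",
    "power_pg",
    "power_sw",
    "gls_oracle_var",
]

Design = Union[PGDesign, SWDesign]


@dataclass(frozen=True)
class VarianceComponents:
    """Total SD and ICC, with the implied between/within split."""

    sigma: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0 <= self.rho <= 1:
            raise ValueError(f"ICC must lie in [0, 1], got {self.rho}")

    @property
    def sigma_c2(self) -> float:
        """Between-cluster variance ``rho * sigma^2``."""
        return self.rho * self.sigma**2

    @property
    def sigma_e2(self) -> float:
        """Within-cluster (residual) variance ``(1 - rho) * sigma^2``."""
        return (1 - self.rho) * self.sigma**2


@dataclass(frozen=True)
class DesignAssumptions:
    """Effect size and error rates for a power or expected-power calculation.

    ``alpha`` is one-sided.  ``gamma`` is the type-II rate used for the
    expected-power target and defaults to ``beta``, mirroring the usual
    pragmatic choice in the hybrid framework.
    """

    delta: float
    alpha: float
    beta: float = 0.1
    gamma: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.gamma is not None and not 0 < self.gamma < 1:
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")

    @property
    def gamma_resolved(self) -> float:
        return self.beta if self.gamma is None else self.gamma

    @property
    def target_power(self) -> float:
        return 1 - self.beta

    @property
    def target_ep(self) -> float:
        return 1 - self.gamma_resolved


@dataclass(frozen=True)
class PowerResult:
    variance: float
    power: float
    design_kind: str  # "pg" | "sw"


# ---------------------------------------------------------------------------
# vectorised kernels (rho / sigma may be arrays; used by expected_power)

def pg_variance_value(C, n, rho, sigma):
    """PG variance, broadcasting over ``rho`` and ``sigma``."""
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return 4.0 * (1.0 + (n - 1.0) * rho) * sigma**2 / (C * n)


def sw_variance_value(C, T, n, U, W, V, rho, sigma):
    """Hussey-Hughes SW variance, broadcasting over ``rho`` and ``sigma``.

    At ``rho = 1`` the value is 0 by continuity (the ``1 - rho`` numerator
    factor); the power convention there is 1.
    """
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    f = 1.0 + rho * (n * T - 1.0)
    num = C * sigma**2 * (1.0 - rho) * f
    den = n * (f * (C * U - W) + n * rho * (U**2 - C * V))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(rho >= 1.0, 0.0, num / den)
    return var


def normal_power_value(delta, variance, alpha):
    """One-sided power ``Phi(delta / sqrt(Var) - z_{1-alpha})``.

    Zero variance maps to power 1 (for ``delta > 0``), the continuity
    convention for the ICC -> 1 limit of the stepped wedge.
    """
    variance = np.asarray(variance, dtype=float)
    z = stats.norm.ppf(1.0 - alpha)
    with np.errstate(divide="ignore"):
        snr = np.where(variance > 0, delta / np.sqrt(np.where(variance > 0, variance, 1.0)), np.inf)
    return stats.norm.cdf(snr - z)


# ---------------------------------------------------------------------------
# public scalar API

def var_pg(design: PGDesign, vc: VarianceComponents, *, force_unequal: bool = False) -> float:
    """Variance of the treatment-effect estimator for a 1:1 PG design.

    Refuses odd ``C`` unless ``force_unequal=True``, since the formula assumes
    exactly equal arms.
    """
    if not design.balanced and not force_unequal:
        raise DesignError(
            f"C={design.C} is odd: the PG variance formula assumes equal arms; "
            "pass force_unequal=True to apply the equal-split approximation"
        )
    if design.C * design.n == 0:
        raise DesignError("empty design")
    return float(pg_variance_value(design.C, design.n, vc.rho, vc.sigma))


def var_sw(design: SWDesign, vc: VarianceComponents) -> float:
    """Hussey-Hughes variance for a stepped-wedge design.

    Returns 0 at ``rho = 1`` (continuity convention).  Raises for degenerate
    wedges where the information about the treatment effect is non-positive
    (e.g. an all-treated or all-control matrix).
    """
    s = design.summaries
    if vc.rho >= 1.0:
        return 0.0
    f = 1.0 + vc.rho * (design.n * design.T - 1.0)
    den = design.n * (f * (design.C * s.U - s.W) + design.n * vc.rho * (s.U**2 - design.C * s.V))
    if den <= 0:
        raise DesignError(
            f"degenerate wedge (C={design.C}, T={design.T}, U={s.U}, W={s.W}, "
            f"V={s.V}): non-positive information for the treatment effect"
        )
    num = design.C * vc.sigma**2 * (1.0 - vc.rho) * f
    return num / den


def power_pg(
    design: PGDesign,
    vc: VarianceComponents,
    da: DesignAssumptions,
    *,
    force_unequal: bool = False,
) -> PowerResult:
    """One-sided frequentist power of a PG design."""
    v = var_pg(design, vc, force_unequal=force_unequal)
    p = float(normal_power_value(da.delta, v, da.alpha))
    return PowerResult(variance=v, power=p, design_kind="pg")


def power_sw(design: SWDesign, vc: VarianceComponents, da: DesignAssumptions) -> PowerResult:
    """One-sided frequentist power of a stepped-wedge design."""
    v = var_sw(design, vc)
    p = float(normal_power_value(da.delta, v, da.alpha))
    return PowerResult(variance=v, power=p, design_kind="sw")


# ---------------------------------------------------------------------------
# GLS oracle

def gls_oracle_var(design: Design, vc: VarianceComponents) -> float:
    """Treatment-effect variance from first principles via GLS.

    Builds the linear model on cluster(-period) means — intercept, period
    indicators (SW only), treatment indicator — with covariance
    ``sigma_e^2 / n`` on the diagonal plus ``sigma_c^2`` between means from
    the same cluster, and returns the treatment entry of the inverse
    information matrix ``(X' Sigma^{-1} X)^{-1}``.

    Intended for small designs as an independent check of the closed forms.
    """
    if isinstance(design, PGDesign):
        C, T = design.C, 1
        treat = design.allocation.reshape(-1, 1).astype(float)
        cells = C
        Xmat = np.column_stack([np.ones(cells), treat.ravel()])
        cluster_of = np.arange(C)
    else:
        C, T = design.C, design.T
        cells = C * T
        treat = design.X.reshape(-1).astype(float)
        period = np.tile(np.arange(T), C)
        period_dummies = np.zeros((cells, T - 1))
        for k in range(1, T):
            period_dummies[period == k, k - 1] = 1.0
        Xmat = np.column_stack([np.ones(cells), period_dummies, treat])
        cluster_of = np.repeat(np.arange(C), T)

    sig_e2 = vc.sigma_e2 / design.n
    sig_c2 = vc.sigma_c2
    cov = sig_c2 * (cluster_of[:, None] == cluster_of[None, :]).astype(float)
    cov[np.diag_indices(cells)] += sig_e2

    try:
        cov_inv_X = np.linalg.solve(cov, Xmat)
    except np.linalg.LinAlgError as exc:
        raise DesignError(f"singular covariance for design {design!r}") from exc
    info = Xmat.T @ cov_inv_X
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise DesignError(f"singular information matrix for design {design!r}") from exc
    return float(info_inv[-1, -1])
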