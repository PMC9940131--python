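"""Design-stage prior distributions for the ICC and the outcome SD.

These priors quantify uncertainty in nuisance design parameters at the
planning stage; they are never updated to posteriors (the eventual analysis
remains frequentist).  Supported families:

* ``TruncatedNormalPrior`` — a Normal(m, s^2) truncated to [0, 1], the usual
  choice for the ICC.
* ``BetaPrior`` — Beta(a, b) on [0, 1], an alternative ICC prior.
* ``GammaPrior`` — Gamma(k, rate theta) on (0, inf) for the SD, with density
  proportional to ``sigma^(k-1) exp(-theta * sigma)``.  Parametrized by RATE;
  the constructor takes an explicit ``rate`` keyword to avoid the classic
  shape/scale ambiguity.
* ``PointMassPrior`` — a degenerate prior recovering the frequentist
  calculation exactly.

Each family exposes density, closed-form moments, mode, quantile (inverse
CDF) and seeded sampling.  Quantile functions enable quantile-transform
quadrature: integrals against the prior become integrals over the unit
probability scale, which handles Beta endpoint singularities (a < 1 or
b < 1) and the Gamma's unbounded support without domain cutoffs.

:func:`match_mode` constructs a prior whose mode equals a frequentist point
estimate ("correctly specified" prior) with a requested prior SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Prior",
    "TruncatedNormalPrior",
    "BetaPrior",
    "GammaPrior",
    "PointMassPrior",
    "InfeasiblePriorError",
    "density",
    "moments",
    "quantile",
    "sample",
    "match_mode",
    "parse_prior",
]

# SD of the uniform on [0,1]; the supremum prior SD reachable by [0,1]-supported
# families as they flatten out.
_UNIFORM_SD = 1.0 / math.sqrt(12.0)


class InfeasiblePriorError(ValueError):
    """Raised when no prior in the family attains the requested mode/SD."""


@dataclass(frozen=True)
class TruncatedNormalPrior:
    """Normal(m, s^2) truncated to [0, 1].

    ``m`` and ``s`` are the location and scale of the *untruncated* Normal;
    the truncated mean and SD differ whenever the truncation bites.
    """

    m: float
    s: float
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"scale must be positive, got s={self.s}")
        if (self.lo, self.hi) != (0.0, 1.0):
            raise ValueError("truncation bounds are fixed to [0, 1]")

    @property
    def l(self) -> float:  # noqa: E741 - field name from the standard notation
        return (self.lo - self.m) / self.s

    @property
    def u(self) -> float:
        return (self.hi - self.m) / self.s

    def _frozen(self):
        return stats.truncnorm(self.l, self.u, loc=self.m, scale=self.s)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z = stats.norm.cdf(self.u) - stats.norm.cdf(self.l)
        inside = (x >= self.lo) & (x <= self.hi)
        val = stats.norm.pdf((x - self.m) / self.s) / (self.s * z)
        return np.where(inside, val, 0.0)

    def moments(self) -> tuple[float, float]:
        """Closed-form truncated-Normal mean and variance."""
        l, u = self.l, self.u
        z = stats.norm.cdf(u) - stats.norm.cdf(l)
        phi_l, phi_u = stats.norm.pdf(l), stats.norm.pdf(u)
        mean = self.m + self.s * (phi_l - phi_u) / z
        var = self.s**2 * (1.0 + (l * phi_l - u * phi_u) / z - ((phi_l - phi_u) / z) ** 2)
        return float(mean), float(var)

    def mode(self) -> float:
        return float(min(max(self.m, self.lo), self.hi))

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, v):
        return self._frozen().ppf(v)

    def rvs(self, size: int, rng: np.random.Generator):
        return self._frozen().rvs(size=size, random_state=rng)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 1.0)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on [0, 1].

    Shapes below 1 (density unbounded at an endpoint) are allowed; all
    downstream integration is through the quantile transform, so the
    singularity never appears at a quadrature node.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"Beta shapes must be positive, got a={self.a}, b={self.b}")

    def _frozen(self):
        return stats.beta(self.a, self.b)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= 0) & (x <= 1)
        with np.errstate(divide="ignore"):
            val = self._frozen().pdf(np.clip(x, 0, 1))
        return np.where(inside, val, 0.0)

    def moments(self) -> tuple[float, float]:
        a, b = self.a, self.b
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        return float(mean), float(var)

    def mode(self) -> float:
        if self.a > 1 and self.b > 1:
            return (self.a - 1) / (self.a + self.b - 2)
        if self.a <= 1 and self.b > 1:
            return 0.0
        if self.a > 1 and self.b <= 1:
            return 1.0
        raise ValueError(f"Beta({self.a}, {self.b}) has no unique interior mode")

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, v):
        return self._frozen().ppf(v)

    def rvs(self, size: int, rng: np.random.Generator):
        return self._frozen().rvs(size=size, random_state=rng)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, 1.0)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior with shape ``k`` and RATE ``theta`` on (0, inf)."""

    k: float
    theta: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise ValueError(
                f"Gamma parameters must be positive, got k={self.k}, rate={self.theta}"
            )

    def _frozen(self):
        return stats.gamma(self.k, scale=1.0 / self.theta)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            val = self._frozen().pdf(np.clip(x, 0, None))
        return np.where(x >= 0, val, 0.0)

    def moments(self) -> tuple[float, float]:
        return self.k / self.theta, self.k / self.theta**2

    def mode(self) -> float:
        if self.k <= 1:
            return 0.0
        return (self.k - 1) / self.theta

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, v):
        return self._frozen().ppf(v)

    def rvs(self, size: int, rng: np.random.Generator):
        return self._frozen().rvs(size=size, random_state=rng)

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, math.inf)


@dataclass(frozen=True)
class PointMassPrior:
    """Degenerate prior concentrated at a single value.

    Plugging point masses into the hybrid machinery recovers the plain
    frequentist power calculation exactly.
    """

    value: float

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(x == self.value, np.inf, 0.0)

    def moments(self) -> tuple[float, float]:
        return float(self.value), 0.0

    def mode(self) -> float:
        return float(self.value)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return (x >= self.value).astype(float)

    def ppf(self, v):
        v = np.asarray(v, dtype=float)
        return np.full_like(v, self.value, dtype=float)

    def rvs(self, size: int, rng: np.random.Generator):
        return np.full(size, float(self.value))

    @property
    def support(self) -> tuple[float, float]:
        return (float(self.value), float(self.value))


Prior = Union[TruncatedNormalPrior, BetaPrior, GammaPrior, PointMassPrior]


# ---------------------------------------------------------------------------
# functional facade

def density(prior: Prior, x) -> np.ndarray | float:
    """Prior density at ``x``; 0 outside the support (quadrature-friendly)."""
    out = prior.pdf(x)
    return float(out) if np.isscalar(x) else out


def moments(prior: Prior) -> tuple[float, float]:
    """Closed-form (mean, variance) of the prior."""
    return prior.moments()


def quantile(prior: Prior, v) -> np.ndarray | float:
    """Inverse CDF at probability ``v``."""
    out = prior.ppf(v)
    return float(out) if np.isscalar(v) else out


def sample(prior: Prior, count: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``count`` reproducible samples from the prior."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.asarray(prior.rvs(count, rng), dtype=float)


# ---------------------------------------------------------------------------
# mode-matched construction ("correctly specified" priors)

def _tn_sd(m: float, s: float) -> float:
    return math.sqrt(TruncatedNormalPrior(m, s).moments()[1])


def match_mode(family: str, mode: float, sd: float) -> Prior:
    """Construct a prior whose mode equals ``mode`` and whose SD is ``sd``.

    A prior centred this way on the frequentist point estimate is a
    "correctly specified" prior: the most likely parameter value under the
    prior coincides with the value a conventional power calculation would
    plug in, while ``sd`` controls how much uncertainty surrounds it.

    Families: ``"tn"`` (numeric solve for the truncation-adjusted SD),
    ``"beta"`` (mode fixed by ``a = 1 + mode*t``, ``b = 1 + (1-mode)*t``,
    ``t`` solved from the SD), ``"gamma"`` (closed-form quadratic in
    ``sqrt(k)``), ``"point"`` (ignores ``sd``).
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    family = family.lower()
    if family == "point":
        return PointMassPrior(mode)
    if sd == 0:
        raise InfeasiblePriorError("sd=0 requests a point mass; use family='point'")

    if family == "tn":
        if not 0 < mode < 1:
            raise InfeasiblePriorError(f"TN mode must lie in (0, 1), got {mode}")
        # untruncated mode m equals the truncated mode whenever m is interior
        sup_sd = _tn_sd(mode, 1e3)  # flattens towards uniform on [0,1]
        if sd >= sup_sd:
            raise InfeasiblePriorError(
                f"TN prior with mode {mode} supports sd in (0, {sup_sd:.4f}), got {sd}"
            )
        s = optimize.brentq(lambda s_: _tn_sd(mode, s_) - sd, 1e-8, 1e3, xtol=1e-12)
        return TruncatedNormalPrior(m=mode, s=float(s))

    if family == "beta":
        if not 0 < mode < 1:
            raise InfeasiblePriorError(f"Beta mode must lie in (0, 1), got {mode}")
        if sd >= _UNIFORM_SD:
            raise InfeasiblePriorError(
                f"Beta prior with interior mode supports sd in (0, {_UNIFORM_SD:.4f}), got {sd}"
            )

        def beta_sd(t: float) -> float:
            a, b = 1 + mode * t, 1 + (1 - mode) * t
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

        t = optimize.brentq(lambda t_: beta_sd(t_) - sd, 1e-10, 1e12, xtol=1e-12, rtol=1e-14)
        return BetaPrior(a=1 + mode * t, b=1 + (1 - mode) * t)

    if family == "gamma":
        if mode <= 0:
            raise InfeasiblePriorError(f"Gamma mode must be positive, got {mode}")
        # mode = (k-1)/theta, sd = sqrt(k)/theta  =>  k - (mode/sd) sqrt(k) - 1 = 0
        r = mode / sd
        sqrt_k = (r + math.sqrt(r**2 + 4.0)) / 2.0
        k = sqrt_k**2
        theta = sqrt_k / sd
        return GammaPrior(k=k, theta=theta)

    raise ValueError(f"unknown prior family {family!r}")


# ---------------------------------------------------------------------------
# prior grammar:  family:key=value,...

_FAMILY_KEYS = {
    "tn": ({"m", "s"}, {"mode", "sd"}),
    "beta": ({"a", "b"}, {"mode", "sd"}),
    "gamma": ({"k", "rate"}, {"mode", "sd"}),
    "point": ({"value"}, set()),
}


def parse_prior(text: str) -> Prior:
    """Parse a prior specification string.

    Grammar: ``family:key=value,...`` with families ``tn`` (keys ``m``, ``s``),
    ``beta`` (``a``, ``b``), ``gamma`` (``k``, ``rate``) and ``point``
    (``value``).  The [0,1]- and (0,inf)-families alternatively accept
    ``mode`` and ``sd``, routed through :func:`match_mode`.

    Examples: ``tn:m=0.1,s=0.01`` — ``beta:a=2,b=8`` — ``gamma:k=75,rate=10``
    — ``point:value=7.5`` — ``tn:mode=0.1,sd=0.05``.
    """
    try:
        family, _, body = text.partition(":")
        family = family.strip().lower()
        if family not in _FAMILY_KEYS:
            raise ValueError(
                f"unknown prior family {family!r}; expected one of {sorted(_FAMILY_KEYS)}"
            )
        kv: dict[str, float] = {}
        for item in body.split(","):
            if not item.strip():
                continue
            key, _, val = item.partition("=")
            key = key.strip().lower()
            kv[key] = float(val)
    except ValueError:
        raise
    except Exception as exc:  # malformed structure
        raise ValueError(f"malformed prior specification {text!r}") from exc

    direct, moded = _FAMILY_KEYS[family]
    keys = set(kv)
    if keys == direct:
        if family == "tn":
            return TruncatedNormalPrior(m=kv["m"], s=kv["s"])
        if family == "beta":
            return BetaPrior(a=kv["a"], b=kv["b"])
        if family == "gamma":
            return GammaPrior(k=kv["k"], theta=kv["rate"])
        return PointMassPrior(value=kv["value"])
    if moded and keys == moded:
        return match_mode(family, kv["mode"], kv["sd"])
    raise ValueError(
        f"prior {text!r}: expected keys {sorted(direct)}"
        + (f" or {sorted(moded)}" if moded else "")
        + f", got {sorted(keys)}"
    )
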