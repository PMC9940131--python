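"""PG vs SW expected-power comparison over truncated-Normal ICC-prior grids.

On a common measurement budget — each cluster contributes ``N`` measurements,
so ``n = N`` for the parallel-group design and ``n = N / T`` per period for
the stepped wedge — the two designs are compared by their expected power
under a ``TN(0, 1, m, s^2)`` ICC prior, over a grid of the prior location
``m`` and scale ``s``.  The SD is held fixed; EP then depends on ``delta``
and ``sigma`` only through the standardized effect ``delta / sigma``, so the
grid is computed at ``sigma = 1``.

The equal-EP contour (where ``EP_PG - EP_SW = 0``) is extracted by bilinear
interpolation on grid cells; an empty contour means one design dominates
everywhere on the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import contourpy
import numpy as np
import pandas as pd
from scipy import stats

from .designs import make_sw_design
from .power import normal_power_value, pg_variance_value, sw_variance_value

__all__ = [
    "ComparisonGrid",
    "PGRegionSummary",
    "build_grid",
    "extract_contour",
    "summarize_pg_region",
    "default_m_values",
    "default_s_values",
]

#: grid resolution used for replication runs; coarser grids suit quick checks
REPLICATION_RES = 0.005


def default_m_values(res: float = REPLICATION_RES) -> np.ndarray:
    return np.arange(0.0, 0.5 + res / 2, res)


def default_s_values(res: float = REPLICATION_RES) -> np.ndarray:
    return np.arange(res, 0.5 + res / 2, res)


@dataclass(frozen=True)
class ComparisonGrid:
    """EP surfaces of the two designs over a (m, s) prior-parameter grid."""

    m_values: np.ndarray
    s_values: np.ndarray
    ep_pg: np.ndarray  # shape (len(m_values), len(s_values))
    ep_sw: np.ndarray
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.m_values), len(self.s_values))
        if self.ep_pg.shape != shape or self.ep_sw.shape != shape:
            raise ValueError("EP matrices must conform to the grid axes")

    @property
    def diff(self) -> np.ndarray:
        """``EP_PG - EP_SW``; positive where the parallel-group design wins."""
        return self.ep_pg - self.ep_sw

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns m, s, ep_pg, ep_sw, diff."""
        mm, ss = np.meshgrid(self.m_values, self.s_values, indexing="ij")
        return pd.DataFrame(
            {
                "m": mm.ravel(),
                "s": ss.ravel(),
                "ep_pg": self.ep_pg.ravel(),
                "ep_sw": self.ep_sw.ravel(),
                "diff": self.diff.ravel(),
            }
        )


@dataclass(frozen=True)
class PGRegionSummary:
    """Maxima of m and s over grid cells where the PG design has larger EP."""

    max_m: float | None
    max_s: float | None

    @property
    def empty(self) -> bool:
        return self.max_m is None


def _tn_quantiles(m: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """TN(0,1,m,s^2) quantiles on a (m, s, node) broadcast grid."""
    mm = m[:, None, None]
    ss = s[None, :, None]
    a = (0.0 - mm) / ss
    b = (1.0 - mm) / ss
    return stats.truncnorm.ppf(v[None, None, :], a, b, loc=mm, scale=ss)


def build_grid(
    C: int,
    N: float,
    T: int,
    effect: float,
    alpha: float,
    m_values: np.ndarray | None = None,
    s_values: np.ndarray | None = None,
    *,
    nodes: int = 129,
) -> ComparisonGrid:
    """Compute PG and SW expected power over a TN ICC-prior parameter grid.

    ``effect`` is the standardized effect size ``delta / sigma``; ``N`` is the
    common number of measurements per cluster, split as ``n = N / T`` per
    period in the stepped wedge (fractional ``n`` allowed).  Quadrature uses
    ``nodes`` Gauss-Legendre points with one doubling refinement, matching
    the per-spec expected-power routine.
    """
    if N < T:
        raise ValueError(f"need N >= T so the wedge has n >= 1, got N={N}, T={T}")
    m_values = default_m_values() if m_values is None else np.asarray(m_values, float)
    s_values = default_s_values() if s_values is None else np.asarray(s_values, float)
    if (s_values <= 0).any():
        raise ValueError("the TN scale axis must be strictly positive")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sw = make_sw_design(C, T, N / T)
    su = sw.summaries

    def surfaces(k: int) -> tuple[np.ndarray, np.ndarray]:
        x, w = np.polynomial.legendre.leggauss(k)
        v = 0.5 * (x + 1.0)
        w = 0.5 * w
        rho = _tn_quantiles(m_values, s_values, v)
        p_pg = normal_power_value(effect, pg_variance_value(C, N, rho, 1.0), alpha)
        p_sw = normal_power_value(
            effect, sw_variance_value(C, T, N / T, su.U, su.W, su.V, rho, 1.0), alpha
        )
        return p_pg @ w, p_sw @ w

    # one doubling refinement mirrors the EPResult convergence convention
    ep_pg, ep_sw = surfaces(2 * nodes)

    return ComparisonGrid(
        m_values=m_values,
        s_values=s_values,
        ep_pg=ep_pg,
        ep_sw=ep_sw,
        settings={"C": C, "N": N, "T": T, "effect": effect, "alpha": alpha, "nodes": 2 * nodes},
    )


def extract_contour(grid: ComparisonGrid, level: float = 0.0) -> list[np.ndarray]:
    """Zero-level polylines of ``diff`` by bilinear cell interpolation.

    Returns a list of ``(k, 2)`` arrays of (m, s) vertices; empty when
    ``diff`` has one sign over the whole grid.
    """
    gen = contourpy.contour_generator(
        x=grid.s_values, y=grid.m_values, z=grid.diff, line_type=contourpy.LineType.Separate
    )
    lines = gen.lines(level)
    # contourpy yields (x=s, y=m); report as (m, s)
    return [np.column_stack([ln[:, 1], ln[:, 0]]) for ln in lines]


def summarize_pg_region(grid: ComparisonGrid) -> PGRegionSummary:
    """Largest m and s at which the PG design has strictly larger EP."""
    fav = grid.diff > 0
    if not fav.any():
        return PGRegionSummary(max_m=None, max_s=None)
    mi, si = np.where(fav)
    return PGRegionSummary(
        max_m=float(grid.m_values[mi].max()), max_s=float(grid.s_values[si].max())
    )
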