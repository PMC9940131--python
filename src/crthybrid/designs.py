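"""Trial geometries for parallel-group and stepped-wedge cluster-randomized designs.

A parallel-group (PG) design allocates whole clusters 1:1 to control or
intervention for the duration of the trial.  A cross-sectional stepped-wedge
(SW) design starts every cluster in the control condition and rolls the
intervention out in steps: clusters assigned to step ``g`` receive the
intervention from period ``g + 1`` onwards, and by the final period all
clusters are treated.

The scalar summaries ``U``, ``W``, ``V`` of the SW treatment-indicator matrix
feed the closed-form Hussey-Hughes variance of the treatment-effect estimator
(see :mod:`crthybrid.power`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PGDesign",
    "SWDesign",
    "DesignSummaries",
    "DesignError",
    "make_pg_design",
    "make_sw_design",
    "compute_summaries",
]


class DesignError(ValueError):
    """Raised when a requested design is infeasible or degenerate."""


@dataclass(frozen=True)
class PGDesign:
    """Parallel-group cluster-randomized design.

    Parameters
    ----------
    C : int
        Number of clusters (>= 2).
    n : float
        Measurements per cluster.  Integer in a real trial; fractional values
        are permitted so that designs can be compared on a common measurement
        budget.
    allocation : numpy.ndarray
        Length-``C`` vector of 0/1 treatment indicators with a 1:1 split
        (``floor(C/2)`` or ``ceil(C/2)`` ones).
    """

    C: int
    n: float
    allocation: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.C < 2:
            raise DesignError(f"a PG design needs at least 2 clusters, got C={self.C}")
        if self.n <= 0:
            raise DesignError(f"cluster size must be positive, got n={self.n}")
        alloc = np.asarray(self.allocation)
        if alloc.shape != (self.C,) or not np.isin(alloc, (0, 1)).all():
            raise DesignError("allocation must be a length-C binary vector")
        ones = int(alloc.sum())
        if ones not in (self.C // 2, -(-self.C // 2)):
            raise DesignError(
                f"allocation must be 1:1 (got {ones} treated of {self.C} clusters)"
            )
        object.__setattr__(self, "allocation", alloc.astype(np.int64))

    @property
    def balanced(self) -> bool:
        """True when the two arms have exactly equal cluster counts."""
        return self.C % 2 == 0

    @property
    def total_measurements(self) -> float:
        return self.C * self.n


@dataclass(frozen=True)
class SWDesign:
    """Cross-sectional stepped-wedge design.

    ``X[j, k] = 1`` when cluster ``j`` (0-based internally, reported 1-based)
    is on the intervention in period ``k``.  Rows are non-decreasing (once
    treated, always treated); in the standard wedge the first column is all
    zeros and the last all ones.
    """

    C: int
    T: int
    n: float
    X: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.T < 2:
            raise DesignError(f"a stepped wedge needs at least 2 periods, got T={self.T}")
        if self.n <= 0:
            raise DesignError(f"cluster-period size must be positive, got n={self.n}")
        X = np.asarray(self.X)
        if X.shape != (self.C, self.T) or not np.isin(X, (0, 1)).all():
            raise DesignError("X must be a binary C x T matrix")
        if (np.diff(X, axis=1) < 0).any():
            raise DesignError("rows of X must be non-decreasing (no treatment reversal)")
        object.__setattr__(self, "X", X.astype(np.int64))

    @property
    def N(self) -> float:
        """Total measurements per cluster across all periods (``n * T``)."""
        return self.n * self.T

    @property
    def total_measurements(self) -> float:
        return self.C * self.n * self.T

    @property
    def summaries(self) -> "DesignSummaries":
        return compute_summaries(self.X)


@dataclass(frozen=True)
class DesignSummaries:
    """Scalar summaries of a binary treatment matrix.

    ``U`` is the total number of treated cluster-periods, ``W`` the sum over
    periods of squared column sums, and ``V`` the sum over clusters of squared
    row sums.
    """

    U: int
    W: int
    V: int


def make_pg_design(C: int, n: float) -> PGDesign:
    """Build a 1:1 parallel-group design.

    The first ``ceil(C/2)`` clusters act as controls and the rest receive the
    intervention; labels are exchangeable since only arm sizes enter the
    variance.  Odd ``C`` triggers a warning: the closed-form variance assumes
    exactly equal arms, and downstream variance computation will refuse the
    design unless explicitly forced.
    """
    if C < 2:
        raise DesignError(f"a PG design needs at least 2 clusters, got C={C}")
    if C % 2:
        warnings.warn(
            f"C={C} is odd: the PG variance formula assumes equal arms; "
            "variance computation requires force_unequal=True",
            UserWarning,
            stacklevel=2,
        )
    alloc = np.zeros(C, dtype=np.int64)
    alloc[-(C // 2):] = 1
    return PGDesign(C=C, n=n, allocation=alloc)


def make_sw_design(C: int, T: int, n: float) -> SWDesign:
    """Build a standard stepped wedge with ``T - 1`` steps.

    Clusters are divided as evenly as possible across steps; when ``T - 1``
    does not divide ``C`` the remainder clusters go to the earliest steps and
    a warning notes that the wedge is unequal.  Clusters in step ``g``
    (1-based) are treated in periods ``g + 1, ..., T``.
    """
    if T < 2:
        raise DesignError(f"a stepped wedge needs at least 2 periods, got T={T}")
    steps = T - 1
    if C < steps:
        raise DesignError(
            f"C={C} clusters cannot fill {steps} steps (some step would be empty)"
        )
    base, rem = divmod(C, steps)
    if rem:
        warnings.warn(
            f"C={C} is not divisible by T-1={steps}: building an unequal wedge "
            f"with {rem} step(s) of size {base + 1} (earliest steps) and the "
            f"rest of size {base}",
            UserWarning,
            stacklevel=2,
        )
    sizes = [base + 1 if g < rem else base for g in range(steps)]
    X = np.zeros((C, T), dtype=np.int64)
    row = 0
    for g, size in enumerate(sizes):
        X[row:row + size, g + 1:] = 1
        row += size
    return SWDesign(C=C, T=T, n=n, X=X)


def compute_summaries(X: np.ndarray) -> DesignSummaries:
    """Compute ``U``, ``W``, ``V`` from a binary treatment matrix.

    U = sum of all entries; W = sum over periods of squared column sums;
    V = sum over clusters of squared row sums.
    """
    X = np.asarray(X)
    if not np.isin(X, (0, 1)).all():
        raise DesignError("treatment matrix must be binary")
    X = X.astype(np.int64)
    U = int(X.sum())
    W = int((X.sum(axis=0) ** 2).sum())
    V = int((X.sum(axis=1) ** 2).sum())
    return DesignSummaries(U=U, W=W, V=V)


def step_sizes(design: SWDesign) -> list[int]:
    """Cluster counts per roll-out step, derived from the treatment matrix."""
    first_treated = np.argmax(design.X == 1, axis=1)
    first_treated[design.X.sum(axis=1) == 0] = design.T  # never treated
    counts = []
    for g in range(1, design.T):
        counts.append(int((first_treated == g).sum()))
    return counts


def render_matrix(design: PGDesign | SWDesign) -> str:
    """Render a design as CSV text: rows = clusters, columns = periods."""
    if isinstance(design, PGDesign):
        mat = design.allocation.reshape(-1, 1)
        header = "cluster,allocation"
    else:
        mat = design.X
        header = "cluster," + ",".join(f"period_{k}" for k in range(1, design.T + 1))
    lines = [header]
    for j, row in enumerate(mat, start=1):
        lines.append(f"{j}," + ",".join(str(int(v)) for v in row))
    return "\n".join(lines)
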