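"""One-sided binomial confidence bounds via inverse binomial-quantile search.

Given ``k`` affected studies out of ``n``, the bound at confidence ``level``
is found by scanning a proportion grid and inverting the binomial quantile
function: the reported bound is the largest grid proportion ``p`` such that

    quantile(q; n, p) <= k        with q = level      (lower bound)
                                       q = 1 - level  (upper bound)

equivalently, the largest ``p`` for which observing at most ``k`` successes
still has probability ``>= q``.  The default grid step of 0.01 matches
whole-percent reporting.  The continuous counterpart of this search is the
beta quantile ``Beta(k+1, n-k).ppf(1-q)`` (for the upper side this is exactly
the one-sided Clopper–Pearson bound), which the test suite uses as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = ["PrevalenceEstimate", "binomial_bound", "estimate_prevalence"]

DEFAULT_STEP = 0.01


@dataclass
class PrevalenceEstimate:
    """Lower/upper one-sided bounds on the population proportion of affected studies."""

    k: int
    n: int
    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.k / self.n <= self.upper:
            raise ValueError("bounds must bracket the observed proportion")


def _validate(k: int, n: int, level: float, side: str, step: float) -> None:
    if int(k) != k or int(n) != n:
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.5 < level < 1:
        raise ValueError(f"confidence level must lie in (0.5, 1), got {level}")
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    if not 0 < step < 1:
        raise ValueError(f"grid step must lie in (0, 1), got {step}")


def binomial_bound(
    k: int, n: int, level: float, side: str, step: float = DEFAULT_STEP
) -> float:
    """One-sided confidence bound for a binomial proportion (grid search).

    Returns the largest proportion on a ``step``-spaced grid whose binomial
    ``q``-quantile does not exceed ``k`` (``q`` = ``level`` for the lower
    bound, ``1 - level`` for the upper), clipped so the result never crosses
    the observed proportion ``k/n`` (only relevant at extreme inputs).
    """
    _validate(k, n, level, side, step)
    q = level if side == "lower" else 1.0 - level
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    feasible = binom.ppf(q, n, grid) <= k
    bound = float(grid[feasible][-1])  # p=0 is always feasible
    # Bounds must bracket the point estimate; the grid floor can land one step
    # on the wrong side of k/n at extreme inputs (k=0, or level near 0.5).
    bound = min(bound, k / n) if side == "lower" else max(bound, k / n)
    return bound


def estimate_prevalence(
    k: int, n: int, level: float = 0.95, step: float = DEFAULT_STEP
) -> PrevalenceEstimate:
    """Both one-sided bounds at the same confidence level."""
    return PrevalenceEstimate(
        k=k,
        n=n,
        level=level,
        lower=binomial_bound(k, n, level, "lower", step),
        upper=binomial_bound(k, n, level, "upper", step),
    )
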