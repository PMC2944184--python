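"""Lineage-through-time curves, the gamma statistic, and the CR test.

The gamma statistic summarizes where a clade's branching times sit relative
to the constant-rate pure-birth expectation.  With n tips, internode
durations g_k (k lineages present), lineage-time increments e_k = k*g_k,
total T = sum(e_k) and partial sums S_i = e_2 + ... + e_i:

    gamma = [ mean(S_2..S_{n-1}) - T/2 ] / [ T * sqrt(1 / (12 (n-2))) ]

Under a complete-sampling pure-birth process gamma has mean 0 and unit
variance exactly, and is asymptotically standard normal; negative values
mean branching times concentrated toward the root (a slowdown).  The
constant-rates (CR) test is the one-tailed lower comparison of gamma with
the standard-normal quantile: only the slowdown direction is ever rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .chronogram import BranchingTimes, ChronogramError

__all__ = [
    "LTTCurve",
    "GammaResult",
    "GammaUndefinedError",
    "DegenerateTreeError",
    "ltt_curve",
    "gamma_statistic",
    "gamma_from_intervals",
    "cr_test",
]


class GammaUndefinedError(ChronogramError):
    """gamma requires at least 3 tips."""


class DegenerateTreeError(ChronogramError):
    """All internode intervals are zero; gamma is undefined."""


@dataclass(frozen=True)
class LTTCurve:
    """Step-function knots (age, lineage count) from (root_age, 2) to (0, n)."""

    points: tuple[tuple[float, int], ...]

    @property
    def n(self) -> int:
        return self.points[-1][1]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ages = np.array([p[0] for p in self.points])
        counts = np.array([p[1] for p in self.points])
        return ages, counts

    def to_tsv(self) -> str:
        lines = ["age\tlineages"]
        lines += [f"{a:.10g}\t{c}" for a, c in self.points]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n: int
    p_one_tailed: float
    alpha: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "n": self.n,
            "p_one_tailed": self.p_one_tailed,
            "alpha": self.alpha,
            "reject": self.reject,
        }


def ltt_curve(bt: BranchingTimes) -> LTTCurve:
    """Lineage count through time as a step function.

    Tied branching times (e.g. from resolved polytomies) appear as a single
    knot whose count jumps by the multiplicity.
    """
    t = bt.times
    points: list[tuple[float, int]] = [(float(t[0]), 2)]
    count = 2
    for age in t[1:]:
        count += 1
        age = float(age)
        if points[-1][0] == age:
            points[-1] = (age, count)
        else:
            points.append((age, count))
    if points[-1][0] != 0.0:
        points.append((0.0, count))
    else:
        points[-1] = (0.0, bt.n)
    return LTTCurve(points=tuple(points))


def gamma_from_intervals(g: np.ndarray) -> np.ndarray:
    """Vectorized gamma over the trailing axis of an interval array.

    ``g[..., k-2]`` is the duration with k lineages, k = 2..n.  Returns an
    array of gamma values with the trailing axis reduced.  This is the
    computational core shared by the per-tree API and the Monte-Carlo nulls.
    """
    g = np.asarray(g, dtype=float)
    m = g.shape[-1]  # == n - 1
    n = m + 1
    if n < 3:
        raise GammaUndefinedError("gamma requires n >= 3 tips")
    k = np.arange(2, n + 1, dtype=float)
    e = g * k
    T = e.sum(axis=-1)
    if np.any(T <= 0):
        raise DegenerateTreeError("total lineage-time is zero")
    S = np.cumsum(e[..., : n - 2], axis=-1)  # S_2 .. S_{n-1}
    mean_S = S.mean(axis=-1)
    denom = T * np.sqrt(1.0 / (12.0 * (n - 2)))
    return (mean_S - T / 2.0) / denom


def gamma_statistic(bt: BranchingTimes, alpha: float = 0.05) -> GammaResult:
    """The gamma statistic with its analytic standard-normal comparison."""
    if bt.n < 3:
        raise GammaUndefinedError("gamma requires n >= 3 tips")
    gam = float(gamma_from_intervals(bt.intervals))
    res = GammaResult(
        gamma=gam,
        n=bt.n,
        p_one_tailed=float(norm.cdf(gam)),
        alpha=alpha,
        reject=bool(gam < norm.ppf(alpha)),
    )
    return res


def cr_test(g: GammaResult, alpha: float) -> GammaResult:
    """Constant-rates test at level ``alpha`` (one-tailed, lower only).

    Rejection uses the strict inequality gamma < z_alpha, so gamma exactly
    at the critical value is retained.  Positive gamma (an apparent late
    burst) is reported but never rejected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return replace(g, alpha=alpha, reject=bool(g.gamma < norm.ppf(alpha)))
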