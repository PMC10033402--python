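"""Exact post-trial inference under the attained two-stage design.

After a Simon-type trial stops, the raw proportion is biased and naive
binomial tests ignore the stopping rule.  This module provides the exact
machinery for inference that respects the design actually realized (the
*attained* design, whose stage-2 size may differ from plan):

* the uniformly minimum-variance unbiased estimator (UMVUE) of the
  response probability, a ratio of binomial-coefficient sums over the
  feasible stage-1 splits of the total response count;
* one-sided exact p-values under the stagewise ordering, in which every
  outcome that continued to stage 2 ranks above every stage-1 stop;
* two-sided confidence intervals obtained by inverting the stagewise
  upper-tail probability at (1 - level)/2 and 1 - (1 - level)/2 (the
  convention that reproduces published adjusted intervals for this family
  of designs; see docs/methods.md);
* Clopper-Pearson exact binomial intervals and 2x2 odds ratios with an
  optional Haldane-Anscombe zero-cell correction.

All stagewise quantities condition only on the design, never on the
observed data beyond the sufficient statistic (stage stopped, total
responses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom, norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AttainedDesign",
    "TrialOutcome",
    "ExactInferenceResult",
    "OutcomeError",
    "umvue",
    "stagewise_p_value",
    "stagewise_ci",
    "exact_inference",
    "clopper_pearson",
    "odds_ratio_2x2",
]


class OutcomeError(ValueError):
    """Raised when a trial outcome violates its stage/boundary consistency."""


@dataclass(frozen=True)
class AttainedDesign:
    """The two-stage design as realized: futility boundary ``r1``, stage-1
    size ``n1`` and *attained* stage-2 size ``n2`` (which may differ from the
    planned ``n - n1``, e.g. through over-enrollment)."""

    r1: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0 <= self.r1 < self.n1:
            raise OutcomeError(f"require 0 <= r1 < n1, got r1={self.r1}, n1={self.n1}")
        if self.n2 < 0:
            raise OutcomeError(f"n2 must be non-negative, got {self.n2}")


@dataclass(frozen=True)
class TrialOutcome:
    """Sufficient statistic of a completed two-stage trial.

    ``stage_stopped`` is 1 for a futility stop (then ``s == x1 <= r1``) and
    2 for a completed trial (then ``x1 > r1`` and ``x1 <= s <= x1 + n2``).
    """

    stage_stopped: int
    x1: int
    s: int
    attained: AttainedDesign

    def __post_init__(self) -> None:
        d = self.attained
        if self.stage_stopped == 1:
            if self.x1 > d.r1:
                raise OutcomeError(
                    f"stage-1 stop requires x1 <= r1, got x1={self.x1}, r1={d.r1}"
                )
            if self.s != self.x1:
                raise OutcomeError("stage-1 stop requires s == x1")
        elif self.stage_stopped == 2:
            if self.x1 <= d.r1:
                raise OutcomeError(
                    f"continuation requires x1 > r1, got x1={self.x1}, r1={d.r1}"
                )
            if not (self.x1 <= self.s <= self.x1 + d.n2):
                raise OutcomeError(
                    f"require x1 <= s <= x1 + n2, got x1={self.x1}, s={self.s}, n2={d.n2}"
                )
        else:
            raise OutcomeError(f"stage_stopped must be 1 or 2, got {self.stage_stopped}")
        if self.x1 < 0 or self.x1 > d.n1:
            raise OutcomeError(f"x1 must lie in [0, n1], got {self.x1}")


@dataclass(frozen=True)
class ExactInferenceResult:
    umvue: float
    p_value: float
    ci: tuple[float, float]
    level: float


def umvue(outcome: TrialOutcome) -> float:
    """UMVUE of the response probability under the attained design.

    For a stage-1 stop this reduces to the sample proportion ``x1 / n1``.
    For a completed trial with total responses ``s`` it is

        sum_j C(n1-1, j-1) C(n2, s-j)  /  sum_j C(n1, j) C(n2, s-j)

    with j running over the feasible stage-1 counts
    ``max(r1+1, s-n2) .. min(n1, s)``.  Evaluated in exact rational
    arithmetic.
    """
    d = outcome.attained
    if outcome.stage_stopped == 1:
        return outcome.x1 / d.n1
    s = outcome.s
    lo = max(d.r1 + 1, s - d.n2)
    hi = min(d.n1, s)
    num = sum(math.comb(d.n1 - 1, j - 1) * math.comb(d.n2, s - j) for j in range(lo, hi + 1))
    den = sum(math.comb(d.n1, j) * math.comb(d.n2, s - j) for j in range(lo, hi + 1))
    return float(Fraction(num, den))


def _upper_tail(d: AttainedDesign, s: int, p: float) -> float:
    """P(stagewise ordering >= a completed trial with total s; p).

    Equals sum over continuing stage-1 counts j of
    P(X1 = j; n1, p) * P(X2 >= s - j; n2, p), the stage-2 tail being 1
    whenever s - j <= 0.
    """
    j = np.arange(d.r1 + 1, d.n1 + 1)
    k = s - j
    tail2 = np.where(k <= 0, 1.0, binom.sf(k - 1, d.n2, p))
    return float(np.sum(binom.pmf(j, d.n1, p) * tail2))


def stagewise_p_value(outcome: TrialOutcome, p0: float) -> float:
    """One-sided exact p-value against ``p0`` under the stagewise ordering.

    Every completed trial ranks above every stage-1 stop; completed trials
    are ordered by the total response count.  For a stage-1 stop the upper
    tail at the observed stage-1 count is returned (such trials never
    reject; this branch is an extension beyond the usual reporting need).
    """
    if not 0 <= p0 <= 1:
        raise OutcomeError(f"p0 must lie in [0, 1], got {p0}")
    d = outcome.attained
    if outcome.stage_stopped == 1:
        # P(ordering >= stop with x1) = P(X1 >= x1): larger stops and all
        # continuations rank at or above the observed outcome.
        return float(binom.sf(outcome.x1 - 1, d.n1, p0))
    return _upper_tail(d, outcome.s, p0)


def _lower_tail(d: AttainedDesign, s: int, p: float) -> float:
    """P(stagewise ordering <= a completed trial with total s; p): all
    stage-1 stops plus completed trials with totals at most s."""
    pet = float(binom.cdf(d.r1, d.n1, p))
    j = np.arange(d.r1 + 1, d.n1 + 1)
    k = s - j
    tail2 = np.where(k < 0, 0.0, binom.cdf(np.maximum(k, 0), d.n2, p))
    return pet + float(np.sum(binom.pmf(j, d.n1, p) * tail2))


def _invert(f, target: float, increasing: bool, tol: float) -> float:
    """Root of the monotone tail equation f(p) = target on [0, 1], with the
    degenerate cases mapped to the interval ends."""
    g = (lambda p: f(p) - target) if increasing else (lambda p: target - f(p))
    if g(0.0) >= 0.0:
        return 0.0
    if g(1.0) <= 0.0:
        return 1.0
    try:
        return float(brentq(g, 0.0, 1.0, xtol=tol, maxiter=200))
    except RuntimeError as exc:  # pragma: no cover - brentq converges here
        raise ArithmeticError(f"CI inversion failed to converge: {exc}") from exc


def stagewise_ci(
    outcome: TrialOutcome,
    level: float = 0.80,
    method: str = "koyama-chen",
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Two-sided confidence interval under the stagewise ordering.

    ``method="koyama-chen"`` (default) inverts the single stagewise
    upper-tail function at ``(1 - level)/2`` and ``1 - (1 - level)/2``.
    This is the convention of published adjusted intervals for Simon-type
    designs; its one-sided coverage on the rejection side is exact, but its
    two-sided coverage can dip slightly below nominal at large p.

    ``method="equal-tail"`` inverts the upper tail for the lower bound and
    the lower tail (stage-1 stops plus smaller completed totals) for the
    upper bound, each at ``(1 - level)/2``; this interval is strictly
    conservative (coverage >= level for every p) but wider, and does not
    reproduce the published intervals.

    Both tails are monotone in p, so bracketing root-finding to ``tol``
    applies; degenerate tails map to 0 or 1.
    """
    if not 0 < level < 1:
        raise OutcomeError(f"level must lie in (0, 1), got {level}")
    if outcome.stage_stopped != 2:
        raise OutcomeError("stagewise_ci is defined for completed (stage-2) trials")
    if method not in ("koyama-chen", "equal-tail"):
        raise OutcomeError(f"unknown method {method!r}")
    d, s = outcome.attained, outcome.s
    half = (1.0 - level) / 2.0
    upper_tail = lambda p: _upper_tail(d, s, p)  # increasing in p
    lo = _invert(upper_tail, half, increasing=True, tol=tol)
    if method == "koyama-chen":
        hi = _invert(upper_tail, 1.0 - half, increasing=True, tol=tol)
    else:
        lower_tail = lambda p: _lower_tail(d, s, p)  # decreasing in p
        hi = _invert(lower_tail, half, increasing=False, tol=tol)
    return lo, hi


def exact_inference(
    outcome: TrialOutcome, p0: float, level: float = 0.80
) -> ExactInferenceResult:
    """UMVUE, stagewise p-value and adjusted CI in one call."""
    return ExactInferenceResult(
        umvue=umvue(outcome),
        p_value=stagewise_p_value(outcome, p0),
        ci=stagewise_ci(outcome, level),
        level=level,
    )


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n."""
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"require 0 <= x <= n and n >= 1, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    lo, hi = proportion_confint(x, n, alpha=1.0 - level, method="beta")
    # statsmodels returns NaN at the boundary cases; pin the exact values
    lo = 0.0 if x == 0 else float(lo)
    hi = 1.0 if x == n else float(hi)
    return lo, hi


def odds_ratio_2x2(
    table, zero_cell_rule: str = "haldane", level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Odds ratio and Wald CI for a 2x2 table ``[[a, b], [c, d]]``.

    Rows are the two comparison groups, columns (event, no event).  With
    ``zero_cell_rule="haldane"`` 0.5 is added to every cell whenever any
    cell is zero (Haldane-Anscombe); with ``"none"`` a zero cell raises.
    An all-zero row or column leaves the odds ratio undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.all(t == np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: a row or column is all zero")
    if zero_cell_rule not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell_rule {zero_cell_rule!r}")
    if (t == 0).any():
        if zero_cell_rule == "none":
            raise ValueError("zero cell present and zero_cell_rule='none'")
        t = t + 0.5
    a, b, c, d = t.ravel()
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo = math.exp(math.log(oratio) - z * se)
    hi = math.exp(math.log(oratio) + z * se)
    return oratio, (lo, hi)
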