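"""Two-stage single-arm binomial designs and Simon's design search.

A two-stage design enrolls ``n1`` subjects and stops for futility if the
number of responses is at most ``r1``; otherwise it enrolls ``n - n1`` more
and declares the treatment efficacious if the total number of responses
exceeds ``r`` (i.e. at least ``r + 1`` responses).  The stage-1 boundary is
futility-only: there is no early efficacy stop.

Boundary convention
-------------------
Efficacy is declared iff total responses >= r + 1.  A protocol phrased as
"six or more responses out of 21" therefore corresponds to ``r = 5``.
Conventions differ across software; this one matches Simon's original
tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "TwoStageDesign",
    "OperatingCharacteristics",
    "DesignError",
    "InfeasibleDesignError",
    "operating_characteristics",
    "search_simon",
]


class DesignError(ValueError):
    """Raised for invalid design parameters or probabilities."""


class InfeasibleDesignError(DesignError):
    """Raised when no design within the search cap meets the error targets."""


@dataclass(frozen=True)
class TwoStageDesign:
    """A Simon-type two-stage design with its hypothesis parameters.

    Parameters
    ----------
    r1, n1
        Stage-1 futility boundary and sample size; the trial continues to
        stage 2 iff stage-1 responses exceed ``r1``.
    r, n
        Final boundary and planned total sample size; efficacy is declared
        iff total responses exceed ``r``.
    p0, p1
        Null (historical control) and alternative response probabilities.
    alpha, beta
        One-sided type-I and type-II error targets.
    """

    r1: int
    n1: int
    r: int
    n: int
    p0: float
    p1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 <= self.n):
            raise DesignError(
                f"require 0 <= r1 < n1 <= n, got r1={self.r1}, n1={self.n1}, n={self.n}"
            )
        if not (self.r1 <= self.r < self.n):
            raise DesignError(
                f"require r1 <= r < n, got r1={self.r1}, r={self.r}, n={self.n}"
            )
        if not (0 <= self.p0 < self.p1 <= 1):
            raise DesignError(f"require 0 <= p0 < p1 <= 1, got p0={self.p0}, p1={self.p1}")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise DesignError("alpha and beta must lie strictly in (0, 1)")

    @property
    def n2(self) -> int:
        """Planned stage-2 sample size."""
        return self.n - self.n1


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Exact operating characteristics of a design at one true rate ``p``."""

    p: float
    reject_prob: float
    pet: float
    expected_n: float


def operating_characteristics(design: TwoStageDesign, p: float) -> OperatingCharacteristics:
    """Exact operating characteristics of ``design`` at true response rate ``p``.

    Returns the probability of declaring efficacy (type-I error at ``p0``,
    power at ``p1``), the probability of early termination at stage 1 (PET),
    and the expected sample size ``n1 + (1 - PET) * (n - n1)``.  All
    quantities are exact binomial sums; nothing is simulated.
    """
    if not 0 <= p <= 1:
        raise DesignError(f"p must lie in [0, 1], got {p}")
    r1, n1, r, n2 = design.r1, design.n1, design.r, design.n2
    pet = float(binom.cdf(r1, n1, p))
    x1 = np.arange(r1 + 1, n1 + 1)
    # P(reject) = sum over continuing x1 of P(X1 = x1) * P(X2 >= r + 1 - x1)
    reject = float(np.sum(binom.pmf(x1, n1, p) * binom.sf(r - x1, n2, p)))
    expected_n = design.n1 + (1.0 - pet) * n2
    return OperatingCharacteristics(p=p, reject_prob=reject, pet=pet, expected_n=expected_n)


def _feasible_designs_at_n(
    n: int, p0: float, p1: float, alpha: float, beta: float
) -> list[tuple[float, TwoStageDesign]]:
    """All admissible (r1, n1, r) at total size ``n``, with E[N | p0] attached.

    For each (n1, r1) the smallest final boundary r meeting the type-I
    constraint is taken; a larger r only loses power.
    """
    out: list[tuple[float, TwoStageDesign]] = []
    for n1 in range(1, n):
        n2 = n - n1
        pmf1_0 = binom.pmf(np.arange(n1 + 1), n1, p0)
        pmf1_1 = binom.pmf(np.arange(n1 + 1), n1, p1)
        pmf2_0 = binom.pmf(np.arange(n2 + 1), n2, p0)
        pmf2_1 = binom.pmf(np.arange(n2 + 1), n2, p1)
        cdf1_0 = np.cumsum(pmf1_0)
        sf1_1 = 1.0 - np.cumsum(pmf1_1)
        for r1 in range(0, n1):
            # power is bounded by P(continue; p1); prune hopeless r1
            if sf1_1[r1] < 1.0 - beta:
                break
            # distribution of the total S restricted to continuation;
            # rest[k] = P(continue and S = r1 + 1 + k)
            rest0 = np.convolve(pmf1_0[r1 + 1 :], pmf2_0)
            rest1 = np.convolve(pmf1_1[r1 + 1 :], pmf2_1)
            # tail[i] = P(continue and S > r1 + i), i.e. rejection prob at r = r1 + i
            tail0 = rest0.sum() - np.concatenate(([0.0], rest0.cumsum()))
            tail1 = rest1.sum() - np.concatenate(([0.0], rest1.cumsum()))
            ok = np.nonzero(tail0 <= alpha)[0]
            if ok.size == 0:
                continue
            i = int(ok[0])  # smallest boundary meeting the type-I constraint
            r = r1 + i
            if r >= n:
                continue
            if tail1[i] < 1.0 - beta:
                continue
            en0 = n1 + (1.0 - cdf1_0[r1]) * n2
            out.append(
                (
                    en0,
                    TwoStageDesign(
                        r1=r1, n1=n1, r=r, n=n, p0=p0, p1=p1, alpha=alpha, beta=beta
                    ),
                )
            )
    return out


def search_simon(
    p0: float,
    p1: float,
    alpha: float,
    beta: float,
    criterion: str = "minimax",
    n_max: int = 100,
) -> TwoStageDesign:
    """Exhaustive Simon design search.

    Scans every (n1, n, r1, r) with ``n <= n_max`` meeting
    ``reject_prob(p0) <= alpha`` and ``reject_prob(p1) >= 1 - beta`` and
    returns

    * ``criterion="minimax"``: the design minimizing the maximum sample
      size ``n``, ties broken by the smaller expected sample size under p0;
    * ``criterion="optimal"``: the design minimizing the expected sample
      size under p0.

    Raises
    ------
    InfeasibleDesignError
        If no design with ``n <= n_max`` satisfies the error constraints.
    """
    if not (0 < p0 < p1 < 1):
        raise DesignError(f"require 0 < p0 < p1 < 1, got p0={p0}, p1={p1}")
    if n_max < 2:
        raise DesignError("n_max must be at least 2")
    if criterion not in ("minimax", "optimal"):
        raise DesignError(f"unknown criterion {criterion!r}")

    best: tuple[float, TwoStageDesign] | None = None
    for n in range(2, n_max + 1):
        cands = _feasible_designs_at_n(n, p0, p1, alpha, beta)
        if not cands:
            continue
        local = min(cands, key=lambda t: t[0])
        if criterion == "minimax":
            return local[1]
        if best is None or local[0] < best[0]:
            best = local
    if best is None:
        raise InfeasibleDesignError(
            f"no feasible two-stage design with n <= {n_max} for "
            f"p0={p0}, p1={p1}, alpha={alpha}, beta={beta}"
        )
    return best[1]
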