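"""Bayesian beta-binomial toxicity monitoring.

Sequentially monitors a perioperative toxicity rate: with a Beta(a, b)
prior and ``x`` toxicities among ``n`` evaluated patients, enrollment is
paused for review when the posterior probability that the toxicity rate
exceeds an unacceptable threshold passes a cutoff.  The boundary is
advisory (pause-and-evaluate), not a binding stop.

No default threshold or cutoff is assumed: monitoring parameters are
protocol choices and must be supplied explicitly.  The default prior is
the uniform Beta(1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import beta as beta_dist

__all__ = ["ToxicityMonitorSpec", "posterior_exceedance", "stopping_boundary"]


@dataclass(frozen=True)
class ToxicityMonitorSpec:
    """Monitoring rule: prior, unacceptable rate, posterior cutoff and the
    interim sample sizes at which the rule is evaluated."""

    p_unacceptable: float
    posterior_cutoff: float
    prior_a: float = 1.0
    prior_b: float = 1.0
    cohort_schedule: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior parameters must be positive")
        if not 0 < self.p_unacceptable < 1:
            raise ValueError("p_unacceptable must lie in (0, 1)")
        if not 0 < self.posterior_cutoff <= 1:
            raise ValueError("posterior_cutoff must lie in (0, 1]")
        sched = tuple(int(n) for n in self.cohort_schedule)
        if any(n <= 0 for n in sched) or any(
            b <= a for a, b in zip(sched, sched[1:])
        ):
            raise ValueError("cohort_schedule must be strictly increasing positive integers")
        object.__setattr__(self, "cohort_schedule", sched)


def posterior_exceedance(spec: ToxicityMonitorSpec, x_tox: int, n: int) -> float:
    """P(toxicity rate > p_unacceptable | x_tox toxicities in n patients).

    The posterior is Beta(prior_a + x, prior_b + n - x); the exceedance
    probability is its upper tail at the unacceptable rate.
    """
    if not 0 <= x_tox <= n:
        raise ValueError(f"require 0 <= x_tox <= n, got x_tox={x_tox}, n={n}")
    return float(
        beta_dist.sf(spec.p_unacceptable, spec.prior_a + x_tox, spec.prior_b + n - x_tox)
    )


def stopping_boundary(spec: ToxicityMonitorSpec) -> list[tuple[int, int | None]]:
    """Pause boundary: for each interim size n, the smallest toxicity count
    whose posterior exceedance passes the cutoff, or None if no count up to
    n triggers the rule."""
    out: list[tuple[int, int | None]] = []
    for n in spec.cohort_schedule:
        stop_x: int | None = None
        for x in range(n + 1):
            if posterior_exceedance(spec, x, n) > spec.posterior_cutoff:
                stop_x = x
                break
        out.append((n, stop_x))
    return out
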