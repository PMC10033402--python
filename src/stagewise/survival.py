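"""Kaplan-Meier estimation, log-rank comparison and landmark analysis.

Event-free survival (EFS) is measured from treatment initiation to
progression, recurrence or death, censored at last imaging.  Landmark
analyses re-zero the clock at surgery and stratify by the pathologic
response determined there, avoiding guarantee-time bias.

The product-limit fit and the log-rank statistic are delegated to
lifelines; this module adds the curve container used throughout the
package, Greenwood pointwise intervals on the plain and log(-log) scales,
and the landmark bookkeeping.  Ties are handled the standard way: events
precede censorings at equal times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm

from .cohort import PatientRecord

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "km_estimate",
    "km_confidence_band",
    "logrank_test",
    "landmark_efs",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: positive time in months and event flag
    (True = event, False = censored)."""

    time: float
    event: bool
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``greenwood_se[i]`` the Greenwood standard error there.  ``n`` is the
    number of subjects the curve was fit on.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n: int

    def evaluate(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t) with the right-continuous step convention: the value at
        the largest event time <= t, and 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(t), side="right")
        vals = np.concatenate(([1.0], self.survival))[idx]
        return float(vals) if np.isscalar(t) or np.asarray(t).ndim == 0 else vals


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValueError("records must be non-empty")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([bool(r.event) for r in records])
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    All-censored input is legal and returns the constant-1 curve.  The
    output is invariant to the ordering of the input records.
    """
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n_risk = ev["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    se = surv * np.sqrt(np.cumsum(incr))
    se = np.where(surv == 0.0, 0.0, se)  # S hit zero: variance degenerate
    return SurvivalCurve(
        event_times=times,
        at_risk=n_risk,
        n_events=d,
        survival=surv,
        greenwood_se=se,
        n=len(records),
    )


def km_confidence_band(
    curve: SurvivalCurve, level: float = 0.95, transform: str = "log-log"
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Greenwood confidence limits at the event times.

    ``transform="plain"`` uses S +/- z*se clipped to [0, 1];
    ``transform="log-log"`` works on log(-log S), which respects the unit
    interval without clipping and is the common default in survival
    software.  Zero-variance points (S = 1 exactly) return (1, 1).
    """
    if transform not in ("plain", "log-log"):
        raise ValueError(f"unknown transform {transform!r}")
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    s, se = curve.survival, curve.greenwood_se
    if transform == "plain":
        lo = np.clip(s - z * se, 0.0, 1.0)
        hi = np.clip(s + z * se, 0.0, 1.0)
        return lo, hi
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    for i, (si, sei) in enumerate(zip(s, se)):
        if si >= 1.0:
            lo[i] = hi[i] = 1.0
        elif si <= 0.0:
            lo[i] = hi[i] = 0.0
        else:
            theta = z * sei / (si * abs(np.log(si)))
            lo[i] = si ** np.exp(theta)
            hi[i] = si ** np.exp(-theta)
    return lo, hi


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p-value).

    The statistic is the usual observed-minus-expected form with
    hypergeometric variance, referred to chi-square with k-1 degrees of
    freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durations, events, labels = [], [], []
    for g, recs in enumerate(groups):
        if not recs:
            raise ValueError(f"group {g} is empty")
        t, e = _to_arrays(recs)
        durations.append(t)
        events.append(e)
        labels.append(np.full(len(recs), g))
    res = multivariate_logrank_test(
        np.concatenate(durations), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


def landmark_efs(
    patients: Sequence[PatientRecord], stratifier: str = "mpr"
) -> dict[str, dict]:
    """Landmark EFS by pathologic response, re-zeroed at surgery.

    Only resected patients enter (others are dropped with a warning);
    each needs ``surgery_months`` so that the landmark time is
    ``efs_months - surgery_months``.  Returns, per stratum (``"MPR"`` /
    ``"no MPR"`` or the pCR analogues), the Kaplan-Meier curve, the event
    tally and the stratum size.  An empty stratum is simply absent from
    the output.
    """
    if stratifier not in ("mpr", "pcr"):
        raise ValueError(f"stratifier must be 'mpr' or 'pcr', got {stratifier!r}")
    dropped = [p.id for p in patients if not p.resected]
    if dropped:
        warnings.warn(f"excluding {len(dropped)} unresected patient(s): {dropped}", stacklevel=2)
    label_pos = stratifier.upper() if stratifier == "mpr" else "pCR"
    out: dict[str, dict] = {}
    for flag, label in ((True, label_pos), (False, f"no {label_pos}")):
        recs = []
        for p in patients:
            if not p.resected or bool(getattr(p, stratifier)) != flag:
                continue
            if p.surgery_months is None:
                raise ValueError(f"{p.id}: resected patient lacks surgery_months")
            recs.append(
                SurvivalRecord(
                    time=p.efs_months - p.surgery_months,
                    event=p.efs_event,
                    group_label=label,
                )
            )
        if not recs:
            continue
        out[label] = {
            "curve": km_estimate(recs),
            "events": sum(r.event for r in recs),
            "n": len(recs),
        }
    return out


def records_from_frame(df: pd.DataFrame, time_col: str = "time_months",
                       event_col: str = "event") -> list[SurvivalRecord]:
    """Build survival records from a data frame (e.g. a parsed cohort file)."""
    return [
        SurvivalRecord(time=float(t), event=bool(e))
        for t, e in zip(df[time_col], df[event_col])
    ]
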