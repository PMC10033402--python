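"""Synthetic two-stage trial generator with known ground truth.

Every estimator and operating characteristic in the package can be
exercised against data whose generating truth is known: Bernoulli
responses at a chosen rate with the futility stop applied, optional
over-enrollment at stage 2 (the attained stage-2 size is a parameter,
mirroring trials that treat one extra patient), exponential or Weibull
event times with administrative censoring, and a per-patient toxicity
indicator.  Responders receive a reduced event hazard by default,
mirroring the premise of landmark response-stratified survival analyses;
the hazard ratio is a knob.

Randomness contract: one PCG64 generator seeded from ``config.seed``
drives a run.  ``simulate_trials`` draws a fixed-width row of Bernoulli
indicators per replicate in row-major order, so replicate ``i`` depends
only on the seed, the design width and ``i`` — any prefix of the
replicate table is bit-identical across runs with different
``n_replicates``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .design import TwoStageDesign

__all__ = ["SimulationConfig", "simulate_trials", "simulate_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and bookkeeping for a simulation run.

    ``attained_n2`` defaults to the design's planned stage-2 size.
    ``hazard_month`` is the event hazard (1/months) for non-responders;
    responders get ``hazard_month * hazard_ratio_responder``.  With
    ``survival_model="weibull"`` the same scale applies with shape
    ``weibull_shape`` (shape 1 recovers the exponential).
    """

    design: TwoStageDesign
    true_response_rate: float
    seed: int
    attained_n2: int | None = None
    n_replicates: int = 1
    survival_model: str = "exponential"
    hazard_month: float = 1.0 / 36.0
    hazard_ratio_responder: float = 0.5
    weibull_shape: float = 1.0
    admin_censor_months: float = 36.0
    true_tox_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("true_response_rate", "true_tox_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.survival_model not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival_model {self.survival_model!r}")
        if self.hazard_month <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard and shape must be positive")
        if self.attained_n2 is not None and self.attained_n2 < 0:
            raise ValueError("attained_n2 must be non-negative")

    @property
    def n2(self) -> int:
        return self.design.n2 if self.attained_n2 is None else self.attained_n2


def simulate_trials(config: SimulationConfig) -> pd.DataFrame:
    """Replicate table of two-stage trials at the configured true rate.

    Each replicate draws stage-1 responses, stops if they do not exceed
    the futility boundary, otherwise adds the attained stage-2 draws;
    efficacy is declared when the total exceeds the final boundary.
    Columns: replicate, x1, s, stopped_early, reject.
    """
    d = config.design
    rng = np.random.default_rng(config.seed)
    width = d.n1 + config.n2
    draws = rng.random((config.n_replicates, width)) < config.true_response_rate
    x1 = draws[:, : d.n1].sum(axis=1)
    cont = x1 > d.r1
    s = x1 + np.where(cont, draws[:, d.n1 :].sum(axis=1), 0)
    return pd.DataFrame(
        {
            "replicate": np.arange(config.n_replicates),
            "x1": x1,
            "s": s,
            "stopped_early": ~cont,
            "reject": s > d.r,
        }
    )


def _event_times(rng: np.random.Generator, hazard: np.ndarray, shape: float) -> np.ndarray:
    # Weibull with scale 1/hazard: T = (E)^{1/shape} / hazard, E ~ Exp(1);
    # shape 1 is the exponential.
    e = rng.exponential(1.0, size=hazard.shape)
    return e ** (1.0 / shape) / hazard


def simulate_cohort(config: SimulationConfig, n_patients: int | None = None) -> list[PatientRecord]:
    """One synthetic patient cohort with known response/survival/toxicity truth.

    Response is Bernoulli at the true rate; the event time comes from the
    responder- or non-responder-stratum model, administratively censored.
    Covariates irrelevant to the generator are filled with neutral
    constants; the per-patient toxicity indicator lives on the frame
    returned by :func:`simulate_survival_frame`, which shares the same
    generator layout.  The size defaults to the design's attained total.
    """
    d = config.design
    n = d.n1 + config.n2 if n_patients is None else n_patients
    rng = np.random.default_rng(config.seed)
    resp = rng.random(n) < config.true_response_rate
    hazard = np.where(
        resp,
        config.hazard_month * config.hazard_ratio_responder,
        config.hazard_month,
    )
    shape = config.weibull_shape if config.survival_model == "weibull" else 1.0
    t = _event_times(rng, hazard, shape)
    event = t < config.admin_censor_months
    t_obs = np.minimum(t, config.admin_censor_months)
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"S{i + 1:04d}",
                arm="NivoCT",
                mpr=bool(resp[i]),
                pcr=False,
                viable_tumor_pct=None,
                resected=True,
                stage_group="IB-II",
                histology="non-squamous",
                smoking="former/current",
                egfr_alk_altered=False,
                efs_months=float(max(t_obs[i], 1e-9)),
                efs_event=bool(event[i]),
                surgery_months=0.0,  # synthetic clock already starts at surgery
            )
        )
    return records


def simulate_survival_frame(config: SimulationConfig, n_patients: int) -> pd.DataFrame:
    """Lightweight survival-only draw: columns responder, time_months, event,
    toxicity.  Shares the generator layout of ``simulate_cohort``."""
    rng = np.random.default_rng(config.seed)
    resp = rng.random(n_patients) < config.true_response_rate
    hazard = np.where(
        resp,
        config.hazard_month * config.hazard_ratio_responder,
        config.hazard_month,
    )
    shape = config.weibull_shape if config.survival_model == "weibull" else 1.0
    t = _event_times(rng, hazard, shape)
    event = t < config.admin_censor_months
    return pd.DataFrame(
        {
            "responder": resp,
            "time_months": np.minimum(t, config.admin_censor_months),
            "event": event,
            "toxicity": rng.random(n_patients) < config.true_tox_rate,
        }
    )
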