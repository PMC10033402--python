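"""Packaged fixtures transcribing the published trial's printed inputs.

Two neoadjuvant chemoimmunotherapy arms of 22 patients each: nivolumab +
chemotherapy ("NivoCT") and ipilimumab + nivolumab + chemotherapy
("IpiNivoCT").  Only quantities actually printed in the trial report are
treated as ground truth: per-arm response counts, stage-1 response counts,
the design constants, per-arm recurrence/death times, median follow-up,
aggregate viable-tumor medians, and Table-1 covariate margins.

Everything below patient level is a labelled reconstruction:

* covariate assignments match the printed margins and response tallies
  only — the individual cross-classifications are synthetic;
* the assignment of the printed recurrence times to response strata
  follows the printed landmark tallies, but which patient got which time
  is synthetic;
* the one unprinted event time (a death during treatment cycle 1 in the
  IpiNivoCT arm) is encoded as 1.5 months; any value below the earliest
  recurrence (8.3 months) yields identical survival estimates at the
  12- and 24-month landmarks;
* non-event subjects are censored at the arm's printed median follow-up
  (39.2 and 24.0 months);
* landmark (surgery-origin) times use a nominal 2.6-month interval from
  treatment initiation to surgery, synthetic but tally-preserving;
* per-patient viable-tumor percentages are NOT invented: only pCR
  patients carry the definitional 0%, all others are missing, and the
  printed medians live in aggregate form on the fixture set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import PatientRecord
from .design import TwoStageDesign
from .inference import AttainedDesign, TrialOutcome

__all__ = [
    "DESIGN",
    "ATTAINED",
    "nivo_ct_outcome",
    "ipi_nivo_ct_outcome",
    "nivo_ct_cohort",
    "ipi_nivo_ct_cohort",
    "FixtureSet",
    "fixture_set",
]

#: The planned design common to both arms: continue past stage 1 only with
#: >2 responses in 15; declare efficacy with >5 responses in 21 planned.
DESIGN = TwoStageDesign(r1=2, n1=15, r=5, n=21, p0=0.15, p1=0.40, alpha=0.10, beta=0.10)

#: The attained design: both arms treated 22 patients, so stage 2 enrolled
#: 7 rather than the planned 6; all post-trial inference conditions on this.
ATTAINED = AttainedDesign(r1=2, n1=15, n2=7)

_SURGERY_OFFSET = 2.6  # months, nominal treatment-initiation-to-surgery interval

# Printed event times (months from treatment initiation)
NIVO_CT_RECURRENCES = (8.7, 17.7, 18.8, 19.5, 20.6, 21.7, 29.0, 30.4, 30.7, 35.7)
IPI_NIVO_CT_RECURRENCES = (8.3, 8.6, 9.6, 14.8)
IPI_NIVO_CT_DEATH_MONTHS = 1.5  # synthetic placement of the unprinted cycle-1 death
NIVO_CT_FOLLOWUP = 39.2
IPI_NIVO_CT_FOLLOWUP = 24.0


def nivo_ct_outcome() -> TrialOutcome:
    """NivoCT arm: 6 stage-1 responses, 7 total among 22 treated."""
    return TrialOutcome(stage_stopped=2, x1=6, s=7, attained=ATTAINED)


def ipi_nivo_ct_outcome() -> TrialOutcome:
    """IpiNivoCT arm: 7 stage-1 responses, 11 total among 22 treated."""
    return TrialOutcome(stage_stopped=2, x1=7, s=11, attained=ATTAINED)


def _record(i, arm, mpr, pcr, resected, stage, hist, smoke, altered, months, event):
    return PatientRecord(
        id=f"{'C' if arm == 'NivoCT' else 'D'}{i:02d}",
        arm=arm,
        mpr=mpr,
        pcr=pcr,
        viable_tumor_pct=0.0 if pcr else None,
        resected=resected,
        stage_group=stage,
        histology=hist,
        smoking=smoke,
        egfr_alk_altered=altered,
        efs_months=months,
        efs_event=event,
        surgery_months=_SURGERY_OFFSET if resected else None,
    )


def nivo_ct_cohort() -> list[PatientRecord]:
    """22 reconstructed NivoCT records.

    Printed anchors: 7 MPR (4 pCR), all 22 resected, 5 known EGFR/ALK
    alterations (all among non-MPR, matching 7/17 MPR without known
    alterations), 10 recurrences at the printed times split 3 MPR (one of
    them pCR) / 7 no-MPR per the printed landmark tallies, 12 subjects
    censored at the 39.2-month median follow-up.
    """
    recs = []
    event_times = iter(NIVO_CT_RECURRENCES)
    for i in range(1, 23):
        pcr = i <= 4
        mpr = i <= 7
        has_event = i in (1, 5, 6, 8, 9, 10, 11, 12, 13, 14)
        months = next(event_times) if has_event else NIVO_CT_FOLLOWUP
        recs.append(
            _record(
                i,
                "NivoCT",
                mpr,
                pcr,
                True,
                "IIIA" if i <= 11 else "IB-II",
                "squamous" if i <= 5 else "non-squamous",
                "never" if i >= 18 else "former/current",
                i >= 18,  # 5 known-altered, all non-MPR
                months,
                has_event,
            )
        )
    return recs


def ipi_nivo_ct_cohort() -> list[PatientRecord]:
    """22 reconstructed IpiNivoCT records.

    Printed anchors: 11 MPR (4 pCR) in the ITT population, 20 resected
    (one death from SARS-CoV-2 complications during cycle 1, one not
    resected on surgical judgment; both count as no-MPR in ITT), 6 known
    EGFR/ALK alterations with exactly one among MPR patients (matching
    10/16 MPR and 4/16 pCR without known alterations), 4 recurrences at
    the printed times split 1 MPR (non-pCR) / 3 no-MPR per the printed
    landmark tallies, remaining subjects censored at the 24.0-month
    median follow-up.
    """
    recs = []
    rec_times = {5: 8.3, 12: 8.6, 13: 9.6, 14: 14.8}
    for i in range(1, 23):
        pcr = i <= 4
        mpr = i <= 11
        resected = i <= 20
        if i == 21:  # death during cycle 1, never resected
            months, event = IPI_NIVO_CT_DEATH_MONTHS, True
        elif i in rec_times:
            months, event = rec_times[i], True
        else:
            months, event = IPI_NIVO_CT_FOLLOWUP, False
        recs.append(
            _record(
                i,
                "IpiNivoCT",
                mpr and resected,
                pcr,
                resected,
                "IIIA" if i <= 13 else "IB-II",
                "squamous" if i <= 5 else "non-squamous",
                "never" if i >= 18 else "former/current",
                i in (11, 17, 18, 19, 20, 22),  # 6 known-altered, one MPR
                months,
                event,
            )
        )
    return recs


@dataclass(frozen=True)
class FixtureSet:
    """Aggregate printed values plus the reconstructed cohorts.

    ``derived_tables`` holds 2x2 MPR cross-tabulations reconstructed by
    inverting printed odds ratios; they are NOT printed in the report and
    are marked derived/unverified.
    """

    design: TwoStageDesign = DESIGN
    attained: AttainedDesign = ATTAINED
    stage1_responses: dict = field(
        default_factory=lambda: {"NivoCT": 6, "IpiNivoCT": 7}
    )
    total_responses: dict = field(
        default_factory=lambda: {"NivoCT": 7, "IpiNivoCT": 11}
    )
    viable_tumor_median: dict = field(
        default_factory=lambda: {
            "NivoCT": {"median": 50.5, "range": (0.0, 95.5), "n": 22},
            "IpiNivoCT": {"median": 4.5, "range": (0.0, 94.4), "n": 20},
        }
    )
    event_times: dict = field(
        default_factory=lambda: {
            "NivoCT": NIVO_CT_RECURRENCES,
            "IpiNivoCT": (IPI_NIVO_CT_DEATH_MONTHS,) + IPI_NIVO_CT_RECURRENCES,
        }
    )
    # rows: (group with event count, group size) -> [[events, non-events], ...]
    derived_tables: dict = field(
        default_factory=lambda: {
            # squamous 8/10 MPR vs non-squamous 10/34, both arms combined
            "histology": ((8, 2), (10, 24)),
            # former/current smokers 18/34 vs never 0/10, both arms combined
            "smoking": ((18, 16), (0, 10)),
            # stage IIIA: IpiNivoCT 8/13 MPR vs NivoCT 1/11 (unverified)
            "stage_iiia_by_arm": ((8, 5), (1, 10)),
        }
    )

    def __post_init__(self) -> None:
        for arm, cohort in (("NivoCT", nivo_ct_cohort()), ("IpiNivoCT", ipi_nivo_ct_cohort())):
            if len(cohort) != 22:
                raise AssertionError(f"{arm}: expected 22 records")
            if sum(1 for r in cohort if r.mpr) != self.total_responses[arm]:
                raise AssertionError(f"{arm}: MPR count inconsistent with fixture totals")
            n_events = sum(1 for r in cohort if r.efs_event)
            if n_events != len(self.event_times[arm]):
                raise AssertionError(f"{arm}: event count inconsistent with event times")
        for name, ((a, b), (c, d)) in self.derived_tables.items():
            if min(a, b, c, d) < 0:
                raise AssertionError(f"{name}: negative cell")


def fixture_set() -> FixtureSet:
    """The validated fixture bundle (checks run at construction)."""
    return FixtureSet()
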