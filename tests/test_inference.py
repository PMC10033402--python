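"""Exact inference under the attained design: UMVUE, stagewise p-values
and CIs, Clopper-Pearson intervals, odds ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from stagewise import (
    AttainedDesign,
    OutcomeError,
    TrialOutcome,
    clopper_pearson,
    format_percent,
    odds_ratio_2x2,
    stagewise_ci,
    stagewise_p_value,
    umvue,
)


def outcome_for_total(att: AttainedDesign, s: int) -> TrialOutcome:
    """A completed trial with total s (the stage-1 split is irrelevant to
    every stagewise quantity, which depend on the sufficient statistic)."""
    return TrialOutcome(stage_stopped=2, x1=min(s, att.n1), s=s, attained=att)


def enumerate_outcomes(att: AttainedDesign, p: float):
    """Yield (outcome, probability) over the full two-stage sample space."""
    for x1 in range(0, att.r1 + 1):
        yield (
            TrialOutcome(stage_stopped=1, x1=x1, s=x1, attained=att),
            float(binom.pmf(x1, att.n1, p)),
        )
    for x1 in range(att.r1 + 1, att.n1 + 1):
        for x2 in range(0, att.n2 + 1):
            yield (
                TrialOutcome(stage_stopped=2, x1=x1, s=x1 + x2, attained=att),
                float(binom.pmf(x1, att.n1, p) * binom.pmf(x2, att.n2, p)),
            )


class TestUmvue:
    def test_reported_response_rates(self, outcome_s7, outcome_s11):
        """7 and 11 total responses under the attained design give adjusted
        rates of 32.1% and exactly 50%."""
        assert format_percent(umvue(outcome_s7)) == "32.1"
        assert umvue(outcome_s7) == pytest.approx(0.32076346495634034, abs=1e-12)
        assert umvue(outcome_s11) == 0.5

    def test_stage1_stop_is_sample_proportion(self, attained):
        out = TrialOutcome(stage_stopped=1, x1=1, s=1, attained=attained)
        assert umvue(out) == pytest.approx(1 / 15)

    def test_degenerate_stage2_without_enrollment(self):
        """With n2=0 the estimator collapses to the stage-1 proportion."""
        att = AttainedDesign(r1=2, n1=15, n2=0)
        for s in (3, 7, 15):
            out = TrialOutcome(stage_stopped=2, x1=s, s=s, attained=att)
            assert umvue(out) == pytest.approx(s / 15)

    @pytest.mark.parametrize("p", [0.10, 0.15, 0.40])
    def test_unbiasedness_by_exhaustive_enumeration(self, attained, p):
        """E[UMVUE] = p when summed over the entire outcome space."""
        mean = sum(umvue(out) * w for out, w in enumerate_outcomes(attained, p))
        assert mean == pytest.approx(p, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(s=st.integers(3, 22))
    def test_estimate_stays_in_unit_interval(self, s):
        att = AttainedDesign(r1=2, n1=15, n2=7)
        assert 0.0 <= umvue(outcome_for_total(att, s)) <= 1.0


class TestStagewisePValue:
    def test_reported_p_values(self, outcome_s7, outcome_s11):
        """Adjusted tests against the 15% historical control."""
        assert round(stagewise_p_value(outcome_s7, 0.15), 3) == 0.036
        p11 = stagewise_p_value(outcome_s11, 0.15)
        assert float(f"{p11:.2g}") == 0.00012

    def test_impossible_data_under_null(self, outcome_s7):
        assert stagewise_p_value(outcome_s7, 0.0) == 0.0

    def test_strictly_decreasing_in_total_responses(self, attained):
        vals = [
            stagewise_p_value(outcome_for_total(attained, s), 0.15)
            for s in range(3, 23)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_stage1_stop_upper_tail(self, attained):
        """A futility stop reports the stage-1 upper tail (never rejects)."""
        out = TrialOutcome(stage_stopped=1, x1=2, s=2, attained=attained)
        expected = float(binom.sf(1, 15, 0.15))
        assert stagewise_p_value(out, 0.15) == pytest.approx(expected)

    def test_invalid_p0_rejected(self, outcome_s7):
        with pytest.raises(OutcomeError):
            stagewise_p_value(outcome_s7, 1.2)


class TestStagewiseCI:
    def test_reported_80pct_intervals(self, outcome_s7, outcome_s11):
        lo, hi = stagewise_ci(outcome_s7, 0.80)
        assert (format_percent(lo), format_percent(hi)) == ("18.7", "43.1")
        lo, hi = stagewise_ci(outcome_s11, 0.80)
        assert (format_percent(lo), format_percent(hi)) == ("34.6", "61.1")

    def test_duality_with_p_value_on_p0_grid(self, attained):
        """p0 lies below the level-L interval iff the upper-tail p-value at
        p0 is below (1-L)/2 (up to inversion tolerance)."""
        level = 0.80
        for s in (5, 7, 11, 15):
            out = outcome_for_total(attained, s)
            lo, hi = stagewise_ci(out, level)
            for p0 in np.arange(0.05, 0.96, 0.05):
                pval = stagewise_p_value(out, p0)
                if abs(p0 - lo) > 1e-4:  # skip the knife edge at the bound
                    assert (pval < (1 - level) / 2) == (p0 < lo)

    def test_equal_tail_interval_contains_default(self, outcome_s7):
        lo_kc, hi_kc = stagewise_ci(outcome_s7, 0.80)
        lo_eq, hi_eq = stagewise_ci(outcome_s7, 0.80, method="equal-tail")
        assert lo_eq == pytest.approx(lo_kc, abs=1e-9)  # same lower inversion
        assert hi_eq >= hi_kc  # conservative upper bound is wider

    def test_exact_coverage_of_equal_tail_interval(self, attained):
        """Full-outcome-space coverage >= 0.80 on a p grid by enumeration;
        stage-1 stops use the stage-1 tail inversion (Clopper-Pearson at
        (x1, n1)), completed trials the equal-tailed stagewise interval."""
        level = 0.80
        ci2 = {
            s: stagewise_ci(outcome_for_total(attained, s), level, method="equal-tail")
            for s in range(attained.r1 + 1, attained.n1 + attained.n2 + 1)
        }
        ci1 = {x1: clopper_pearson(x1, attained.n1, level) for x1 in range(attained.r1 + 1)}
        for p in np.arange(0.05, 0.96, 0.05):
            cov = 0.0
            for out, w in enumerate_outcomes(attained, p):
                lo, hi = ci1[out.x1] if out.stage_stopped == 1 else ci2[out.s]
                cov += w * (lo <= p <= hi)
            assert cov >= level - 1e-9, f"coverage {cov:.4f} at p={p:.2f}"

    def test_stage1_outcome_rejected(self, attained):
        out = TrialOutcome(stage_stopped=1, x1=0, s=0, attained=attained)
        with pytest.raises(OutcomeError):
            stagewise_ci(out, 0.80)

    def test_invalid_level_rejected(self, outcome_s7):
        with pytest.raises(OutcomeError):
            stagewise_ci(outcome_s7, 1.0)


class TestOutcomeValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(stage_stopped=1, x1=3, s=3),   # stop with x1 > r1
            dict(stage_stopped=1, x1=2, s=3),   # stop but s != x1
            dict(stage_stopped=2, x1=2, s=5),   # continued with x1 <= r1
            dict(stage_stopped=2, x1=5, s=13),  # s > x1 + n2
            dict(stage_stopped=2, x1=5, s=4),   # s < x1
            dict(stage_stopped=3, x1=5, s=5),   # bad stage
        ],
    )
    def test_inconsistent_outcomes_rejected(self, attained, kwargs):
        with pytest.raises(OutcomeError):
            TrialOutcome(attained=attained, **kwargs)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, lo, hi",
        [(4, 22, "5.2", "40.3"), (7, 17, "18.4", "67.1"), (10, 16, "35.4", "84.8")],
    )
    def test_reported_95pct_intervals(self, x, n, lo, hi):
        a, b = clopper_pearson(x, n, 0.95)
        assert (format_percent(a), format_percent(b)) == (lo, hi)

    def test_boundary_counts(self):
        assert clopper_pearson(0, 10, 0.95)[0] == 0.0
        assert clopper_pearson(10, 10, 0.95)[1] == 1.0

    def test_coverage_at_least_nominal_by_enumeration(self):
        """Exact coverage >= 95% for every n <= 30 on a p grid."""
        for n in range(1, 31):
            cis = [clopper_pearson(x, n, 0.95) for x in range(n + 1)]
            for p in np.arange(0.05, 0.96, 0.05):
                pmf = binom.pmf(np.arange(n + 1), n, p)
                cov = sum(w for x, w in enumerate(pmf) if cis[x][0] <= p <= cis[x][1])
                assert cov >= 0.95 - 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4, 0.95)


class TestOddsRatio:
    def test_histology_association(self):
        """Squamous 8/10 MPR vs non-squamous 10/34: OR 9.60 (1.73-53.4)."""
        orat, (lo, hi) = odds_ratio_2x2(((8, 2), (10, 24)))
        assert round(orat, 2) == 9.60
        assert round(lo, 2) == 1.73
        assert round(hi, 1) == 53.4

    def test_haldane_correction_for_zero_cell(self):
        """Smokers 18/34 vs never 0/10 needs the 0.5 correction."""
        orat, _ = odds_ratio_2x2(((18, 16), (0, 10)), zero_cell_rule="haldane")
        assert round(orat, 1) == 23.5  # printed as ~23.6 by a different fit

    def test_null_association(self):
        orat, (lo, hi) = odds_ratio_2x2(((6, 3), (4, 2)))
        assert orat == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_agrees_with_statsmodels_on_nonzero_table(self):
        from statsmodels.stats.contingency_tables import Table2x2

        t = [[12, 5], [7, 18]]
        orat, (lo, hi) = odds_ratio_2x2(t)
        ref = Table2x2(np.asarray(t))
        assert orat == pytest.approx(ref.oddsratio)
        assert (lo, hi) == pytest.approx(ref.oddsratio_confint(0.05))

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(((0, 0), (5, 5)))  # all-zero row
        with pytest.raises(ValueError):
            odds_ratio_2x2(((0, 5), (0, 5)))  # all-zero column
        with pytest.raises(ValueError):
            odds_ratio_2x2(((0, 5), (3, 5)), zero_cell_rule="none")
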