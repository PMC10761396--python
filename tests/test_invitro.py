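"""In vitro calling rules across the five assay families."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edscreen.calls import ActivityCall
from edscreen.curves import ConcentrationResponse
from edscreen.invitro import (
    BindingTriage,
    MetabolicEffect,
    RuleThresholds,
    classify_aromatase,
    classify_single_dose_binding,
    classify_steroidogenesis,
    classify_yes_yas,
    compare_metabolic_conditions,
)

T = RuleThresholds()
CONC = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])


def reporter_curve(chemical, assay, means, viability=None, conc=CONC):
    return ConcentrationResponse(
        chemical_id=chemical, assay_id=assay, concentrations=conc,
        responses=[np.array([m, m]) for m in means], viability=viability,
    )


class TestSingleDoseBinding:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (60, BindingTriage.SIGNIFICANT),
            (29, BindingTriage.FOLLOWUP),       # weak binding band
            (10, BindingTriage.NEGATIVE),
            (-30, BindingTriage.NEGATIVE_VARIABILITY),
            # boundary cases per the documented tie rules
            (50, BindingTriage.FOLLOWUP),       # "more than 50" is strict
            (25, BindingTriage.FOLLOWUP),       # closed band [25, 50]
            (-25, BindingTriage.NEGATIVE),      # "less than -25" is strict
        ],
    )
    def test_triage_bands(self, pct, expected):
        assert classify_single_dose_binding(pct, T) is expected

    @given(pct=st.floats(-200, 200, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_the_real_line(self, pct):
        """Every finite inhibition value gets exactly one triage label."""
        label = classify_single_dose_binding(pct, T)
        assert isinstance(label, BindingTriage)
        memberships = [
            pct > 50,
            25 <= pct <= 50,
            pct < -25,
            (-25 <= pct < 25),
        ]
        assert sum(memberships) == 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_single_dose_binding(float("nan"), T)


class TestAromatase:
    def test_followup_concentration_dependent_inhibition_is_positive(self):
        means = 100.0 / (1.0 + (61.0 / CONC))  # IC50 at 61 µM, in range
        res = classify_aromatase(20.0, reporter_curve("iso", "aromatase", means), T)
        assert res.call is ActivityCall.POSITIVE
        assert res.ic50 == pytest.approx(61.0, rel=0.05)

    def test_nonspecific_negative_resolved_by_flat_followup(self):
        res = classify_aromatase(-60.0, reporter_curve("x", "aromatase", np.zeros_like(CONC)), T)
        assert res.call is ActivityCall.NEGATIVE
        assert res.rationale == "nonspecific_resolved"

    def test_nonspecific_without_followup_is_inconclusive(self):
        res = classify_aromatase(-60.0, None, T)
        assert res.call is ActivityCall.INCONCLUSIVE

    def test_quiet_single_dose_without_followup_is_negative(self):
        assert classify_aromatase(0.0, None, T).call is ActivityCall.NEGATIVE

    def test_strong_single_dose_is_positive(self):
        res = classify_aromatase(70.0, None, T)
        assert res.call is ActivityCall.POSITIVE
        assert res.rationale == "above_threshold"


class TestYesYas:
    def panel(self, chemical="c", er_ag=None, er_ant=None, ar_ag=None, ar_ant=None,
              viability=None):
        flat = np.zeros_like(CONC)
        return dict(
            er_agonist=reporter_curve(chemical, "yes_agonist",
                                      er_ag if er_ag is not None else flat, viability),
            er_antagonist=reporter_curve(chemical, "yes_antagonist",
                                         er_ant if er_ant is not None else flat, viability),
            ar_agonist=reporter_curve(chemical, "yas_agonist",
                                      ar_ag if ar_ag is not None else flat, viability),
            ar_antagonist=reporter_curve(chemical, "yas_antagonist",
                                         ar_ant if ar_ant is not None else flat, viability),
        )

    def test_double_antagonist_positive_is_nonspecific(self):
        rising = np.array([0, 0, 5, 15, 40, 70, 90], dtype=float)
        res = classify_yes_yas(**self.panel(er_ant=rising, ar_ant=rising))
        assert res.calls["er_antagonist"] is ActivityCall.INCONCLUSIVE
        assert res.calls["ar_antagonist"] is ActivityCall.INCONCLUSIVE
        assert "nonspecific_pair" in res.flags["er_antagonist"]

    def test_nonspecific_rule_symmetric_under_channel_swap(self):
        a = np.array([0, 0, 5, 15, 40, 70, 90], dtype=float)
        b = np.array([0, 2, 12, 30, 55, 80, 95], dtype=float)
        r1 = classify_yes_yas(**self.panel(er_ant=a, ar_ant=b))
        r2 = classify_yes_yas(**self.panel(er_ant=b, ar_ant=a))
        assert r1.calls["er_antagonist"] is r2.calls["ar_antagonist"]
        assert r1.calls["ar_antagonist"] is r2.calls["er_antagonist"]

    def test_single_agonist_positive_at_nontoxic_concentrations(self):
        rising = np.array([0, 0, 12, 30, 60, 85, 95], dtype=float)
        viability = np.full(CONC.shape, 100.0)
        res = classify_yes_yas(**self.panel(er_ag=rising, viability=viability))
        assert res.calls["er_agonist"] is ActivityCall.POSITIVE
        assert all(
            res.calls[k] is ActivityCall.NEGATIVE
            for k in ("er_antagonist", "ar_agonist", "ar_antagonist")
        )

    def test_signal_only_in_cytotoxic_range_masked_and_flagged(self):
        """Antagonist signal only where growth collapses: negative with a
        follow-up recommendation (lower, more closely spaced concentrations)."""
        signal = np.array([0, 0, 0, 0, 0, 40, 80], dtype=float)
        viability = np.array([100, 100, 100, 100, 100, 40, 10], dtype=float)
        res = classify_yes_yas(**self.panel(ar_ant=signal, viability=viability))
        assert res.calls["ar_antagonist"] is ActivityCall.NEGATIVE
        assert "followup_recommended" in res.flags["ar_antagonist"]

    def test_antagonist_positive_without_growth_channel_is_flagged(self):
        rising = np.array([0, 0, 12, 30, 60, 85, 95], dtype=float)
        res = classify_yes_yas(**self.panel(er_ant=rising))
        assert res.calls["er_antagonist"] is ActivityCall.POSITIVE
        assert "no_cytotox_check" in res.flags["er_antagonist"]

    def test_mixed_chemicals_rejected(self):
        panel = self.panel()
        panel["ar_agonist"] = reporter_curve("other", "yas_agonist", np.zeros_like(CONC))
        with pytest.raises(ValueError, match="mixes chemicals"):
            classify_yes_yas(**panel)


class TestSteroidogenesis:
    def test_estrogen_increase_with_lec(self):
        conc = np.array([0.1, 1.0, 10.0, 100.0])
        est = np.array([1.0, 1.1, 1.5, 1.5])
        andr = np.ones(4)
        e, a = classify_steroidogenesis(est, andr, conc)
        assert e.call is ActivityCall.POSITIVE and e.direction == "increase"
        assert e.lec == pytest.approx(10.0)
        assert a.call is ActivityCall.NEGATIVE and a.lec is None

    def test_androgen_decrease_with_lec(self):
        conc = np.array([0.077, 0.77, 7.7, 77.0])
        andr = np.array([0.9, 0.5, 0.2, 0.06])
        e, a = classify_steroidogenesis(np.ones(4), andr, conc)
        assert a.call is ActivityCall.POSITIVE and a.direction == "decrease"
        assert a.lec == pytest.approx(0.77)

    def test_flat_folds_negative_both_channels(self):
        conc = np.array([1.0, 10.0, 100.0])
        e, a = classify_steroidogenesis(np.ones(3), np.ones(3), conc)
        assert e.call is a.call is ActivityCall.NEGATIVE

    def test_fold_threshold_is_inclusive_and_symmetric(self):
        conc = np.array([1.0, 10.0])
        e, _ = classify_steroidogenesis([1.0, 1.5], [1.0, 1.0], conc)
        assert e.call is ActivityCall.POSITIVE
        _, a = classify_steroidogenesis([1.0, 1.0], [1.0, 1 / 1.5], conc)
        assert a.call is ActivityCall.POSITIVE


class TestMetabolicComparison:
    @pytest.mark.parametrize(
        "without,with_,expected",
        [
            (ActivityCall.POSITIVE, ActivityCall.NEGATIVE, MetabolicEffect.DETOXIFIED),
            (ActivityCall.NEGATIVE, ActivityCall.POSITIVE, MetabolicEffect.ACTIVATED),
            (ActivityCall.NEGATIVE, ActivityCall.NEGATIVE, MetabolicEffect.UNCHANGED),
            (ActivityCall.POSITIVE, ActivityCall.POSITIVE, MetabolicEffect.UNCHANGED),
            (ActivityCall.WEAK_POSITIVE, ActivityCall.NEGATIVE, MetabolicEffect.DETOXIFIED),
        ],
    )
    def test_effect_classification(self, without, with_, expected):
        assert compare_metabolic_conditions(without, with_).effect is expected

    def test_inconclusive_side_gives_low_confidence_unchanged(self):
        res = compare_metabolic_conditions(ActivityCall.INCONCLUSIVE, ActivityCall.POSITIVE)
        assert res.effect is MetabolicEffect.UNCHANGED and res.low_confidence


class TestThresholdValidation:
    def test_band_must_lie_below_significant(self):
        with pytest.raises(ValueError):
            RuleThresholds(significant_binding_pct=40, followup_band_pct=(25, 50))
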