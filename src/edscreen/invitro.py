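"""Decision rules turning in vitro readouts into activity calls.

Five assay families are covered, each with its own calling convention:

* **YES/YAS** (yeast reporter): per-endpoint threshold crossing with a
  non-specificity rule — a chemical positive in *both* the ER- and
  AR-antagonist channels is scored inconclusive in both, and responses at
  concentrations where yeast growth drops below the viability threshold are
  masked before calling.
* **ER/AR radioligand binding**: a single-dose (10 µM) triage into
  significant / follow-up / negative bands, with moderate *negative*
  inhibition values treated as signal variability rather than biology.
* **Aromatase** (recombinant CYP19A1): single-dose triage where large
  negative values flag non-specific interference requiring a follow-up
  concentration series.
* **CALUX** (mammalian reporter): LEC derivation at a fraction of the
  reference maximum (see :func:`edscreen.curves.derive_lec`).
* **H295R steroidogenesis**: fold-of-control calls on hormone production
  with a symmetric 1.5-fold / (1/1.5)-fold band.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .calls import ActivityCall
from .curves import (
    ConcentrationResponse,
    FitResult,
    derive_lec,
    derive_relative_ic50,
    fit_concentration_response,
)

__all__ = [
    "RuleThresholds",
    "PotencyResult",
    "BindingTriage",
    "MetabolicEffect",
    "MetabolicComparison",
    "YesYasResult",
    "SteroidogenesisCall",
    "classify_single_dose_binding",
    "classify_aromatase",
    "classify_yes_yas",
    "classify_steroidogenesis",
    "compare_metabolic_conditions",
]


@dataclasses.dataclass(frozen=True)
class RuleThresholds:
    """All tunable cut-offs of the in vitro calling rules.

    Attributes
    ----------
    significant_binding_pct:
        Single-dose inhibition above which binding is significant
        (strictly greater than; default 50%).
    followup_band_pct:
        Closed inhibition interval triggering a follow-up dose–response
        assay (default [25, 50]).
    artifact_negative_pct:
        Inhibition strictly below this (default −25%) is attributed to
        signal variability around the control, not biology.
    nonspecific_negative_pct:
        Aromatase single-dose values at or below this (default −50%, i.e.
        magnitude ≥ 50) flag non-specific interference.
    lec_threshold_fraction:
        Fraction of the assay reference maximum defining the LEC
        (default 0.10, the PC10 convention).
    steroid_fold_threshold:
        Fold-of-control bound for steroidogenesis calls (default 1.5; the
        decrease bound is its reciprocal).
    cytotox_viability_pct:
        Viability (% of control) below which responses are masked as
        cytotoxicity-confounded (default 80%).
    """

    significant_binding_pct: float = 50.0
    followup_band_pct: tuple[float, float] = (25.0, 50.0)
    artifact_negative_pct: float = -25.0
    nonspecific_negative_pct: float = -50.0
    lec_threshold_fraction: float = 0.10
    steroid_fold_threshold: float = 1.5
    cytotox_viability_pct: float = 80.0

    def __post_init__(self) -> None:
        lo, hi = self.followup_band_pct
        if not all(
            np.isfinite(v)
            for v in (
                self.significant_binding_pct,
                lo,
                hi,
                self.artifact_negative_pct,
                self.nonspecific_negative_pct,
                self.cytotox_viability_pct,
            )
        ):
            raise ValueError("thresholds must be finite")
        if not lo <= hi <= self.significant_binding_pct:
            raise ValueError("follow-up band must lie below significant_binding_pct")
        if not 0 < self.lec_threshold_fraction < 1:
            raise ValueError("lec_threshold_fraction must be in (0, 1)")
        if self.steroid_fold_threshold <= 1:
            raise ValueError("steroid_fold_threshold must exceed 1")


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclasses.dataclass(frozen=True)
class PotencyResult:
    """Derived potency bundle attached to a call.

    ``ic50``/``ki``/``lec`` in µM when present; ``max_effect`` in the
    assay's response units; ``rationale`` is a short machine-readable code
    naming the rule that produced the call (e.g. ``nonspecific_pair``,
    ``cytotox_masked``, ``below_threshold``).
    """

    call: ActivityCall
    ic50: float | None = None
    ki: float | None = None
    lec: float | None = None
    max_effect: float | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ki is not None and self.ki > self.ic50 * (1 + 1e-12):
            raise ValueError("ki must not exceed ic50")


class BindingTriage(str, enum.Enum):
    """Outcome of the single-dose (10 µM) radioligand binding screen."""

    SIGNIFICANT = "significant"
    FOLLOWUP = "followup"
    NEGATIVE = "negative"
    NEGATIVE_VARIABILITY = "negative_variability"


def classify_single_dose_binding(
    pct_inhibition: float, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> BindingTriage:
    """Triage a single-dose % inhibition of control specific binding.

    The bands partition the real line; boundary handling is strict as
    documented on :class:`RuleThresholds`: > 50 significant, [25, 50]
    follow-up, < −25 variability, everything else negative.
    """
    if not np.isfinite(pct_inhibition):
        raise ValueError("pct_inhibition must be finite")
    lo, hi = thresholds.followup_band_pct
    if pct_inhibition > thresholds.significant_binding_pct:
        return BindingTriage.SIGNIFICANT
    if lo <= pct_inhibition <= hi:
        return BindingTriage.FOLLOWUP
    if pct_inhibition < thresholds.artifact_negative_pct:
        return BindingTriage.NEGATIVE_VARIABILITY
    return BindingTriage.NEGATIVE


def classify_aromatase(
    single_dose_pct: float,
    followup_curve: ConcentrationResponse | None = None,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> PotencyResult:
    """Call aromatase inhibition from the 10 µM screen plus optional
    follow-up concentration series.

    Rules: inhibition strictly above the significant threshold is positive;
    a negative value of magnitude ≥ 50% flags non-specific interference and
    demands a follow-up series (inconclusive without one); with a follow-up
    series the call is positive only when a converged, rising fit places the
    relative IC50 inside the tested range.
    """
    if not np.isfinite(single_dose_pct):
        raise ValueError("single_dose_pct must be finite")

    fit: FitResult | None = None
    ic50 = None
    if followup_curve is not None:
        fit = fit_concentration_response(followup_curve)
        ic50 = derive_relative_ic50(fit)
        in_range = (
            ic50 is not None
            and followup_curve.concentrations[0] <= ic50 <= followup_curve.concentrations[-1]
        )

    if single_dose_pct > thresholds.significant_binding_pct:
        return PotencyResult(
            call=ActivityCall.POSITIVE,
            ic50=ic50,
            max_effect=single_dose_pct if fit is None else fit.max_observed_effect,
            rationale="above_threshold",
        )

    nonspecific = single_dose_pct <= thresholds.nonspecific_negative_pct
    if followup_curve is None:
        if nonspecific:
            return PotencyResult(
                call=ActivityCall.INCONCLUSIVE,
                max_effect=single_dose_pct,
                rationale="nonspecific_unresolved",
            )
        return PotencyResult(
            call=ActivityCall.NEGATIVE,
            max_effect=single_dose_pct,
            rationale="below_threshold",
        )

    if in_range:
        return PotencyResult(
            call=ActivityCall.POSITIVE,
            ic50=ic50,
            max_effect=fit.max_observed_effect,
            rationale="followup_concentration_dependent",
        )
    return PotencyResult(
        call=ActivityCall.NEGATIVE,
        max_effect=fit.max_observed_effect,
        rationale="nonspecific_resolved" if nonspecific else "followup_negative",
    )


@dataclasses.dataclass(frozen=True)
class YesYasResult:
    """Per-endpoint calls of a YES/YAS panel plus rule flags.

    ``calls`` maps the endpoint names (``er_agonist``, ``er_antagonist``,
    ``ar_agonist``, ``ar_antagonist``) to ActivityCalls; ``flags`` carries
    per-endpoint rule annotations (``nonspecific_pair``,
    ``followup_recommended``, ``no_cytotox_check``).
    """

    calls: dict[str, ActivityCall]
    flags: dict[str, tuple[str, ...]]


def _masked_call(
    curve: ConcentrationResponse, thresholds: RuleThresholds
) -> tuple[ActivityCall, tuple[str, ...]]:
    """Threshold-crossing call for one reporter endpoint with viability
    masking; flags a negative whose only effective signal lay in the masked
    range."""
    means = curve.mean_responses()
    threshold = 100.0 * thresholds.lec_threshold_fraction
    flags: list[str] = []
    if curve.viability is None:
        mask = np.zeros(means.shape, dtype=bool)
    else:
        mask = curve.viability < thresholds.cytotox_viability_pct
    unmasked_hit = bool(np.any(means[~mask] >= threshold))
    masked_hit = bool(np.any(means[mask] >= threshold))
    if unmasked_hit:
        return ActivityCall.POSITIVE, ()
    if masked_hit:
        flags.append("followup_recommended")
    return ActivityCall.NEGATIVE, tuple(flags)


def classify_yes_yas(
    er_agonist: ConcentrationResponse,
    er_antagonist: ConcentrationResponse,
    ar_agonist: ConcentrationResponse,
    ar_antagonist: ConcentrationResponse,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> YesYasResult:
    """Call the four YES/YAS endpoints of one chemical.

    Each curve's viability field is the yeast growth channel; responses at
    concentrations with growth below the viability threshold are masked
    before calling. A chemical positive in both antagonist channels is an
    indication of non-specific interference: both antagonist calls become
    inconclusive. Antagonist positives called without any growth channel
    are annotated ``no_cytotox_check``.
    """
    panel = {
        "er_agonist": er_agonist,
        "er_antagonist": er_antagonist,
        "ar_agonist": ar_agonist,
        "ar_antagonist": ar_antagonist,
    }
    chems = {c.chemical_id for c in panel.values()}
    if len(chems) != 1:
        raise ValueError(f"panel mixes chemicals: {sorted(chems)}")

    calls: dict[str, ActivityCall] = {}
    flags: dict[str, list[str]] = {k: [] for k in panel}
    for name, curve in panel.items():
        call, f = _masked_call(curve, thresholds)
        calls[name] = call
        flags[name].extend(f)

    if (
        calls["er_antagonist"] is ActivityCall.POSITIVE
        and calls["ar_antagonist"] is ActivityCall.POSITIVE
    ):
        for name in ("er_antagonist", "ar_antagonist"):
            calls[name] = ActivityCall.INCONCLUSIVE
            flags[name].append("nonspecific_pair")

    for name in ("er_antagonist", "ar_antagonist"):
        if calls[name] is ActivityCall.POSITIVE and panel[name].viability is None:
            flags[name].append("no_cytotox_check")

    return YesYasResult(
        calls=calls, flags={k: tuple(v) for k, v in flags.items()}
    )


@dataclasses.dataclass(frozen=True)
class SteroidogenesisCall:
    """Call for one hormone channel of the H295R assay."""

    call: ActivityCall
    lec: float | None
    direction: str | None  # "increase" | "decrease" | None


def _fold_call(
    folds: np.ndarray, concentrations: np.ndarray, threshold: float
) -> SteroidogenesisCall:
    up = folds >= threshold
    down = folds <= 1.0 / threshold
    up_first = int(np.argmax(up)) if up.any() else None
    down_first = int(np.argmax(down)) if down.any() else None
    if up_first is not None and (down_first is None or up_first <= down_first):
        return SteroidogenesisCall(
            ActivityCall.POSITIVE, float(concentrations[up_first]), "increase"
        )
    if down_first is not None:
        return SteroidogenesisCall(
            ActivityCall.POSITIVE, float(concentrations[down_first]), "decrease"
        )
    return SteroidogenesisCall(ActivityCall.NEGATIVE, None, None)


def classify_steroidogenesis(
    estrogen_folds,
    androgen_folds,
    concentrations,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[SteroidogenesisCall, SteroidogenesisCall]:
    """Call hormone-production changes in the H295R steroidogenesis assay.

    A channel is positive when production reaches ≥ 1.5-fold of control
    (increase) or ≤ 1/1.5-fold (decrease) at any tested concentration; the
    LEC is the lowest tested concentration meeting the criterion. Returns
    the (oestrogen, androgen) pair of calls.
    """
    conc = np.asarray(concentrations, dtype=float)
    e = np.asarray(estrogen_folds, dtype=float)
    a = np.asarray(androgen_folds, dtype=float)
    if e.shape != conc.shape or a.shape != conc.shape:
        raise ValueError("fold series must align with concentrations")
    if np.any(e <= 0) or np.any(a <= 0):
        raise ValueError("fold-of-control values must be positive")
    t = thresholds.steroid_fold_threshold
    return _fold_call(e, conc, t), _fold_call(a, conc, t)


class MetabolicEffect(str, enum.Enum):
    """Effect of metabolic supplementation on an assay outcome."""

    DETOXIFIED = "detoxified"
    ACTIVATED = "activated"
    UNCHANGED = "unchanged"


@dataclasses.dataclass(frozen=True)
class MetabolicComparison:
    effect: MetabolicEffect
    low_confidence: bool = False


def compare_metabolic_conditions(
    call_without: ActivityCall, call_with: ActivityCall
) -> MetabolicComparison:
    """Compare one assay's call without vs with a metabolic supplement.

    positive → negative is detoxification (the parent's activity is
    abolished by metabolism); negative → positive is activation; anything
    else is unchanged. An inconclusive on either side yields unchanged with
    a low-confidence flag.
    """
    from .calls import POSITIVE_FAMILY

    if ActivityCall.INCONCLUSIVE in (call_without, call_with):
        return MetabolicComparison(MetabolicEffect.UNCHANGED, low_confidence=True)
    if call_without in POSITIVE_FAMILY and call_with is ActivityCall.NEGATIVE:
        return MetabolicComparison(MetabolicEffect.DETOXIFIED)
    if call_without is ActivityCall.NEGATIVE and call_with in POSITIVE_FAMILY:
        return MetabolicComparison(MetabolicEffect.ACTIVATED)
    return MetabolicComparison(MetabolicEffect.UNCHANGED)
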