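"""ToxCast-style reference final calls.

The reference classification each in silico model is scored against is
derived from high-throughput screening evidence per chemical × target: the
pathway-model scores (0–1 values summarising receptor agonism/antagonism
across the assay battery; a score above 0.1 marks a significant
interaction), the active-flagged assay counts with their cytotoxicity
overlap, and an optional potency class. The combination rule is an explicit
rule table (:func:`derive_reference_call`).

The ten-chemical study panel's reference calls ship as a packaged fixture
(:func:`load_reference_fixture`): every row carries a provenance tag saying
whether the entry is recoverable from the study's main narrative or only
from supplementary material.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

from .calls import ActivityCall, parse_call
from .consensus import ReferenceCallSet

__all__ = [
    "ToxcastEvidence",
    "derive_reference_call",
    "load_reference_fixture",
    "reference_fixture_path",
]


@dataclasses.dataclass(frozen=True)
class ToxcastEvidence:
    """High-throughput screening evidence for one chemical × target.

    ``agonism_score`` / ``antagonism_score`` are pathway-model values in
    [0, 1] (None when the model did not cover the chemical);
    ``active_assay_count`` of ``assay_count`` assays were active-flagged,
    ``confounded_active_count`` of those with overlapping cytotoxicity.
    ``potency_class`` is an ordinal potency level (e.g. a consensus potency
    category), or None; any class above zero counts as supportive.
    """

    chemical_id: str
    target: str
    agonism_score: float | None = None
    antagonism_score: float | None = None
    active_assay_count: int = 0
    assay_count: int = 0
    confounded_active_count: int = 0
    potency_class: int | None = None

    def __post_init__(self) -> None:
        for s in (self.agonism_score, self.antagonism_score):
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError("pathway scores must lie in [0, 1]")
        if self.active_assay_count > self.assay_count:
            raise ValueError("active_assay_count cannot exceed assay_count")
        if self.confounded_active_count > self.active_assay_count:
            raise ValueError("confounded actives cannot exceed actives")

    @property
    def scores(self) -> list[float]:
        return [s for s in (self.agonism_score, self.antagonism_score) if s is not None]

    @property
    def clean_active_count(self) -> int:
        """Active assays not confounded by cytotoxicity."""
        return self.active_assay_count - self.confounded_active_count


def derive_reference_call(
    evidence: ToxcastEvidence, score_threshold: float = 0.1
) -> ActivityCall:
    """Rule table combining pathway scores, assay flags and potency class.

    1. No pathway scores and no assay summary at all → not_evaluated.
    2. Any pathway score strictly above ``score_threshold`` → positive
       (significant receptor interaction).
    3. Non-confounded active assays present AND a supportive potency class
       → positive.
    4. Any active assays present (all cytotoxicity-confounded, or clean but
       without potency support) → inconclusive: activity was seen but is
       borderline or confounded.
    5. Otherwise (scores at or below threshold, no active assays)
       → negative.

    The rule is monotone in the pathway scores: raising a score can only
    move the call toward positive.
    """
    has_scores = bool(evidence.scores)
    has_assays = evidence.assay_count > 0
    if not has_scores and not has_assays:
        return ActivityCall.NOT_EVALUATED
    if any(s > score_threshold for s in evidence.scores):
        return ActivityCall.POSITIVE
    if evidence.clean_active_count > 0 and (evidence.potency_class or 0) > 0:
        return ActivityCall.POSITIVE
    if evidence.active_assay_count > 0:
        return ActivityCall.INCONCLUSIVE
    return ActivityCall.NEGATIVE


def reference_fixture_path():
    """Path-like handle on the packaged reference-call table."""
    return resources.files("edscreen.data") / "reference_calls.csv"


def load_reference_fixture() -> ReferenceCallSet:
    """Load the packaged ten-chemical reference-call panel.

    ER: five positives (tamoxifen, 4-TO, mestanolone, daidzein, BBP), three
    negatives (MBP, DEABA, terephthalic acid), two inconclusives (DBABA,
    isoeugenol). AR: mestanolone positive; tamoxifen, daidzein and BBP
    inconclusive; the rest negative. Aromatase: tamoxifen positive, 4-TO
    inconclusive, the other eight negative. Excluding inconclusives leaves
    included panels of 8 (ER), 7 (AR) and 9 (aromatase) chemicals.
    """
    with resources.as_file(reference_fixture_path()) as path:
        df = pd.read_csv(path)
    calls = df.pivot(index="chemical_id", columns="target", values="call").map(parse_call)
    prov = df.pivot(index="chemical_id", columns="target", values="provenance")
    # preserve panel order from the file
    order = list(dict.fromkeys(df["chemical_id"]))
    return ReferenceCallSet(calls=calls.loc[order], provenance=prov.loc[order])
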