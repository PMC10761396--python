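"""Consensus calling over panels of in silico predictions, and scoring of
each model's efficiency and correctness against a reference-call set.

A *final in silico call* for one chemical × target is a majority vote over
the distinct calls (positive family vs negative) of every model addressing
that target, regardless of endpoint role; a winning positive additionally
carries a high-confidence flag when at least one binding-role model and at
least one activation/antagonism-role model agree on the positive, since
binding and activation are mechanistically linked.

Two performance metrics are computed per model against the reference set:

* **% efficiency** — the share of included chemicals for which the model
  returned a distinct call at all (out-of-domain and inconclusive results
  are the failures this metric counts).
* **% correct** — among distinct calls, the share matching the reference
  sign.

"Included" chemicals are by default those whose *reference* call for the
model's target is itself distinct (reference-inconclusive chemicals are
excluded from both metrics); the full panel can be used instead via
``denominator="panel"``. Out-of-domain chemicals are by default excluded
from the %-correct denominator (``oad_policy="exclude"``); the alternative
policy ``count_as_incorrect`` scores them as zeros. All percentages round
half-up to integers.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from .calls import (
    ActivityCall,
    call_sign,
    is_distinct,
    round_half_up,
)

__all__ = [
    "ModelSpec",
    "ModelPredictionMatrix",
    "ReferenceCallSet",
    "FinalCall",
    "ModelPerformance",
    "PerformanceSummary",
    "TargetSummary",
    "derive_final_insilico_call",
    "compute_efficiency",
    "compute_pct_correct",
    "summarize_performance",
]

TARGETS = ("ER", "AR", "aromatase")
ENDPOINT_ROLES = ("binding", "activation", "antagonist", "inhibition")
#: roles counting toward the binding arm of the high-confidence rule
_BINDING_ROLES = frozenset({"binding"})
#: roles counting toward the activation/antagonism arm
_ACTIVITY_ROLES = frozenset({"activation", "antagonist", "inhibition"})


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One in silico model: identifier, its target and its endpoint role."""

    model_id: str
    target: str
    endpoint_role: str

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.endpoint_role not in ENDPOINT_ROLES:
            raise ValueError(f"unknown endpoint role {self.endpoint_role!r}")


@dataclasses.dataclass
class ModelPredictionMatrix:
    """Chemicals × models grid of activity calls from in silico tools.

    ``calls`` is a DataFrame indexed by chemical with one column per
    model_id; every cell is populated (``not_evaluated`` is an allowed
    state). ``in_training_set`` flags chemicals that were part of a model's
    training data (informational; not used by the metrics).
    """

    models: list[ModelSpec]
    calls: pd.DataFrame
    in_training_set: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate model_id")
        if list(self.calls.columns) != ids:
            self.calls = self.calls[ids]
        if self.calls.isna().any().any():
            raise ValueError("every cell of the call grid must be populated")
        for col in self.calls.columns:
            self.calls[col] = self.calls[col].map(ActivityCall)
        if self.in_training_set is None:
            self.in_training_set = pd.DataFrame(
                False, index=self.calls.index, columns=self.calls.columns
            )

    @property
    def chemicals(self) -> list[str]:
        return list(self.calls.index)

    def model(self, model_id: str) -> ModelSpec:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    def models_for_target(self, target: str) -> list[ModelSpec]:
        return [m for m in self.models if m.target == target]


@dataclasses.dataclass
class ReferenceCallSet:
    """Per chemical × target reference classification.

    ``calls`` is a DataFrame indexed by chemical with one column per
    target; values are positive / negative / inconclusive. ``provenance``
    optionally records, per cell, whether the entry is recoverable from the
    main text or only from supplementary material.
    """

    calls: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in self.calls.columns:
            self.calls[col] = self.calls[col].map(ActivityCall)
        if self.calls.isna().any().any():
            raise ValueError("every chemical needs a call for every target")

    @property
    def chemicals(self) -> list[str]:
        return list(self.calls.index)

    def call(self, chemical: str, target: str) -> ActivityCall:
        return self.calls.at[chemical, target]

    def included_chemicals(self, target: str) -> list[str]:
        """Chemicals whose reference call for ``target`` is distinct."""
        col = self.calls[target]
        return [c for c in self.calls.index if is_distinct(col[c])]


@dataclasses.dataclass(frozen=True)
class FinalCall:
    """Consensus outcome for one chemical × target."""

    call: ActivityCall
    high_confidence: bool
    n_positive: int
    n_negative: int


def derive_final_insilico_call(
    chemical: str, target: str, matrix: ModelPredictionMatrix
) -> FinalCall:
    """Majority vote over all distinct model calls for one chemical × target.

    weak_positive votes as positive; inconclusive / out-of-domain /
    not-evaluated calls do not vote. An exact tie, or no distinct calls at
    all, yields inconclusive. No models for the target yields
    not_evaluated. A winning positive is flagged high-confidence when both
    a binding-role and an activation/antagonism-role model are positive.
    """
    models = matrix.models_for_target(target)
    if not models:
        return FinalCall(ActivityCall.NOT_EVALUATED, False, 0, 0)
    votes = Counter()
    positive_roles: set[str] = set()
    for m in models:
        sign = call_sign(matrix.calls.at[chemical, m.model_id])
        if sign is None:
            continue
        votes[sign] += 1
        if sign > 0:
            positive_roles.add(m.endpoint_role)
    n_pos, n_neg = votes[1], votes[-1]
    if n_pos == n_neg:  # includes the no-distinct-calls case (0 == 0)
        return FinalCall(ActivityCall.INCONCLUSIVE, False, n_pos, n_neg)
    if n_pos > n_neg:
        high = bool(positive_roles & _BINDING_ROLES) and bool(
            positive_roles & _ACTIVITY_ROLES
        )
        return FinalCall(ActivityCall.POSITIVE, high, n_pos, n_neg)
    return FinalCall(ActivityCall.NEGATIVE, False, n_pos, n_neg)


def _included(
    model: ModelSpec, matrix: ModelPredictionMatrix, reference: ReferenceCallSet,
    denominator: str,
) -> list[str]:
    if denominator == "panel":
        return matrix.chemicals
    if denominator == "included":
        inc = set(reference.included_chemicals(model.target))
        return [c for c in matrix.chemicals if c in inc]
    raise ValueError(f"unknown denominator policy {denominator!r}")


def compute_efficiency(
    model_id: str,
    matrix: ModelPredictionMatrix,
    reference: ReferenceCallSet,
    denominator: str = "included",
) -> int:
    """% of included chemicals for which the model returned a distinct call.

    Out-of-domain, inconclusive and not-evaluated results all count against
    efficiency. Rounded half-up to an integer percent.
    """
    model = matrix.model(model_id)
    chems = _included(model, matrix, reference, denominator)
    if not chems:
        raise ValueError(f"no included chemicals for {model_id} / {model.target}")
    n_distinct = sum(is_distinct(matrix.calls.at[c, model_id]) for c in chems)
    return round_half_up(100.0 * n_distinct / len(chems))


@dataclasses.dataclass(frozen=True)
class ModelPerformance:
    """Per-model scorecard against the reference set.

    ``pct_correct`` is None (undefined) when the model produced no distinct
    call for any included chemical — never coerced to 0 or 100.
    """

    model_id: str
    target: str
    pct_correct: int | None
    pct_efficiency: int
    n_included: int
    n_distinct: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_distinct > self.n_included:
            raise ValueError("n_distinct cannot exceed n_included")
        if self.pct_correct is not None and not 0 <= self.pct_correct <= 100:
            raise ValueError("pct_correct out of range")
        if not 0 <= self.pct_efficiency <= 100:
            raise ValueError("pct_efficiency out of range")


def compute_pct_correct(
    model_id: str,
    matrix: ModelPredictionMatrix,
    reference: ReferenceCallSet,
    oad_policy: str = "exclude",
    denominator: str = "included",
) -> ModelPerformance:
    """Score one model's calls against the reference signs.

    The %-correct denominator is the included chemicals with distinct model
    calls; under ``oad_policy="count_as_incorrect"`` chemicals the model
    declared out-of-domain are added to the denominator and scored zero
    (the footnote-style convention). The numerator is distinct calls whose
    sign (positive family vs negative) matches the reference.
    """
    if oad_policy not in ("exclude", "count_as_incorrect"):
        raise ValueError(f"unknown oad_policy {oad_policy!r}")
    model = matrix.model(model_id)
    chems = _included(model, matrix, reference, denominator)
    if not chems:
        raise ValueError(f"no included chemicals for {model_id} / {model.target}")
    n_distinct = n_correct = n_oad = 0
    for c in chems:
        call = matrix.calls.at[c, model_id]
        if call is ActivityCall.OUT_OF_DOMAIN:
            n_oad += 1
            continue
        if not is_distinct(call):
            continue
        n_distinct += 1
        if call_sign(call) == call_sign(reference.call(c, model.target)):
            n_correct += 1
    denom = n_distinct + (n_oad if oad_policy == "count_as_incorrect" else 0)
    pct = round_half_up(100.0 * n_correct / denom) if denom else None
    return ModelPerformance(
        model_id=model_id,
        target=model.target,
        pct_correct=pct,
        pct_efficiency=round_half_up(100.0 * n_distinct / len(chems)),
        n_included=len(chems),
        n_distinct=n_distinct,
        n_correct=n_correct,
    )


@dataclasses.dataclass(frozen=True)
class TargetSummary:
    """Aggregate of one target's column of the performance table."""

    target: str
    n_models: int
    mean_pct_correct: int
    min_pct_correct: int
    n_full_efficiency: int


@dataclasses.dataclass(frozen=True)
class PerformanceSummary:
    """Cross-model summary: per-target aggregates plus, for models scored on
    both ER and AR, the pooled combined correct-call rate
    (numerators and denominators summed before dividing)."""

    per_target: dict[str, TargetSummary]
    combined_er_ar: dict[str, int]


def summarize_performance(table: list[ModelPerformance]) -> PerformanceSummary:
    """Summarise a performance table per target.

    Per target: mean %-correct (half-up, over models with a defined value),
    the minimum %-correct, and the count of models at 100% efficiency.
    Additionally, for each model name appearing under both ER and AR, the
    pooled ER+AR correct-call rate. Pooling across targets other than this
    ER+AR statistic is rejected.
    """
    if not table:
        raise ValueError("empty performance table")
    per_target: dict[str, TargetSummary] = {}
    for target in sorted({p.target for p in table}):
        rows = [p for p in table if p.target == target]
        defined = [p.pct_correct for p in rows if p.pct_correct is not None]
        if not defined:
            raise ValueError(f"no defined %-correct for target {target}")
        per_target[target] = TargetSummary(
            target=target,
            n_models=len(rows),
            mean_pct_correct=round_half_up(sum(defined) / len(defined)),
            min_pct_correct=min(defined),
            n_full_efficiency=sum(p.pct_efficiency == 100 for p in rows),
        )
    combined: dict[str, int] = {}
    er = {p.model_id: p for p in table if p.target == "ER"}
    ar = {p.model_id: p for p in table if p.target == "AR"}
    for mid in sorted(set(er) & set(ar)):
        num = er[mid].n_correct + ar[mid].n_correct
        den = er[mid].n_distinct + ar[mid].n_distinct
        if den:
            combined[mid] = round_half_up(100.0 * num / den)
    return PerformanceSummary(per_target=per_target, combined_er_ar=combined)
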