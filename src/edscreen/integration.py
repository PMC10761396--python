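"""Weight-of-evidence integration and the summary heatmap.

Three evidence classes feed the overall call for a chemical × target: the
in silico consensus call, the in vitro assay calls, and the reference
classification. The integration is a fixed, totally ordered rule list
(:func:`integrate_weight_of_evidence`): concordant negatives give a
confident negative, concordant positives a positive, and opposition
between the in silico and in vitro streams is never averaged away — it
yields an inconclusive that flags the chemical for follow-up.

An in vitro positive for rule purposes is any non-masked positive-family
assay call at any tested concentration; potency does not gate the call,
since exposure comparison belongs to later assessment tiers.
"""

from __future__ import annotations

import dataclasses

import matplotlib
import numpy as np
import pandas as pd

from .calls import ActivityCall, POSITIVE_FAMILY
from .invitro import PotencyResult

__all__ = [
    "EvidenceBundle",
    "OverallCall",
    "integrate_weight_of_evidence",
    "render_summary_heatmap",
    "heatmap_table_to_calls",
    "CALL_COLOURS",
]


@dataclasses.dataclass(frozen=True)
class EvidenceBundle:
    """All evidence lines for one chemical × target.

    ``invitro`` is a list of (assay_id, call, potency-or-None) triples; the
    list may be empty (integration then falls back to in silico vs
    reference concordance).
    """

    chemical_id: str
    target: str
    insilico: ActivityCall
    invitro: tuple[tuple[str, ActivityCall, PotencyResult | None], ...]
    reference: ActivityCall

    def __post_init__(self) -> None:
        object.__setattr__(self, "invitro", tuple(self.invitro))
        if (
            self.insilico is ActivityCall.NOT_EVALUATED
            and not self.invitro
            and self.reference is ActivityCall.NOT_EVALUATED
        ):
            raise ValueError("bundle must carry at least one evidence line")


@dataclasses.dataclass(frozen=True)
class OverallCall:
    """Integrated conclusion with confidence tier and rule identifier."""

    call: ActivityCall
    confidence: str  # "high" | "moderate" | "low"
    rationale: str


def _is_negative(call: ActivityCall) -> bool:
    return call is ActivityCall.NEGATIVE


def _is_positive(call: ActivityCall) -> bool:
    return call in POSITIVE_FAMILY


def integrate_weight_of_evidence(bundle: EvidenceBundle) -> OverallCall:
    """Apply the fixed rule order to one evidence bundle.

    1. All three classes negative → negative / high.
    2. Every in vitro call negative AND (reference negative OR in silico
       negative) → negative / moderate.
    3. In silico positive AND at least one in vitro positive → positive
       (high confidence when the reference agrees, else moderate).
    4. In silico and in vitro carry opposing signs → inconclusive / low.
    5. Anything else → inconclusive / low.

    With no in vitro evidence at all, the call falls back to in silico vs
    reference concordance at low confidence.
    """
    invitro_calls = [c for _, c, _ in bundle.invitro]
    if not invitro_calls:
        if _is_negative(bundle.insilico) and _is_negative(bundle.reference):
            return OverallCall(ActivityCall.NEGATIVE, "low", "no_invitro_concordant_negative")
        if _is_positive(bundle.insilico) and _is_positive(bundle.reference):
            return OverallCall(ActivityCall.POSITIVE, "low", "no_invitro_concordant_positive")
        return OverallCall(ActivityCall.INCONCLUSIVE, "low", "no_invitro_discordant")

    all_invitro_negative = all(_is_negative(c) for c in invitro_calls)
    any_invitro_positive = any(_is_positive(c) for c in invitro_calls)

    if all_invitro_negative and _is_negative(bundle.insilico) and _is_negative(bundle.reference):
        return OverallCall(ActivityCall.NEGATIVE, "high", "all_negative")
    if all_invitro_negative and (_is_negative(bundle.reference) or _is_negative(bundle.insilico)):
        return OverallCall(ActivityCall.NEGATIVE, "moderate", "invitro_negative_supported")
    if _is_positive(bundle.insilico) and any_invitro_positive:
        conf = "high" if _is_positive(bundle.reference) else "moderate"
        return OverallCall(ActivityCall.POSITIVE, conf, "concordant_positive")
    if (_is_positive(bundle.insilico) and all_invitro_negative) or (
        _is_negative(bundle.insilico) and any_invitro_positive
    ):
        return OverallCall(ActivityCall.INCONCLUSIVE, "low", "opposing_evidence")
    return OverallCall(ActivityCall.INCONCLUSIVE, "low", "insufficient_evidence")


#: Fig-style colour legend: light red positive, pink weak positive, yellow
#: inconclusive, green negative; greys for no-call states.
CALL_COLOURS = {
    ActivityCall.POSITIVE: "#f08080",
    ActivityCall.WEAK_POSITIVE: "#ffc0cb",
    ActivityCall.INCONCLUSIVE: "#ffe066",
    ActivityCall.NEGATIVE: "#8fce8f",
    ActivityCall.OUT_OF_DOMAIN: "#c0c0c0",
    ActivityCall.NOT_EVALUATED: "#f0f0f0",
}


def _bundle_grid(bundles: list[EvidenceBundle]) -> pd.DataFrame:
    """Chemicals × evidence-line grid of calls, deterministically ordered."""
    rows: dict[str, dict[str, ActivityCall]] = {}
    for b in bundles:
        row = rows.setdefault(b.chemical_id, {})
        row[f"{b.target}:insilico"] = b.insilico
        row[f"{b.target}:reference"] = b.reference
        for assay_id, call, _ in b.invitro:
            row[f"{b.target}:{assay_id}"] = call
    grid = pd.DataFrame.from_dict(rows, orient="index")
    grid = grid.sort_index()
    grid = grid[sorted(grid.columns)]
    return grid.fillna(ActivityCall.NOT_EVALUATED)


def render_summary_heatmap(
    bundles: list[EvidenceBundle],
    image_path=None,
    table_path=None,
):
    """Render the call grid as a colour-coded heatmap plus a
    machine-readable table.

    Returns the grid as a DataFrame (chemicals × evidence lines, values are
    call tokens). Potencies (LECs) attached to the in vitro evidence are
    annotated on the cells as log10(molar) values, mirroring the reporting
    convention of summary figures. Layout is deterministic: chemicals and
    columns sorted lexicographically.
    """
    if not bundles:
        raise ValueError("no evidence bundles to render")
    grid = _bundle_grid(bundles)
    lecs: dict[tuple[str, str], float] = {}
    for b in bundles:
        for assay_id, _, pot in b.invitro:
            if pot is not None and pot.lec is not None:
                lecs[(b.chemical_id, f"{b.target}:{assay_id}")] = pot.lec

    if image_path is not None:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_rows, n_cols = grid.shape
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.55 * n_cols + 2), max(2.0, 0.45 * n_rows + 1.5))
        )
        for i, chem in enumerate(grid.index):
            for j, col in enumerate(grid.columns):
                call = grid.iat[i, j]
                ax.add_patch(
                    plt.Rectangle((j, n_rows - 1 - i), 1, 1,
                                  facecolor=CALL_COLOURS[call], edgecolor="white")
                )
                lec = lecs.get((chem, col))
                if lec is not None:
                    log_molar = np.log10(lec * 1e-6)
                    ax.text(j + 0.5, n_rows - 0.5 - i, f"{log_molar:.1f}",
                            ha="center", va="center", fontsize=6)
        ax.set_xlim(0, n_cols)
        ax.set_ylim(0, n_rows)
        ax.set_xticks(np.arange(n_cols) + 0.5)
        ax.set_xticklabels(grid.columns, rotation=90, fontsize=6)
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels(list(grid.index)[::-1], fontsize=7)
        ax.set_aspect("equal")
        fig.tight_layout()
        fig.savefig(image_path)
        plt.close(fig)

    table = grid.map(lambda c: c.value)
    if table_path is not None:
        table.to_csv(table_path, index_label="chemical_id")
    return table


def heatmap_table_to_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Parse a heatmap summary table back into an ActivityCall grid
    (round-trip inverse of :func:`render_summary_heatmap`)."""
    return table.map(ActivityCall)
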