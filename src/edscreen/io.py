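"""Delimited-file readers/writers, packaged fixtures and run configuration.

All tabular interchange uses UTF-8 delimited text (comma for ``.csv``, tab
for ``.tsv``) with a single header row and period decimal separators.
Concentrations are µM in files; log10(molar) appears only in rendered
reports. Malformed rows are reported with their line numbers; unknown call
tokens are hard errors naming the token.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .calls import ActivityCall, parse_call
from .consensus import (
    ModelPerformance,
    ModelPredictionMatrix,
    ModelSpec,
    ReferenceCallSet,
    round_half_up,
)
from .curves import ConcentrationResponse, MetabolicCondition
from .invitro import RuleThresholds

__all__ = [
    "StudyConfig",
    "read_call_matrix",
    "write_call_matrix",
    "read_curves",
    "write_curves",
    "read_reference_calls",
    "write_reference_calls",
    "write_performance",
    "read_performance",
    "load_table1_fixture",
    "load_invitro_summary_fixture",
    "run_log",
]

_PANEL_SIZES = {"ER": 8, "AR": 7, "aromatase": 9}


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.empty:
        raise ValueError(f"{path}: empty table")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _parse_call_cell(token, path, line: int) -> ActivityCall:
    try:
        return parse_call(str(token))
    except ValueError as exc:
        raise ValueError(f"{path}, line {line}: {exc}") from None


# ---------------------------------------------------------------- matrices

def read_call_matrix(path) -> ModelPredictionMatrix:
    """Read a long-format prediction table (chemical_id, model_id, target,
    endpoint_role, call[, in_training_set]) into a matrix."""
    df = _read_table(path, {"chemical_id", "model_id", "target", "endpoint_role", "call"})
    calls = [
        _parse_call_cell(tok, path, i + 2) for i, tok in enumerate(df["call"])
    ]
    df = df.assign(call=calls)
    models = []
    seen = {}
    for _, row in df.drop_duplicates("model_id").iterrows():
        spec = ModelSpec(row["model_id"], row["target"], row["endpoint_role"])
        models.append(spec)
        seen[spec.model_id] = spec
    mismatch = df[
        (df["target"] != df["model_id"].map(lambda m: seen[m].target))
        | (df["endpoint_role"] != df["model_id"].map(lambda m: seen[m].endpoint_role))
    ]
    if not mismatch.empty:
        raise ValueError(
            f"{path}: inconsistent target/endpoint_role for model(s) "
            f"{sorted(mismatch['model_id'].unique())}"
        )
    grid = df.pivot(index="chemical_id", columns="model_id", values="call")
    order = list(dict.fromkeys(df["chemical_id"]))
    grid = grid.loc[order]
    if grid.isna().any().any():
        raise ValueError(f"{path}: incomplete chemical × model grid")
    train = None
    if "in_training_set" in df.columns:
        train = df.pivot(index="chemical_id", columns="model_id",
                         values="in_training_set").loc[order].astype(bool)
    return ModelPredictionMatrix(models=models, calls=grid, in_training_set=train)


def write_call_matrix(matrix: ModelPredictionMatrix, path) -> None:
    rows = []
    for m in matrix.models:
        for chem in matrix.chemicals:
            rows.append(
                {
                    "chemical_id": chem,
                    "model_id": m.model_id,
                    "target": m.target,
                    "endpoint_role": m.endpoint_role,
                    "call": matrix.calls.at[chem, m.model_id].value,
                    "in_training_set": bool(matrix.in_training_set.at[chem, m.model_id]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------------ curves

def read_curves(path) -> list[ConcentrationResponse]:
    """Read a long-format curve table (chemical_id, assay_id,
    concentration_uM, replicate, response[, viability, metabolic_condition])."""
    df = _read_table(path, {"chemical_id", "assay_id", "concentration_uM",
                            "replicate", "response"})
    if "metabolic_condition" not in df.columns:
        df["metabolic_condition"] = MetabolicCondition.NONE.value
    curves = []
    for (chem, assay, cond), grp in df.groupby(
        ["chemical_id", "assay_id", "metabolic_condition"], sort=False
    ):
        concs = np.sort(grp["concentration_uM"].unique())
        responses = [
            grp.loc[grp["concentration_uM"] == c, "response"].to_numpy() for c in concs
        ]
        viability = None
        if "viability" in grp.columns and grp["viability"].notna().any():
            viability = np.array(
                [grp.loc[grp["concentration_uM"] == c, "viability"].mean() for c in concs]
            )
        curves.append(
            ConcentrationResponse(
                chemical_id=chem, assay_id=assay, concentrations=concs,
                responses=responses, viability=viability,
                metabolic_condition=MetabolicCondition(cond),
            )
        )
    return curves


def write_curves(curves: list[ConcentrationResponse], path) -> None:
    rows = []
    for curve in curves:
        for i, conc in enumerate(curve.concentrations):
            for rep, value in enumerate(curve.responses[i]):
                rows.append(
                    {
                        "chemical_id": curve.chemical_id,
                        "assay_id": curve.assay_id,
                        "concentration_uM": conc,
                        "replicate": rep,
                        "response": value,
                        "viability": (
                            curve.viability[i] if curve.viability is not None else np.nan
                        ),
                        "metabolic_condition": curve.metabolic_condition.value,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------- references

def read_reference_calls(path) -> ReferenceCallSet:
    df = _read_table(path, {"chemical_id", "target", "call"})
    df = df.assign(call=[_parse_call_cell(t, path, i + 2) for i, t in enumerate(df["call"])])
    calls = df.pivot(index="chemical_id", columns="target", values="call")
    order = list(dict.fromkeys(df["chemical_id"]))
    targets = list(dict.fromkeys(df["target"]))
    prov = None
    if "provenance" in df.columns:
        prov = df.pivot(index="chemical_id", columns="target",
                        values="provenance").loc[order, targets]
    return ReferenceCallSet(calls=calls.loc[order, targets], provenance=prov)


def write_reference_calls(reference: ReferenceCallSet, path) -> None:
    rows = []
    for chem in reference.chemicals:
        for target in reference.calls.columns:
            row = {"chemical_id": chem, "target": target,
                   "call": reference.call(chem, target).value}
            if reference.provenance is not None:
                row["provenance"] = reference.provenance.at[chem, target]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------------ performance

def write_performance(table: list[ModelPerformance], path) -> None:
    pd.DataFrame([dataclass_row(p) for p in table]).to_csv(path, sep=_sep(path), index=False)


def dataclass_row(p: ModelPerformance) -> dict:
    return {
        "model_id": p.model_id,
        "target": p.target,
        "pct_correct": "" if p.pct_correct is None else p.pct_correct,
        "pct_efficiency": p.pct_efficiency,
        "n_included": p.n_included,
        "n_distinct": p.n_distinct,
        "n_correct": p.n_correct,
    }


def read_performance(path) -> list[ModelPerformance]:
    df = _read_table(path, {"model_id", "target", "pct_correct", "pct_efficiency",
                            "n_included", "n_distinct", "n_correct"})
    out = []
    for _, row in df.iterrows():
        pct = row["pct_correct"]
        out.append(
            ModelPerformance(
                model_id=row["model_id"], target=row["target"],
                pct_correct=None if pd.isna(pct) or pct == "" else int(pct),
                pct_efficiency=int(row["pct_efficiency"]),
                n_included=int(row["n_included"]),
                n_distinct=int(row["n_distinct"]),
                n_correct=int(row["n_correct"]),
            )
        )
    return out


# --------------------------------------------------------------- fixtures

def _invert_pct(pct: int, n: int, what: str) -> int:
    """Recover the unique count k with round_half_up(100 k / n) == pct."""
    hits = [k for k in range(n + 1) if round_half_up(100.0 * k / n) == pct]
    if len(hits) != 1:
        raise ValueError(f"cannot invert {what} {pct}% on denominator {n}: {hits}")
    return hits[0]


def load_table1_fixture() -> list[ModelPerformance]:
    """Load the packaged model-evaluation table (printed integer percents)
    as ModelPerformance rows.

    The printed efficiencies and correct-call rates are percentages of the
    included panels (8 ER, 7 AR, 9 aromatase chemicals); the underlying
    integer counts are recovered exactly by inverting the half-up rounding,
    which is unambiguous at these panel sizes.
    """
    with resources.as_file(resources.files("edscreen.data") / "table1_performance.csv") as p:
        df = pd.read_csv(p)
    out = []
    for _, row in df.iterrows():
        n_included = _PANEL_SIZES[row["target"]]
        n_distinct = _invert_pct(int(row["pct_efficiency"]), n_included, "efficiency")
        if n_distinct == 0:
            pct_correct, n_correct = None, 0
        else:
            pct_correct = int(row["pct_correct"])
            n_correct = _invert_pct(pct_correct, n_distinct, "correct")
        out.append(
            ModelPerformance(
                model_id=row["model_id"], target=row["target"],
                pct_correct=pct_correct,
                pct_efficiency=int(row["pct_efficiency"]),
                n_included=n_included, n_distinct=n_distinct, n_correct=n_correct,
            )
        )
    return out


def load_invitro_summary_fixture() -> pd.DataFrame:
    """Packaged per-chemical in vitro summary: calls and potencies for the
    thirteen assay endpoints of the ten-chemical panel. Rows whose ``note``
    starts with ``discrepancy`` record values that conflict between
    sources and are excluded from assertions."""
    with resources.as_file(resources.files("edscreen.data") / "invitro_summary.csv") as p:
        df = pd.read_csv(p)
    df["call"] = df["call"].map(parse_call)
    return df


# ------------------------------------------------------------------ config

class StudyConfig(BaseModel):
    """Validated run configuration shared by all CLI stages."""

    thresholds: dict = Field(default_factory=dict)
    oad_policy: str = "exclude"
    denominator: str = "included"
    seed: int = 0
    simulation: dict = Field(default_factory=dict)

    def rule_thresholds(self) -> RuleThresholds:
        kw = dict(self.thresholds)
        if "followup_band_pct" in kw:
            kw["followup_band_pct"] = tuple(kw["followup_band_pct"])
        return RuleThresholds(**kw)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_log(config: StudyConfig | None, inputs: list, log_path=None) -> dict:
    """Structured run log: tool version, config hash, seed, input digests."""
    digests = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    record = {
        "tool": "edscreen",
        "version": __version__,
        "config_hash": config.config_hash() if config else None,
        "seed": config.seed if config else None,
        "inputs": digests,
    }
    if log_path is not None:
        Path(log_path).write_text(json.dumps(record, indent=2) + "\n")
    return record
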