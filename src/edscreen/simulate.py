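"""Synthetic study generation with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_prediction_matrix` draws an in silico call grid from a
  ground-truth call vector under per-model error profiles (sensitivity,
  specificity, inconclusive rate, out-of-domain rate), emulating the
  behaviour spread of a panel of QSAR/docking models.
* :func:`generate_dose_response` samples replicate responses from a 4PL
  mean curve with Gaussian noise, an optional solubility plateau (the mean
  response freezes at the level reached at the solubility cap) and an
  optional cytotoxicity onset driving a declining viability channel.

All randomness flows through an explicit integer seed; identical
(config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd

from .calls import ActivityCall, call_sign
from .consensus import ModelPredictionMatrix, ModelSpec, ReferenceCallSet
from .curves import ConcentrationResponse, MetabolicCondition, four_param_logistic

__all__ = [
    "ModelProfile",
    "CurveSpec",
    "StudyBundle",
    "generate_prediction_matrix",
    "generate_dose_response",
    "generate_truth",
    "generate_study",
    "default_profiles",
    "DEFAULT_STUDY_CONFIG",
]


@dataclasses.dataclass(frozen=True)
class ModelProfile:
    """Error profile of one simulated in silico model.

    ``sensitivity`` is the probability a true positive is called positive
    (given the model returns a distinct call); ``specificity`` likewise for
    true negatives. ``inconclusive_rate`` and ``oad_rate`` govern the
    non-distinct outcomes.
    """

    model_id: str
    target: str
    endpoint_role: str
    sensitivity: float = 0.8
    specificity: float = 0.8
    inconclusive_rate: float = 0.0
    oad_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.sensitivity, self.specificity, self.inconclusive_rate, self.oad_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("profile probabilities must lie in [0, 1]")
        if self.inconclusive_rate + self.oad_rate > 1.0:
            raise ValueError("inconclusive_rate + oad_rate must not exceed 1")

    def spec(self) -> ModelSpec:
        return ModelSpec(self.model_id, self.target, self.endpoint_role)


@dataclasses.dataclass(frozen=True)
class CurveSpec:
    """Generative parameters for one synthetic concentration–response curve.

    ``replicates`` defaults to 4, emulating duplicates measured in two
    independent experiments. ``solubility_cap_uM`` freezes the mean
    response above the cap at the level reached at the cap;
    ``cytotox_onset_uM`` is the concentration of half-maximal viability
    loss in the accompanying viability channel.
    """

    bottom: float = 0.0
    top: float = 100.0
    midpoint: float = 1.0
    hill_slope: float = 1.0
    noise_sd: float = 0.0
    solubility_cap_uM: float | None = None
    cytotox_onset_uM: float | None = None
    concentrations: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError("midpoint must be positive")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates (duplicate measurements)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def mean_response(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        mean = four_param_logistic(
            conc, self.bottom, self.top, np.log10(self.midpoint), self.hill_slope
        )
        if self.solubility_cap_uM is not None:
            cap_level = four_param_logistic(
                np.array([self.solubility_cap_uM]),
                self.bottom, self.top, np.log10(self.midpoint), self.hill_slope,
            )[0]
            mean = np.where(conc > self.solubility_cap_uM, cap_level, mean)
        return mean


def generate_dose_response(
    spec: CurveSpec,
    seed: int,
    chemical_id: str = "synthetic",
    assay_id: str = "er_binding",
    metabolic_condition: MetabolicCondition = MetabolicCondition.NONE,
) -> ConcentrationResponse:
    """Sample one replicate curve table from a :class:`CurveSpec`."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    mean = spec.mean_response(conc)
    responses = [
        mean[i] + rng.normal(0.0, spec.noise_sd, size=spec.replicates)
        if spec.noise_sd > 0
        else np.full(spec.replicates, mean[i])
        for i in range(conc.size)
    ]
    viability = None
    if spec.cytotox_onset_uM is not None:
        viability = 100.0 / (1.0 + (conc / spec.cytotox_onset_uM) ** 4)
    return ConcentrationResponse(
        chemical_id=chemical_id,
        assay_id=assay_id,
        concentrations=conc,
        responses=responses,
        viability=viability,
        metabolic_condition=metabolic_condition,
    )


def generate_truth(
    n_chemicals: int,
    targets: tuple[str, ...] = ("ER", "AR", "aromatase"),
    positive_fraction: float = 0.5,
    inconclusive_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[ReferenceCallSet, pd.DataFrame]:
    """Draw a ground-truth call panel plus the hidden signs.

    Returns the truth as a :class:`ReferenceCallSet` and a parallel
    DataFrame of hidden true signs (+1/-1). Inconclusive truth calls keep a
    hidden coin-flip sign so exclusion logic can be exercised both ways.
    """
    rng = np.random.default_rng(seed)
    chems = [f"chem{i:05d}" for i in range(n_chemicals)]
    calls = {}
    signs = {}
    for t in targets:
        sign = rng.choice([1, -1], size=n_chemicals,
                          p=[positive_fraction, 1 - positive_fraction])
        inconc = rng.random(n_chemicals) < inconclusive_fraction
        calls[t] = [
            ActivityCall.INCONCLUSIVE if m
            else (ActivityCall.POSITIVE if s > 0 else ActivityCall.NEGATIVE)
            for s, m in zip(sign, inconc)
        ]
        signs[t] = sign
    truth = ReferenceCallSet(calls=pd.DataFrame(calls, index=chems))
    return truth, pd.DataFrame(signs, index=chems)


def generate_prediction_matrix(
    truth: ReferenceCallSet,
    profiles: list[ModelProfile],
    seed: int,
    hidden_signs: pd.DataFrame | None = None,
) -> ModelPredictionMatrix:
    """Draw an in silico call grid from ground truth under model profiles.

    Per cell, in order: out-of-domain with probability ``oad_rate``;
    otherwise inconclusive with probability ``inconclusive_rate``;
    otherwise the true sign is reproduced with probability ``sensitivity``
    (true positives) or ``specificity`` (true negatives) and flipped
    otherwise. Chemicals whose truth call is inconclusive are simulated
    from their hidden sign (coin flip if none supplied).
    """
    if not profiles:
        raise ValueError("at least one model profile required")
    rng = np.random.default_rng(seed)
    chems = truth.chemicals
    grid = {}
    for prof in profiles:
        col = []
        for chem in chems:
            true_call = truth.call(chem, prof.target)
            sign = call_sign(true_call)
            if sign is None:
                if hidden_signs is not None:
                    sign = int(hidden_signs.at[chem, prof.target])
                else:
                    sign = int(rng.choice([1, -1]))
            if rng.random() < prof.oad_rate:
                col.append(ActivityCall.OUT_OF_DOMAIN)
                continue
            if rng.random() < prof.inconclusive_rate:
                col.append(ActivityCall.INCONCLUSIVE)
                continue
            p_keep = prof.sensitivity if sign > 0 else prof.specificity
            out = sign if rng.random() < p_keep else -sign
            col.append(ActivityCall.POSITIVE if out > 0 else ActivityCall.NEGATIVE)
        grid[prof.model_id] = col
    calls = pd.DataFrame(grid, index=chems)
    return ModelPredictionMatrix(models=[p.spec() for p in profiles], calls=calls)


def default_profiles() -> list[ModelProfile]:
    """A model panel emulating the study layout: 18 ER, 17 AR and 4
    aromatase models with a realistic spread of accuracies (around 80%
    correct on distinct calls) and occasional inconclusive / out-of-domain
    behaviour."""
    profiles: list[ModelProfile] = []
    roles = ("binding", "activation", "antagonist")
    for i in range(18):
        profiles.append(ModelProfile(
            model_id=f"er_model_{i:02d}", target="ER", endpoint_role=roles[i % 3],
            sensitivity=0.75 + 0.02 * (i % 10), specificity=0.75 + 0.02 * ((i + 3) % 10),
            inconclusive_rate=0.05 if i % 4 else 0.15,
            oad_rate=0.05 if i % 6 == 0 else 0.0,
        ))
    for i in range(17):
        profiles.append(ModelProfile(
            model_id=f"ar_model_{i:02d}", target="AR", endpoint_role=roles[i % 3],
            sensitivity=0.75 + 0.02 * ((i + 5) % 10), specificity=0.75 + 0.02 * (i % 10),
            inconclusive_rate=0.1 if i % 3 else 0.2,
            oad_rate=0.05 if i % 5 == 0 else 0.0,
        ))
    for i in range(4):
        profiles.append(ModelProfile(
            model_id=f"aromatase_model_{i}", target="aromatase", endpoint_role="inhibition",
            sensitivity=0.8, specificity=0.85 - 0.1 * (i == 3),
            inconclusive_rate=0.0, oad_rate=0.05 if i == 1 else 0.0,
        ))
    return profiles


DEFAULT_STUDY_CONFIG: dict = {
    "n_chemicals": 10,
    "targets": ["ER", "AR", "aromatase"],
    "positive_fraction": 0.5,
    "inconclusive_fraction": 0.1,
    "curve": {
        "bottom": 0.0,
        "top": 100.0,
        "midpoint": 1.0,
        "hill_slope": 1.0,
        "noise_sd": 5.0,
        "replicates": 4,
    },
}


@dataclasses.dataclass
class StudyBundle:
    """End-to-end synthetic dataset: truth, prediction matrix, curves and a
    manifest recording the seed and config hash."""

    truth: ReferenceCallSet
    hidden_signs: pd.DataFrame
    matrix: ModelPredictionMatrix
    curves: list[ConcentrationResponse]
    manifest: dict


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def generate_study(config: dict | None = None, seed: int = 0,
                   profiles: list[ModelProfile] | None = None) -> StudyBundle:
    """Generate a complete synthetic study exercising every pipeline stage.

    The default configuration mirrors the study layout: a ten-chemical
    panel over the three targets, the default model panel, and one
    positive-style binding curve per truth-positive chemical (midpoint
    jittered around the configured value, negatives flat).
    """
    config = {**DEFAULT_STUDY_CONFIG, **(config or {})}
    if profiles is None:
        profiles = default_profiles()
    seed = int(seed)
    truth, signs = generate_truth(
        config["n_chemicals"], tuple(config["targets"]),
        config["positive_fraction"], config["inconclusive_fraction"],
        seed=seed,
    )
    matrix = generate_prediction_matrix(truth, profiles, seed=seed + 1,
                                        hidden_signs=signs)
    rng = np.random.default_rng(seed + 2)
    curve_cfg = config["curve"]
    curves = []
    for i, chem in enumerate(truth.chemicals):
        positive = signs.at[chem, config["targets"][0]] > 0
        spec = CurveSpec(
            bottom=curve_cfg["bottom"],
            top=curve_cfg["top"] if positive else curve_cfg["bottom"],
            midpoint=float(curve_cfg["midpoint"] * 10 ** rng.uniform(-0.5, 0.5)),
            hill_slope=curve_cfg["hill_slope"],
            noise_sd=curve_cfg["noise_sd"],
            replicates=curve_cfg["replicates"],
        )
        curves.append(
            generate_dose_response(spec, seed=seed + 100 + i, chemical_id=chem,
                                   assay_id="er_binding")
        )
    manifest = {"seed": seed, "config_hash": _config_hash(config),
                "n_chemicals": config["n_chemicals"], "n_models": len(profiles)}
    return StudyBundle(truth=truth, hidden_signs=signs, matrix=matrix,
                       curves=curves, manifest=manifest)
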