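import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from edscreen.calls import ActivityCall
from edscreen.consensus import ModelPredictionMatrix, ModelSpec, ReferenceCallSet
from edscreen.curves import ConcentrationResponse


@pytest.fixture
def logistic_curve():
    """Noise-free 4PL samples: bottom 0, top 100, midpoint 1 µM, slope 1."""
    conc = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])
    mean = 100.0 / (1.0 + 1.0 / conc)
    return ConcentrationResponse(
        chemical_id="chemA",
        assay_id="er_binding",
        concentrations=conc,
        responses=[np.array([m, m]) for m in mean],
    )


def make_matrix(calls_by_model, roles=None, targets=None):
    """Build a small prediction matrix from {model_id: [calls...]}."""
    model_ids = list(calls_by_model)
    n = len(next(iter(calls_by_model.values())))
    chems = [f"c{i}" for i in range(n)]
    models = [
        ModelSpec(
            mid,
            (targets or {}).get(mid, "ER"),
            (roles or {}).get(mid, "binding"),
        )
        for mid in model_ids
    ]
    calls = pd.DataFrame(calls_by_model, index=chems)
    return ModelPredictionMatrix(models=models, calls=calls)


def make_reference(calls, target="ER"):
    """Reference set over chemicals c0..cN for one target (others negative)."""
    chems = [f"c{i}" for i in range(len(calls))]
    cols = {t: [ActivityCall.NEGATIVE] * len(calls) for t in ("ER", "AR", "aromatase")}
    cols[target] = list(calls)
    return ReferenceCallSet(calls=pd.DataFrame(cols, index=chems))


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def reference_factory():
    return make_reference
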