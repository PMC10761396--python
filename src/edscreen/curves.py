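"""Concentration–response containers, four-parameter logistic fitting and
potency derivation (relative IC50, Cheng–Prusoff Ki, LEC).

The curve model used throughout is the four-parameter logistic (4PL, the
Hill model) in log concentration::

    y(c) = bottom + (top - bottom) / (1 + (midpoint / c) ** hill_slope)

``midpoint`` is the concentration at half of the compound's *own* maximal
effect, which is exactly the "relative IC50" convention used for follow-up
binding assays: a compound whose inhibition plateaus at 69% (for example
because of limited solubility) has its IC50 read at 34.5% inhibition, not at
50% of the positive control. ``top`` is therefore free to converge below
100%; fits are never forced through the full response range.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MetabolicCondition",
    "ConcentrationResponse",
    "FitResult",
    "FourParamLogistic",
    "fit_concentration_response",
    "derive_relative_ic50",
    "cheng_prusoff_ki",
    "derive_lec",
    "four_param_logistic",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when a curve has too few concentrations to support a fit."""


class MetabolicCondition(str, enum.Enum):
    """Metabolic supplementation of an assay incubation.

    ``S9_PHASE1`` adds liver S9 with the Phase 1 cofactor (NADPH);
    ``S9_PHASE1_2`` additionally supplies Phase 2 cofactors (UDPGA, PAPS,
    glutathione).
    """

    NONE = "none"
    S9_PHASE1 = "s9_phase1"
    S9_PHASE1_2 = "s9_phase1_2"


#: Assay identifiers accepted on a ConcentrationResponse.
ASSAY_IDS = frozenset(
    {
        "yes_agonist",
        "yes_antagonist",
        "yas_agonist",
        "yas_antagonist",
        "er_binding",
        "ar_binding",
        "aromatase",
        "calux_er_ag",
        "calux_er_ant",
        "calux_ar_ag",
        "calux_ar_ant",
        "h295r_estrogen",
        "h295r_androgen",
    }
)


@dataclasses.dataclass
class ConcentrationResponse:
    """Replicate responses of one assay over a concentration series.

    Parameters
    ----------
    chemical_id, assay_id:
        Identifiers. ``assay_id`` must be one of :data:`ASSAY_IDS`.
    concentrations:
        Strictly increasing, strictly positive, in µM.
    responses:
        One sequence of replicate values per concentration. Units depend on
        the assay family: % inhibition of control for binding/aromatase,
        % of the assay reference maximum for reporter assays, fold of
        control for steroidogenesis.
    viability:
        Optional per-concentration viability / growth, % of control,
        aligned with ``concentrations``.
    metabolic_condition:
        Metabolic supplementation of the incubation.
    """

    chemical_id: str
    assay_id: str
    concentrations: np.ndarray
    responses: list[np.ndarray]
    viability: np.ndarray | None = None
    metabolic_condition: MetabolicCondition = MetabolicCondition.NONE

    def __post_init__(self) -> None:
        if self.assay_id not in ASSAY_IDS:
            raise ValueError(f"unknown assay_id {self.assay_id!r}")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1 or self.concentrations.size == 0:
            raise ValueError("concentrations must be a non-empty 1-D series")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        self.responses = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.responses]
        if len(self.responses) != self.concentrations.size:
            raise ValueError("one replicate set required per concentration")
        if any(r.size == 0 for r in self.responses):
            raise ValueError("at least one replicate per concentration")
        if self.metabolic_condition is not None:
            self.metabolic_condition = MetabolicCondition(self.metabolic_condition)
        if self.viability is not None:
            self.viability = np.asarray(self.viability, dtype=float)
            if self.viability.shape != self.concentrations.shape:
                raise ValueError("viability must align with concentrations")

    def mean_responses(self) -> np.ndarray:
        """Per-concentration mean over replicates (used for calling)."""
        return np.array([r.mean() for r in self.responses])

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, response) replicate points (used for fitting)."""
        conc = np.concatenate(
            [np.full(r.size, c) for c, r in zip(self.concentrations, self.responses)]
        )
        resp = np.concatenate(self.responses)
        return conc, resp


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Fitted 4PL parameters plus the observed maximal effect.

    ``midpoint`` is None for flat curves (no concentration dependence).
    ``max_observed_effect`` is the largest per-concentration replicate mean,
    reported so that a plateaued maximum (e.g. 69% rather than 100%) is
    visible alongside the asymptotic ``top``.
    """

    bottom: float
    top: float
    midpoint: float | None
    hill_slope: float | None
    max_observed_effect: float
    converged: bool
    flat: bool = False

    def __post_init__(self) -> None:
        if self.midpoint is not None and self.midpoint <= 0:
            raise ValueError("midpoint must be positive")
        if self.converged and not self.flat and self.bottom > self.top:
            raise ValueError("bottom must not exceed top")


def four_param_logistic(
    conc: np.ndarray, bottom: float, top: float, log10_midpoint: float, hill_slope: float
) -> np.ndarray:
    """4PL response at the given concentrations (µM); midpoint in log10 µM."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill_slope * (log10_midpoint - np.log10(conc)))
    )


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic regression of response on concentration.

    A scikit-learn style estimator: ``fit(X, y)`` takes concentrations (µM,
    1-D or column vector) and replicate responses; fitted attributes carry a
    trailing underscore. The midpoint is optimised in log10 concentration.

    Parameters
    ----------
    slope_sign : {0, 1, -1}
        Constrain the Hill slope to be positive (rising) or negative
        (falling); 0 leaves it free.
    flat_tolerance : float
        Response range (in response units) at or below which the curve is
        declared flat; flat curves get ``midpoint_ = None``.

    Attributes
    ----------
    bottom_, top_ : float
        Lower/upper asymptotes in response units.
    midpoint_ : float or None
        Concentration of half-maximal (own-maximum) response, µM.
    hill_slope_ : float or None
    converged_ : bool
    flat_ : bool
    max_observed_effect_ : float
        Largest per-concentration replicate mean.
    """

    def __init__(self, slope_sign: int = 0, flat_tolerance: float = 1e-9, maxfev: int = 20000):
        self.slope_sign = slope_sign
        self.flat_tolerance = flat_tolerance
        self.maxfev = maxfev

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        resp = np.asarray(y, dtype=float).ravel()
        if conc.shape != resp.shape:
            raise ValueError("X and y must have the same number of points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        distinct = np.unique(conc)
        if distinct.size < 4:
            raise DegenerateInputError(
                f"need >=4 distinct concentrations, got {distinct.size}"
            )
        # per-concentration means, for initialisation and the flat check
        means = np.array([resp[conc == c].mean() for c in distinct])
        self.max_observed_effect_ = float(means.max())
        span = float(means.max() - means.min())
        if span <= self.flat_tolerance:
            self.bottom_ = self.top_ = float(means.mean())
            self.midpoint_ = None
            self.hill_slope_ = None
            self.flat_ = True
            self.converged_ = True
            return self

        rising = means[-1] >= means[0] if self.slope_sign == 0 else self.slope_sign > 0
        b0 = float(means.min()) if rising else float(means.max())
        t0 = float(means.max()) if rising else float(means.min())
        # initial midpoint: concentration whose mean is nearest half-range
        half = 0.5 * (b0 + t0)
        c50 = distinct[int(np.argmin(np.abs(means - half)))]
        p0 = [b0, t0, float(np.log10(c50)), 1.0 if rising else -1.0]
        lo = [-np.inf, -np.inf, -np.inf, 0.0 if rising else -np.inf]
        hi = [np.inf, np.inf, np.inf, np.inf if rising else 0.0]
        try:
            popt, _ = curve_fit(
                four_param_logistic, conc, resp, p0=p0,
                bounds=(lo, hi), maxfev=self.maxfev,
            )
            self.converged_ = True
        except RuntimeError:
            popt = p0
            self.converged_ = False
        bottom, top, logmid, slope = (float(v) for v in popt)
        if bottom > top:  # canonicalise: bottom <= top, slope sign flips
            bottom, top, slope = top, bottom, -slope
        self.bottom_ = bottom
        self.top_ = top
        self.midpoint_ = float(10.0 ** logmid)
        self.hill_slope_ = slope
        self.flat_ = False
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).ravel()
        if self.flat_:
            return np.full(conc.shape, self.bottom_)
        return four_param_logistic(
            conc, self.bottom_, self.top_, np.log10(self.midpoint_), self.hill_slope_
        )

    def result_(self) -> FitResult:
        """Bundle the fitted attributes as a :class:`FitResult`."""
        return FitResult(
            bottom=self.bottom_,
            top=self.top_,
            midpoint=self.midpoint_,
            hill_slope=self.hill_slope_,
            max_observed_effect=self.max_observed_effect_,
            converged=self.converged_,
            flat=self.flat_,
        )


def fit_concentration_response(curve: ConcentrationResponse, **kwargs) -> FitResult:
    """Least-squares 4PL fit over all replicate points of one curve.

    Raises :class:`DegenerateInputError` for fewer than 4 distinct
    concentrations. A curve with no response range is returned with the
    ``flat`` flag set and no midpoint. Non-convergence is reported through
    ``converged=False``, never silently defaulted.
    """
    conc, resp = curve.flatten()
    return FourParamLogistic(**kwargs).fit(conc, resp).result_()


def derive_relative_ic50(fit: FitResult) -> float | None:
    """Concentration at half of the compound's own maximal effect, µM.

    For the 4PL this is exactly the fitted midpoint: the response there is
    ``bottom + 0.5 * (top - bottom)`` for any Hill slope. The convention is
    relative — half of the compound's own plateau, not half of the positive
    control's — so a fit with top = 69% still has its IC50 at the midpoint.
    Returns None for flat or unconverged fits.
    """
    if fit.flat or not fit.converged or fit.midpoint is None:
        return None
    if fit.top <= fit.bottom:
        return None
    return fit.midpoint


def cheng_prusoff_ki(ic50: float, ligand_conc: float, ligand_kd: float) -> float:
    """Competitive-binding inhibition constant Ki = IC50 / (1 + L/Kd).

    ``ligand_conc`` (L) is the radioligand concentration used in the
    displacement assay and ``ligand_kd`` its equilibrium dissociation
    constant, both in µM. Ki <= IC50 always, with equality iff L = 0.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if ligand_conc < 0:
        raise ValueError("ligand_conc must be non-negative")
    if ligand_kd <= 0:
        raise ValueError("ligand_kd must be positive")
    return ic50 / (1.0 + ligand_conc / ligand_kd)


def derive_lec(
    curve: ConcentrationResponse | None = None,
    threshold_fraction: float = 0.10,
    *,
    concentrations: Sequence[float] | None = None,
    mean_responses: Sequence[float] | None = None,
) -> float | None:
    """Lowest Effective Concentration: lowest *tested* concentration whose
    mean response meets or exceeds ``threshold_fraction`` of the assay
    reference maximum (responses expressed as % of reference maximum, so
    the default 0.10 means the PC10-style 10% threshold).

    No interpolation between tested concentrations is performed; the LEC is
    always an element of the tested series, or None if the threshold is
    never reached.
    """
    if curve is not None:
        concentrations = curve.concentrations
        mean_responses = curve.mean_responses()
    conc = np.asarray(concentrations, dtype=float)
    means = np.asarray(mean_responses, dtype=float)
    threshold = 100.0 * threshold_fraction
    hits = np.nonzero(means >= threshold)[0]
    if hits.size == 0:
        return None
    return float(conc[hits[0]])
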