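"""Decomposition of soil potential acidity into its Al3+ and H+ components.

Potential acidity (PA, cmol(+)/kg) is titrated in BaCl2-triethanolamine
buffered at pH 8.2, so the number of titratable sites in a soil at suspension
pH is proportional to (8.2 - pH).  The Al and H components of PA are modelled
as non-negative, intercept-free linear combinations of (8.2 - pH)-scaled soil
constituents: pore-accessible fulvic acid, sand, humin for Al(PA); silt+clay,
Tamm-extractable Al and Fe, and accessible fulvic acid for H(PA).

Reference coefficient sets fitted on an 18-sample Arenosol/Luvisol/Chernozem
soil collection are shipped as module constants; `fit_acidity_model` re-fits
the same model structure on any soil table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regression import PenalizedFit, fit_penalized

__all__ = [
    "SoilAcidity",
    "AcidityCoefficients",
    "acidity_design_term",
    "predict_al_pa",
    "predict_h_pa",
    "fit_acidity_model",
    "AL_PA_LASSO_FA25L",
    "AL_PA_LASSO_FA35C",
    "H_PA_LASSO_FA25L",
    "H_PA_LASSO_FA35C",
    "AL_PA_RIDGE_WITH_HA",
]

REFERENCE_PH = 8.2  # pH of the BaCl2-TEA extraction buffer


@dataclass
class SoilAcidity:
    """Exchangeable (EA) and potential (PA) acidity and their components, cmol(+)/kg."""

    ea: float = 0.0
    al_ea: float = 0.0
    h_ea: float = 0.0
    pa: float = 0.0
    al_pa: float = 0.0
    h_pa: float = 0.0

    def __post_init__(self) -> None:
        tol = 1e-6
        for f in ("ea", "al_ea", "h_ea", "pa", "al_pa", "h_pa"):
            if getattr(self, f) < -tol:
                raise ValueError(f"{f} must be non-negative")
        if self.al_pa + self.h_pa > self.pa + max(tol, 1e-6 * self.pa) + tol:
            raise ValueError("Al(PA) + H(PA) exceeds PA")
        if self.al_ea + self.h_ea > self.ea + max(tol, 1e-6 * self.ea) + tol:
            raise ValueError("Al(EA) + H(EA) exceeds EA")


@dataclass
class AcidityCoefficients:
    """Coefficients of one potential-acidity component model.

    ``terms`` maps predictor column names to (coefficient, standardized
    coefficient); all coefficients are non-negative.  The model is
    target = (8.2 - pH) * sum_j coef_j * predictor_j.
    """

    terms: list[tuple[str, float, float]]
    penalty: str = "lasso"
    lambda_optimal: float | None = None
    r2_adj: float | None = None

    def __post_init__(self) -> None:
        for name, coef, _std in self.terms:
            if coef < 0:
                raise ValueError(f"coefficient for {name!r} is negative")
        if self.r2_adj is not None and self.r2_adj > 1:
            raise ValueError("adjusted R2 cannot exceed 1")

    @property
    def predictors(self) -> list[str]:
        return [name for name, _, _ in self.terms]


# Reference models for the Al component of potential acidity (coefficient,
# standardized coefficient); predictors are multiplied by (8.2 - pH).
AL_PA_LASSO_FA25L = AcidityCoefficients(
    terms=[("fa_gt2.5L", 0.1954, 0.54), ("sand", 0.0008, 0.48), ("hu", 0.0033, 0.13)],
    penalty="lasso",
    lambda_optimal=0.0031,
    r2_adj=0.930,
)
AL_PA_LASSO_FA35C = AcidityCoefficients(
    terms=[("fa_gt3.5C", 0.1266, 0.51), ("sand", 0.0008, 0.50), ("hu", 0.0039, 0.16)],
    penalty="lasso",
    lambda_optimal=0.0029,
    r2_adj=0.926,
)
# Ridge variant retaining humic acid as a (weak) predictor.
AL_PA_RIDGE_WITH_HA = AcidityCoefficients(
    terms=[
        ("sand", 0.0008, 0.48),
        ("fa_gt2.5L", 0.1473, 0.40),
        ("ha", 0.0061, 0.06),
        ("hu", 0.0045, 0.18),
    ],
    penalty="ridge",
    lambda_optimal=0.052,
    r2_adj=0.915,
)
# Reference models for the H component of potential acidity.
H_PA_LASSO_FA25L = AcidityCoefficients(
    terms=[
        ("silt_plus_clay", 0.016, 0.33),
        ("al_t", 1.481, 0.45),
        ("fe_t", 0.050, 0.12),
        ("fa_gt2.5L", 0.856, 0.19),
    ],
    penalty="lasso",
    lambda_optimal=0.074,
    r2_adj=0.980,
)
H_PA_LASSO_FA35C = AcidityCoefficients(
    terms=[
        ("silt_plus_clay", 0.017, 0.34),
        ("al_t", 1.379, 0.42),
        ("fe_t", 0.064, 0.16),
        ("fa_gt3.5C", 0.643, 0.21),
    ],
    penalty="lasso",
    lambda_optimal=0.024,
    r2_adj=0.980,
)


def acidity_design_term(soil_value, ph):
    """(8.2 - pH)-scaled predictor: the count of sites titratable up to pH 8.2.

    Warns (does not fail) above pH 8.2, where the extrapolated site count
    would turn negative.
    """
    ph_arr = np.asarray(ph, dtype=float)
    if np.any(ph_arr > REFERENCE_PH):
        warnings.warn(
            f"pH above the {REFERENCE_PH} extraction reference; "
            "(8.2 - pH) site term is negative",
            stacklevel=2,
        )
    out = (REFERENCE_PH - ph_arr) * np.asarray(soil_value, dtype=float)
    return float(out) if np.isscalar(soil_value) and np.isscalar(ph) else out


def _resolve_predictor(soil: Mapping[str, float] | pd.Series, name: str) -> float:
    if name == "silt_plus_clay":
        if "silt_plus_clay" in soil:
            return float(soil["silt_plus_clay"])
        try:
            return float(soil["silt"]) + float(soil["clay"])
        except KeyError as exc:
            raise KeyError(
                "missing predictor 'silt_plus_clay' (or 'silt'/'clay')"
            ) from exc
    try:
        return float(soil[name])
    except KeyError as exc:
        raise KeyError(f"missing predictor {name!r}") from exc


def _predict(soil: Mapping[str, float] | pd.Series, coeffs: AcidityCoefficients) -> float:
    ph = float(soil["ph"])
    total = sum(coef * _resolve_predictor(soil, name) for name, coef, _ in coeffs.terms)
    return acidity_design_term(total, ph)


def predict_al_pa(
    soil: Mapping[str, float] | pd.Series,
    coeffs: AcidityCoefficients = AL_PA_LASSO_FA25L,
) -> float:
    """Predicted Al component of potential acidity, cmol(+)/kg."""
    return _predict(soil, coeffs)


def predict_h_pa(
    soil: Mapping[str, float] | pd.Series,
    coeffs: AcidityCoefficients = H_PA_LASSO_FA25L,
) -> float:
    """Predicted H component of potential acidity, cmol(+)/kg."""
    return _predict(soil, coeffs)


def fit_acidity_model(
    soils: pd.DataFrame,
    target: str,
    predictors: Sequence[str],
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
) -> tuple[AcidityCoefficients, PenalizedFit]:
    """Fit an acidity-component model on a soil table.

    ``target`` is "al_pa" or "h_pa"; ``predictors`` are soil-table column
    names (``silt_plus_clay`` is derived from silt + clay if absent).  Each
    predictor is transformed to its (8.2 - pH)-scaled form before the
    non-negative, intercept-free penalized fit.
    """
    if target not in ("al_pa", "h_pa"):
        raise ValueError(f"target must be 'al_pa' or 'h_pa', got {target!r}")
    if len(soils) < 8:
        raise ValueError(f"need at least 8 samples, got {len(soils)}")
    ph = soils["ph"].to_numpy(dtype=float)
    cols = []
    for name in predictors:
        vals = np.array([_resolve_predictor(row, name) for _, row in soils.iterrows()])
        cols.append(acidity_design_term(vals, ph))
    X = np.column_stack(cols)
    y = soils[target].to_numpy(dtype=float)
    fit = fit_penalized(
        X, y, names=list(predictors), penalty=penalty, cv=cv, seed=seed, lambdas=lambdas
    )
    coeffs = AcidityCoefficients(
        terms=[
            (name, float(c), float(s))
            for name, c, s in zip(fit.names, fit.coefficients, fit.std_coefficients)
        ],
        penalty=penalty,
        lambda_optimal=fit.lambda_optimal,
        r2_adj=fit.r2_adj,
    )
    return coeffs, fit
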