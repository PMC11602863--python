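"""Single-sorbent adsorption-edge models (Kd vs. pH for one sorbent).

Isolated humic fractions (FA, HA, HU) and model oxyhydroxides (Al2O3,
goethite) are probed over a pH range and the observed edge is fitted with
small additive model forms built from the herbicide speciation (Phi_n,
Phi_an) and, where sites are pH-dependent, the positive-site logistic
f_p(eta, pKa):

* ``N_ONLY``        Kd = Phi_n  X k_n
* ``N_AN``          Kd = Phi_n  X k_n  + Phi_an X k_an
* ``N_AN_FP``       Kd = Phi_n  X k_n  + Phi_an X k_an f_p
* ``N_AN1_AN2FP``   Kd = Phi_n  X k_n  + Phi_an X k_an1 + Phi_an X k_an2 f_p
* ``AN_FP_ONLY``    Kd = Phi_an X k_an f_p

X is the sorbent content (mg OC/g for humic fractions, g Al or Fe /kg for
the oxides); the kappas carry the reciprocal unit so Kd is mL/g.

For fixed (eta, pKa) every form is linear in the kappas, so fitting
concentrates the non-negative least-squares solution over the two site
parameters and optimizes those by multi-start Nelder-Mead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .regression import nnls_fit
from .speciation import Herbicide, SiteFractionParams, anionic_fraction, neutral_fraction, site_fraction

__all__ = ["EdgeDataset", "EdgeModelParams", "FORMS", "predict_edge", "fit_edge", "compare_forms"]

FORMS = ("N_ONLY", "N_AN", "N_AN_FP", "N_AN1_AN2FP", "AN_FP_ONLY")

# Forms containing an f_p factor need the pH edge actually sampled.
_FP_FORMS = {"N_AN_FP", "N_AN1_AN2FP", "AN_FP_ONLY"}

# kappa names per form, in design-column order.
_FORM_KAPPAS = {
    "N_ONLY": ("kappa_n",),
    "N_AN": ("kappa_n", "kappa_an"),
    "N_AN_FP": ("kappa_n", "kappa_an"),
    "N_AN1_AN2FP": ("kappa_n", "kappa_an1", "kappa_an2"),
    "AN_FP_ONLY": ("kappa_an",),
}

# Multi-start grid for the site parameters of f_p-bearing forms.
_ETA_STARTS = (0.2, 1.0, 2.0)
_PKA_STARTS = (3.0, 5.0, 7.0)


@dataclass
class EdgeDataset:
    """One adsorption-edge experiment: a sorbent at fixed content X.

    ``x_unit`` records the unit system ("mg OC/g" for humic fractions,
    "g/kg" for Al/Fe oxides).  ``al_loading`` is an optional treatment label
    (mmol(+) Al3+ per g OC) — a covariate identifying the dataset, never a
    model term; each loading is fitted separately.
    """

    sorbent: str
    x_value: float
    records: pd.DataFrame  # columns: ph, kd
    x_unit: str = "mg OC/g"
    al_loading: float | None = None

    def __post_init__(self) -> None:
        for col in ("ph", "kd"):
            if col not in self.records.columns:
                raise ValueError(f"edge records need a {col!r} column")
        if (self.records["kd"] < 0).any():
            raise ValueError("Kd must be non-negative")


@dataclass
class EdgeModelParams:
    """Fitted (or assumed) parameters of one edge-model form."""

    form: str
    kappa_n: float = 0.0
    kappa_an: float = 0.0
    kappa_an1: float = 0.0
    kappa_an2: float = 0.0
    site: SiteFractionParams | None = None
    rss: float | None = None
    r2: float | None = None
    r2_adj: float | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        for f in ("kappa_n", "kappa_an", "kappa_an1", "kappa_an2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.form in _FP_FORMS and self.site is None:
            raise ValueError(f"form {self.form} requires site parameters (eta, pKa)")

    @property
    def n_parameters(self) -> int:
        n = len(_FORM_KAPPAS[self.form])
        if self.form in _FP_FORMS:
            n += 2  # eta and pKa
        return n


def _design(form: str, x: float, ph: np.ndarray, herb: Herbicide,
            site: SiteFractionParams | None) -> np.ndarray:
    phi_n = neutral_fraction(ph, herb.pka)
    phi_an = 1.0 - phi_n
    if form in _FP_FORMS:
        fp = site_fraction(ph, site, polarity="positive_vs_neutral")
    if form == "N_ONLY":
        cols = [phi_n * x]
    elif form == "N_AN":
        cols = [phi_n * x, phi_an * x]
    elif form == "N_AN_FP":
        cols = [phi_n * x, phi_an * x * fp]
    elif form == "N_AN1_AN2FP":
        cols = [phi_n * x, phi_an * x, phi_an * x * fp]
    elif form == "AN_FP_ONLY":
        cols = [phi_an * x * fp]
    else:
        raise ValueError(f"unknown form {form!r}")
    return np.column_stack(cols)


def predict_edge(
    params: EdgeModelParams, x: float, ph, herbicide: Herbicide
) -> np.ndarray | float:
    """Evaluate an edge-model form; non-negative and linear in X."""
    ph_arr = np.atleast_1d(np.asarray(ph, dtype=float))
    X = _design(params.form, x, ph_arr, herbicide, params.site)
    kappas = np.array([getattr(params, k) for k in _FORM_KAPPAS[params.form]])
    out = X @ kappas
    return float(out[0]) if np.isscalar(ph) else out


def _goodness(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float, float]:
    rss = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else (1.0 if rss == 0 else 0.0)
    n = len(y)
    r2_adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
        if n - n_params - 1 > 0
        else float("nan")
    )
    return rss, r2, r2_adj


def fit_edge(dataset: EdgeDataset, form: str, herbicide: Herbicide) -> EdgeModelParams:
    """Fit one edge-model form by non-negative least squares.

    For forms with an f_p factor the kappas are concentrated out by NNLS at
    each candidate (eta, pKa), and the site parameters are optimized by
    Nelder-Mead from a 3x3 multi-start grid (the concentrated objective is
    multimodal); the best residual sum of squares wins, ties toward smaller
    parameter magnitude.  Requires >= 4 distinct pH values for f_p forms.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    ph = dataset.records["ph"].to_numpy(dtype=float)
    y = dataset.records["kd"].to_numpy(dtype=float)
    x = dataset.x_value

    if form in _FP_FORMS and len(np.unique(ph)) < 4:
        raise ValueError(
            f"form {form} needs >= 4 distinct pH values, got {len(np.unique(ph))}"
        )

    def solve_linear(site: SiteFractionParams | None) -> tuple[np.ndarray, float]:
        X = _design(form, x, ph, herbicide, site)
        kappas = nnls_fit(X, y)
        rss = float(np.sum((y - X @ kappas) ** 2))
        return kappas, rss

    if form not in _FP_FORMS:
        kappas, rss = solve_linear(None)
        site = None
    else:
        def objective(theta: np.ndarray) -> float:
            log_eta, pka = theta
            eta = math.exp(log_eta)
            if not (1e-3 <= eta <= 1e3) or not (0.0 <= pka <= 14.0):
                return 1e30
            _, rss = solve_linear(SiteFractionParams(pka_site=pka, eta=eta))
            return rss

        best = None
        for eta0, pka0 in itertools.product(_ETA_STARTS, _PKA_STARTS):
            res = minimize(
                objective,
                x0=np.array([math.log(eta0), pka0]),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
            )
            eta = math.exp(res.x[0])
            pka = float(res.x[1])
            # prefer lower RSS; on near-ties, smaller parameter magnitude
            key = (round(res.fun, 12), abs(eta) + abs(pka))
            if best is None or key < best[0]:
                best = (key, eta, pka, res.fun)
        if best is None or not np.isfinite(best[3]):
            raise RuntimeError(
                f"edge fit for form {form} did not converge from any start"
            )
        _, eta, pka, _ = best
        site = SiteFractionParams(pka_site=pka, eta=eta)
        kappas, rss = solve_linear(site)

    params = EdgeModelParams(form=form, site=site)
    for name, value in zip(_FORM_KAPPAS[form], kappas):
        setattr(params, name, float(value))
    yhat = predict_edge(params, x, ph, herbicide)
    params.rss, params.r2, params.r2_adj = _goodness(y, yhat, params.n_parameters)
    return params


def compare_forms(
    dataset: EdgeDataset, forms: list[str], herbicide: Herbicide
) -> list[EdgeModelParams]:
    """Fit candidate forms and rank them by adjusted R2.

    The adjusted R2 penalizes the parameter count; exact ties break
    deterministically toward the form with fewer parameters.
    """
    if len(forms) < 2 and len(forms) != 1:
        raise ValueError("need at least one candidate form")
    fitted = [fit_edge(dataset, form, herbicide) for form in forms]

    def sort_key(p: EdgeModelParams):
        r2a = p.r2_adj if p.r2_adj is not None and np.isfinite(p.r2_adj) else -np.inf
        return (-round(r2a, 10), p.n_parameters)

    return sorted(fitted, key=sort_key)
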