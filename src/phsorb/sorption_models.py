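"""Soil-scale Kd models: design matrices, penalized fits, and model ladder.

The distribution coefficient of an ionizable herbicide is modelled as an
intercept-free, non-negative linear combination of speciation-weighted soil
predictors.  Each predictor column is a soil variable X multiplied by the
neutral or anionic herbicide fraction (Phi_n, Phi_an) at that sample's
suspension pH, optionally by a pH-dependent site fraction f_p (logistic with
midpoint pKa_site and slope 1/eta), and optionally by the (8.2 - pH)
potential-acidity site count.

Two headline models emerge from the screening ladder:

* the empirical model
  Kd = Phi_n FA_X k_FAX.n
     + Phi_an (HA k_HA.an + HU k_HU.an + Al(PA) k_AlPA.an + H(PA) k_HPA.an),
  with FA_X the pore-accessible fulvic-acid content (FA_>2.5L or FA_>3.5C);
* the mechanistic model
  Kd = Phi_n FA_>2.5L k_FA.n
     + Phi_an [ HA k_HA.an + HU k_HU.an
              + (FA_>2.5L k_FA.an + Al(T) k_Al.an) f_p(eta_Al, pKa_Al)
              + Fe(T) k_Fe.an f_p(eta_Fe, pKa_Fe) ],
  in which a shared pKa governs the Al3+-bridge sites on fulvic acid and on
  Al oxyhydroxides, and a second site term governs Fe oxyhydroxides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regression import PenalizedFit, fit_penalized
from .speciation import Herbicide, SiteFractionParams, anionic_fraction, neutral_fraction, site_fraction

__all__ = [
    "Term",
    "DesignMatrix",
    "FitResult",
    "MechanisticKdParams",
    "DEFAULT_AL_SITE",
    "DEFAULT_FE_SITE",
    "ETA_GRID",
    "PKA_GRID",
    "build_design_matrix",
    "fit_kd_model",
    "model_ladder",
    "grid_fit_site_params",
    "predict_kd_mechanistic",
    "mechanistic_terms",
    "empirical_terms",
    "contribution_partition",
    "kendall_screen",
    "fit_subset_models",
]

ACIDITY_REFERENCE_PH = 8.2

# Site-parameter defaults for the mechanistic model: the Al3+-bridge sites
# (shared by accessible FA and Tamm-extractable Al) and the Fe-oxyhydroxide
# sites, from the single-sorbent edge analyses.
DEFAULT_AL_SITE = SiteFractionParams(pka_site=5.75, eta=0.2)
DEFAULT_FE_SITE = SiteFractionParams(pka_site=2.39, eta=1.16)

# Default search grids for the site parameters.
ETA_GRID: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 1.5, 2.0)
PKA_GRID: tuple[float, ...] = tuple(np.round(np.arange(2.0, 8.0 + 1e-9, 0.05), 2))


@dataclass(frozen=True)
class Term:
    """One design-matrix column descriptor.

    ``variable`` names a soil-table column; ``speciation`` selects the
    herbicide-fraction weight ("n", "an" or None); ``site`` optionally
    multiplies by the positive-site fraction f_p(eta, pKa); ``acidity_scaled``
    additionally multiplies by (8.2 - pH).
    """

    variable: str
    speciation: str | None = None  # "n" | "an" | None
    site: SiteFractionParams | None = None
    acidity_scaled: bool = False

    def __post_init__(self) -> None:
        if self.speciation not in (None, "n", "an"):
            raise ValueError(f"speciation must be 'n', 'an' or None, got {self.speciation!r}")

    @property
    def name(self) -> str:
        parts = []
        if self.speciation:
            parts.append("phi_n" if self.speciation == "n" else "phi_an")
        if self.acidity_scaled:
            parts.append("(8.2-pH)")
        parts.append(self.variable)
        if self.site is not None:
            parts.append(f"fp({self.site.eta:g};{self.site.pka_site:g})")
        return "*".join(parts)


@dataclass
class DesignMatrix:
    """Speciation-weighted predictor matrix with per-column provenance."""

    frame: pd.DataFrame  # indexed by sample_id
    terms: list[Term]
    herbicide: Herbicide

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class FitResult:
    """A fitted soil-scale Kd model."""

    herbicide: str
    label: str
    fit: PenalizedFit
    terms: list[Term]
    residuals: np.ndarray

    @property
    def r2(self) -> float:
        return self.fit.r2

    @property
    def r2_adj(self) -> float:
        return self.fit.r2_adj

    @property
    def coefficients(self) -> dict[str, float]:
        return self.fit.coef_dict


@dataclass
class MechanisticKdParams:
    """Parameter set of the mechanistic Kd model (all kappa in mL/g per unit X)."""

    kappa_fa_n: float = 0.0
    kappa_ha_an: float = 0.0
    kappa_hu_an: float = 0.0
    kappa_fa_an: float = 0.0
    kappa_al_t_an: float = 0.0
    kappa_fe_t_an: float = 0.0
    al_site: SiteFractionParams = DEFAULT_AL_SITE
    fe_site: SiteFractionParams = DEFAULT_FE_SITE
    fa_variable: str = "fa_gt2.5L"

    def __post_init__(self) -> None:
        for f in (
            "kappa_fa_n",
            "kappa_ha_an",
            "kappa_hu_an",
            "kappa_fa_an",
            "kappa_al_t_an",
            "kappa_fe_t_an",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def build_design_matrix(
    soils: pd.DataFrame, herbicide: Herbicide, terms: Sequence[Term]
) -> DesignMatrix:
    """Evaluate each term at every sample's suspension pH.

    Every referenced soil variable must be present as a column; an unknown
    name raises KeyError naming it.
    """
    ph = soils["ph"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        var = term.variable
        if var == "silt_plus_clay" and var not in soils.columns:
            values = soils["silt"].to_numpy(float) + soils["clay"].to_numpy(float)
        elif var not in soils.columns:
            raise KeyError(f"unknown soil variable {var!r}")
        else:
            values = soils[var].to_numpy(dtype=float)
        col = values.copy()
        if term.speciation == "n":
            col = col * neutral_fraction(ph, herbicide.pka)
        elif term.speciation == "an":
            col = col * anionic_fraction(ph, herbicide.pka)
        if term.site is not None:
            col = col * site_fraction(ph, term.site, polarity="positive_vs_neutral")
        if term.acidity_scaled:
            col = col * (ACIDITY_REFERENCE_PH - ph)
        cols[term.name] = col
    index = soils["sample_id"] if "sample_id" in soils.columns else soils.index
    frame = pd.DataFrame(cols, index=pd.Index(index, name="sample_id"))
    return DesignMatrix(frame=frame, terms=list(terms), herbicide=herbicide)


def _align_kd(design: DesignMatrix, kd: pd.Series) -> np.ndarray:
    missing = [i for i in design.frame.index if i not in kd.index]
    extra = [i for i in kd.index if i not in design.frame.index]
    if missing or extra:
        raise ValueError(
            f"sample sets do not match: missing Kd for {missing}, unmatched Kd rows {extra}"
        )
    return kd.loc[design.frame.index].to_numpy(dtype=float)


def fit_kd_model(
    design: DesignMatrix,
    kd: pd.Series,
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    label: str = "model",
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
) -> FitResult:
    """Non-negative, intercept-free penalized fit of Kd on a design matrix.

    ``kd`` must be indexed by the same sample ids as the design matrix.
    """
    y = _align_kd(design, kd)
    fit = fit_penalized(
        design.frame.to_numpy(dtype=float),
        y,
        names=design.names,
        penalty=penalty,
        cv=cv,
        seed=seed,
        lambdas=lambdas,
        n_lambdas=n_lambdas,
    )
    residuals = y - fit.predict(design.frame.to_numpy(dtype=float))
    return FitResult(
        herbicide=design.herbicide.name,
        label=label,
        fit=fit,
        terms=design.terms,
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# Canonical term sets


def empirical_terms(fa_variable: str = "fa_gt2.5L") -> list[Term]:
    """Terms of the empirical Kd model (accessible FA + acidity components)."""
    return [
        Term(fa_variable, "n"),
        Term("ha", "an"),
        Term("hu", "an"),
        Term("al_pa", "an"),
        Term("h_pa", "an"),
    ]


def mechanistic_terms(
    al_site: SiteFractionParams = DEFAULT_AL_SITE,
    fe_site: SiteFractionParams = DEFAULT_FE_SITE,
    fa_variable: str = "fa_gt2.5L",
) -> list[Term]:
    """Terms of the mechanistic Kd model (Al3+-bridge and Fe-site fractions)."""
    return [
        Term(fa_variable, "n"),
        Term("ha", "an"),
        Term("hu", "an"),
        Term(fa_variable, "an", site=al_site),
        Term("al_t", "an", site=al_site),
        Term("fe_t", "an", site=fe_site),
    ]


LADDER_STAGES: list[tuple[str, Callable[[], list[Term]]]] = [
    ("oc_only", lambda: [Term("oc", "n"), Term("oc", "an")]),
    (
        "humic_fractions",
        lambda: [
            Term("fa", "n"),
            Term("ha", "n"),
            Term("hu", "n"),
            Term("fa", "an"),
            Term("ha", "an"),
            Term("hu", "an"),
        ],
    ),
    (
        "oc_plus_acidity",
        lambda: [
            Term("oc", "n"),
            Term("oc", "an"),
            Term("al_pa", "an"),
            Term("h_pa", "an"),
        ],
    ),
    (
        "fractions_plus_acidity",
        lambda: [
            Term("fa", "n"),
            Term("ha", "n"),
            Term("hu", "n"),
            Term("fa", "an"),
            Term("ha", "an"),
            Term("hu", "an"),
            Term("al_pa", "an"),
            Term("h_pa", "an"),
        ],
    ),
    ("empirical_faC", lambda: empirical_terms("fa_gt3.5C")),
    ("empirical_faL", lambda: empirical_terms("fa_gt2.5L")),
    ("mechanistic", mechanistic_terms),
]


def model_ladder(
    soils: pd.DataFrame,
    kd_by_herbicide: Mapping[str, pd.Series],
    herbicides: Mapping[str, Herbicide],
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    stages: Sequence[tuple[str, Callable[[], list[Term]]]] | None = None,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit the screening ladder of model structures for every herbicide.

    Returns all FitResults plus a per-stage summary with the mean plain and
    adjusted R2 across herbicides — the model-comparison statistic.
    """
    if stages is None:
        stages = LADDER_STAGES
    results: list[FitResult] = []
    rows = []
    for stage_name, term_factory in stages:
        terms = term_factory()
        stage_results = []
        for herb_name, kd in kd_by_herbicide.items():
            herb = herbicides[herb_name]
            design = build_design_matrix(soils, herb, terms)
            res = fit_kd_model(
                design, kd, penalty=penalty, cv=cv, seed=seed, label=stage_name
            )
            stage_results.append(res)
        results.extend(stage_results)
        rows.append(
            {
                "stage": stage_name,
                "mean_r2": float(np.mean([r.r2 for r in stage_results])),
                "mean_r2_adj": float(np.nanmean([r.r2_adj for r in stage_results])),
            }
        )
    summary = pd.DataFrame(rows).set_index("stage")
    return results, summary


def grid_fit_site_params(
    soils: pd.DataFrame,
    kd_by_herbicide: Mapping[str, pd.Series],
    herbicides: Mapping[str, Herbicide],
    eta_grid: Sequence[float] = ETA_GRID,
    pka_grid: Sequence[float] = PKA_GRID,
    template: Callable[[SiteFractionParams], list[Term]] | None = None,
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
) -> tuple[float, float, list[FitResult], pd.DataFrame]:
    """Nested search for the site parameters maximizing mean adjusted R2.

    For every (eta, pKa) pair the f_p-bearing columns are rebuilt and all
    herbicides refitted; the pair with the highest mean adjusted R2 across
    herbicides wins.  Ties are broken toward larger eta, then smaller pKa.
    The default template is the mechanistic model with the gridded pair
    applied to the shared Al3+-bridge sites (Fe sites kept at their default).
    """
    if not eta_grid or not pka_grid:
        raise ValueError("eta and pKa grids must be non-empty")
    if template is None:
        template = lambda site: mechanistic_terms(al_site=site)
    records = []
    best_key = None
    best_pair = None
    best_results: list[FitResult] = []
    for eta, pka in itertools.product(eta_grid, pka_grid):
        site = SiteFractionParams(pka_site=pka, eta=eta)
        terms = template(site)
        fits = []
        for herb_name, kd in kd_by_herbicide.items():
            herb = herbicides[herb_name]
            design = build_design_matrix(soils, herb, terms)
            fits.append(
                fit_kd_model(
                    design,
                    kd,
                    penalty=penalty,
                    cv=cv,
                    seed=seed,
                    label=f"grid(eta={eta:g},pKa={pka:g})",
                    n_lambdas=n_lambdas,
                )
            )
        mean_r2a = float(np.nanmean([f.r2_adj for f in fits]))
        records.append({"eta": eta, "pka": pka, "mean_r2_adj": mean_r2a})
        # argmax with deterministic tie-break: larger eta, then smaller pKa
        key = (mean_r2a, eta, -pka)
        if best_key is None or key > best_key:
            best_key = key
            best_pair = (eta, pka)
            best_results = fits
    surface = pd.DataFrame(records)
    return best_pair[0], best_pair[1], best_results, surface


def predict_kd_mechanistic(
    soil: Mapping[str, float] | pd.Series,
    ph: float,
    herbicide: Herbicide,
    params: MechanisticKdParams,
) -> float:
    """Forward-evaluate the mechanistic Kd model for one soil at one pH.

    All anion-sorbing terms, including the Fe-oxyhydroxide term, are weighted
    by the anionic herbicide fraction; the Al3+-bridge term combines the
    accessible-FA and Tamm-Al capacities under a shared site fraction.
    """
    for var in (params.fa_variable, "ha", "hu", "al_t", "fe_t"):
        if var not in soil:
            raise KeyError(f"missing soil variable {var!r}")
    phi_n = neutral_fraction(ph, herbicide.pka)
    phi_an = 1.0 - phi_n
    fp_al = site_fraction(ph, params.al_site, polarity="positive_vs_neutral")
    fp_fe = site_fraction(ph, params.fe_site, polarity="positive_vs_neutral")
    fa_x = float(soil[params.fa_variable])
    kd = phi_n * fa_x * params.kappa_fa_n + phi_an * (
        float(soil["ha"]) * params.kappa_ha_an
        + float(soil["hu"]) * params.kappa_hu_an
        + (fa_x * params.kappa_fa_an + float(soil["al_t"]) * params.kappa_al_t_an) * fp_al
        + float(soil["fe_t"]) * params.kappa_fe_t_an * fp_fe
    )
    return float(kd)


def _mechanistic_term_values(
    soil: Mapping[str, float] | pd.Series,
    ph: float,
    herbicide: Herbicide,
    params: MechanisticKdParams,
) -> dict[str, float]:
    phi_n = neutral_fraction(ph, herbicide.pka)
    phi_an = 1.0 - phi_n
    fp_al = site_fraction(ph, params.al_site, polarity="positive_vs_neutral")
    fp_fe = site_fraction(ph, params.fe_site, polarity="positive_vs_neutral")
    fa_x = float(soil[params.fa_variable])
    return {
        "fa_neutral": phi_n * fa_x * params.kappa_fa_n,
        "ha_anionic": phi_an * float(soil["ha"]) * params.kappa_ha_an,
        "hu_anionic": phi_an * float(soil["hu"]) * params.kappa_hu_an,
        "fa_al_bridge": phi_an * fa_x * params.kappa_fa_an * fp_al,
        "al_t_sites": phi_an * float(soil["al_t"]) * params.kappa_al_t_an * fp_al,
        "fe_t_sites": phi_an * float(soil["fe_t"]) * params.kappa_fe_t_an * fp_fe,
    }


def contribution_partition(
    params: MechanisticKdParams,
    soil: Mapping[str, float] | pd.Series,
    ph: float,
    herbicide: Herbicide,
) -> dict[str, float]:
    """Share of each additive mechanistic term in the predicted Kd; sums to 1.

    Raises ValueError when the predicted Kd is zero (partition undefined).
    """
    terms = _mechanistic_term_values(soil, ph, herbicide, params)
    total = sum(terms.values())
    if total <= 0:
        raise ValueError("predicted Kd is zero; contribution partition undefined")
    return {k: v / total for k, v in terms.items()}


def kendall_screen(kd: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b of Kd against every predictor column.

    Rank correlation is used because the soil variables are mostly
    non-normal.  Constant columns yield NaN, reported as such.
    """
    if len(kd) < 4:
        raise ValueError(f"need at least 4 observations, got {len(kd)}")
    y = kd.to_numpy(dtype=float)
    rows = []
    for col in predictors.columns:
        x = predictors[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            tau, p = float("nan"), float("nan")
        else:
            tau, p = stats.kendalltau(x, y, variant="b")
        rows.append({"predictor": col, "tau": tau, "p_value": p})
    return pd.DataFrame(rows).set_index("predictor")


SUBSET_SITE_LOW = SiteFractionParams(pka_site=4.6, eta=0.1)
SUBSET_SITE_HIGH = SiteFractionParams(pka_site=7.3, eta=0.1)


def fit_subset_models(
    soils: pd.DataFrame,
    kd_by_herbicide: Mapping[str, pd.Series],
    herbicides: Mapping[str, Herbicide],
    variant: str,
    model: str = "mechanistic",
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    fa_variable: str = "fa_gt2.5L",
) -> list[FitResult]:
    """Fit the simplified low-/high-pH model variants on a pH-filtered subset.

    * ``low_pH`` keeps soils with pH <= 5.6.  Empirical variant: neutral
      adsorption on accessible FA plus anionic adsorption on the acidity
      components.  Mechanistic variant: accessible FA for both forms plus
      Al(T)/Fe(T) under a sharp site term f_p(0.1; 4.6).
    * ``high_pH`` keeps soils with pH >= 6.6.  Mechanistic variant: anionic
      adsorption on HA, HU and accessible FA under f_p(0.1; 7.3).
    """
    if variant == "low_pH":
        mask = soils["ph"] <= 5.6
    elif variant == "high_pH":
        mask = soils["ph"] >= 6.6
    else:
        raise ValueError(f"variant must be 'low_pH' or 'high_pH', got {variant!r}")
    subset = soils.loc[mask]
    if subset.empty:
        raise ValueError(f"no soils left after the {variant} pH filter")

    if variant == "low_pH":
        if model == "empirical":
            terms = [Term(fa_variable, "n"), Term("al_pa", "an"), Term("h_pa", "an")]
        else:
            terms = [
                Term(fa_variable, "n"),
                Term(fa_variable, "an"),
                Term("al_t", "an", site=SUBSET_SITE_LOW),
                Term("fe_t", "an", site=SUBSET_SITE_LOW),
            ]
    else:
        terms = [
            Term("ha", "an"),
            Term("hu", "an"),
            Term(fa_variable, "an", site=SUBSET_SITE_HIGH),
        ]

    ids = set(subset["sample_id"]) if "sample_id" in subset.columns else set(subset.index)
    results = []
    for herb_name, kd in kd_by_herbicide.items():
        herb = herbicides[herb_name]
        design = build_design_matrix(subset, herb, terms)
        kd_sub = kd[kd.index.isin(ids)]
        results.append(
            fit_kd_model(
                design, kd_sub, penalty=penalty, cv=cv, seed=seed,
                label=f"{model}_{variant}",
            )
        )
    return results
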