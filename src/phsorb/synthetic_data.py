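"""Synthetic soil, Kd and adsorption-edge data generators.

The generator emulates the structure of the study collection: 6 soil
profiles sampled at 3 depths (Ap/B/C horizons, 18 samples), suspension pH
spanning 4.2-7.7, organic carbon decreasing sharply with depth (topsoil and
subsoil medians 11.0 and 1.3 mg/g), an exhaustive humic fractionation
FA + HA + HU = OC, sandy textures, lognormal Tamm-extractable Al and Fe, and
BJH pore-surface distributions dominated by the finest size classes.
Potential-acidity components are generated from the reference acidity models
so that, at zero perturbation, they round-trip exactly through
`predict_al_pa` / `predict_h_pa`.

Kd observations are generated from the mechanistic model with a known
parameter set (the simulation truth) and multiplicative lognormal noise, and
edge datasets from any of the single-sorbent model forms.  All randomness is
driven by independent child streams of one seed, so a given (config, seed)
pair is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acidity_models import (
    AL_PA_LASSO_FA25L,
    H_PA_LASSO_FA25L,
    AcidityCoefficients,
    predict_al_pa,
    predict_h_pa,
)
from .component_isotherms import EdgeDataset, EdgeModelParams, predict_edge
from .pore_allocation import DEFAULT_PORE_EDGES, add_accessibility_variables, pore_class_columns
from .sorption_models import MechanisticKdParams, predict_kd_mechanistic
from .speciation import Herbicide

__all__ = [
    "GeneratorConfig",
    "SimulationTruth",
    "DEFAULT_TRUTH",
    "generate_soils",
    "simulate_kd",
    "simulate_edge",
]


@dataclass
class GeneratorConfig:
    """Distributional settings of the soil generator.

    Defaults reproduce the study conditions: 6 profiles x 3 horizons, pH
    4.2-7.7 (spanning at least [4.5, 7.5] by construction), topsoil/subsoil
    OC medians of 11.0/1.3 mg/g with lognormal spread, Dirichlet humic
    partition centred on FA:HA:HU = 20:25:55, sandy Dirichlet textures, and
    pore-class surface fractions centred inside the observed ranges (the
    finest micropore classes holding most of the BJH area).
    """

    n_profiles: int = 6
    horizons: tuple[str, ...] = ("Ap", "B", "C")
    depths_cm: tuple[float, ...] = (20.0, 50.0, 90.0)
    ph_range: tuple[float, float] = (4.2, 7.7)
    oc_median_topsoil: float = 11.0  # mg/g
    oc_median_subsoil: float = 1.3  # mg/g
    oc_sigma_log: float = 0.5  # lognormal shape on the natural-log scale
    humic_alpha: tuple[float, float, float] = (4.0, 5.0, 11.0)  # FA:HA:HU
    texture_alpha: tuple[float, float, float] = (12.0, 5.0, 3.0)  # sand:silt:clay
    al_t_median: float = 0.6  # g/kg
    fe_t_median: float = 1.5  # g/kg
    metal_sigma_log: float = 0.6
    bjh_area_median: float = 5.0  # m2/g total BJH surface
    bjh_area_sigma_log: float = 0.6
    pore_edges: tuple[float, ...] = DEFAULT_PORE_EDGES
    # mean share of total pore surface per class (<1.8, 1.8-2.0, 2.0-2.5,
    # 2.5-3.5, 3.5-5.0, 5.0-30, >30 nm); Dirichlet-concentrated around these
    pore_fraction_means: tuple[float, ...] = (0.09, 0.30, 0.18, 0.15, 0.10, 0.12, 0.06)
    pore_fraction_concentration: float = 120.0
    acidity_perturbation_cv: float = 0.0  # multiplicative CV on Al(PA)/H(PA)
    al_pa_model: AcidityCoefficients = field(default_factory=lambda: AL_PA_LASSO_FA25L)
    h_pa_model: AcidityCoefficients = field(default_factory=lambda: H_PA_LASSO_FA25L)

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be >= 1")
        if len(self.horizons) != len(self.depths_cm):
            raise ValueError("horizons and depths_cm must have equal length")
        if not self.ph_range[0] < self.ph_range[1]:
            raise ValueError("ph_range must be increasing")
        if len(self.pore_fraction_means) != len(self.pore_edges):
            raise ValueError(
                "pore_fraction_means must have one entry per pore class "
                f"({len(self.pore_edges)}), got {len(self.pore_fraction_means)}"
            )
        if abs(sum(self.pore_fraction_means) - 1.0) > 1e-9:
            raise ValueError("pore_fraction_means must sum to 1")
        if min(self.oc_median_topsoil, self.oc_median_subsoil, self.al_t_median,
               self.fe_t_median, self.bjh_area_median) <= 0:
            raise ValueError("medians must be positive")


# Simulation truth: plausible capacity coefficients for the mechanistic model,
# with the Al3+-bridge site at (eta 0.2, pKa 5.75) and the Fe-oxyhydroxide
# site at (eta 1.16, pKa 2.39).
DEFAULT_TRUTH = MechanisticKdParams(
    kappa_fa_n=0.5,
    kappa_ha_an=0.05,
    kappa_hu_an=0.02,
    kappa_fa_an=0.3,
    kappa_al_t_an=0.4,
    kappa_fe_t_an=0.1,
)


@dataclass
class SimulationTruth:
    """The generating parameter set and seed of one simulated dataset."""

    params: MechanisticKdParams
    seed: int
    noise_cv: float = 0.0


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=size))


def generate_soils(config: GeneratorConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a soil-property table satisfying all structural invariants.

    Returns one row per sample with ids, horizon data, pH, OC and its humic
    fractionation (summing exactly to OC), texture (summing to 100), Tamm Al
    and Fe, per-class BJH pore areas, generated potential-acidity components,
    and the derived accessibility variables (fa_gt2.5L, fa_gt3.5C, ...).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_profiles * len(cfg.horizons)

    # pH: evenly spaced over the full range with a small jitter, then
    # shuffled over samples — guarantees the span regardless of seed.
    lo, hi = cfg.ph_range
    ph = np.linspace(lo, hi, n)
    if n > 2:
        step = (hi - lo) / (n - 1)
        ph[1:-1] += rng.uniform(-0.3 * step, 0.3 * step, size=n - 2)
    rng.shuffle(ph)

    rows = []
    k = 0
    for p in range(cfg.n_profiles):
        profile_id = f"P{p + 1:02d}"
        # OC decreasing with depth: draw per horizon around depth-specific
        # medians, then sort descending within the profile.
        medians = np.array(
            [cfg.oc_median_topsoil]
            + [cfg.oc_median_subsoil * f for f in np.linspace(2.0, 0.5, len(cfg.horizons) - 1)]
        )
        oc = np.sort(_lognormal(rng, 1.0, cfg.oc_sigma_log, len(cfg.horizons)) * medians)[::-1]
        for h, (horizon, depth) in enumerate(zip(cfg.horizons, cfg.depths_cm)):
            humic = rng.dirichlet(cfg.humic_alpha)
            texture = rng.dirichlet(cfg.texture_alpha) * 100.0
            pore_frac = rng.dirichlet(
                np.asarray(cfg.pore_fraction_means) * cfg.pore_fraction_concentration
            )
            total_area = _lognormal(rng, cfg.bjh_area_median, cfg.bjh_area_sigma_log, None)
            row = {
                "sample_id": f"{profile_id}-{horizon}",
                "profile_id": profile_id,
                "horizon": horizon,
                "depth_cm": depth,
                "ph": float(ph[k]),
                "oc": float(oc[h]),
                "fa": float(oc[h] * humic[0]),
                "ha": float(oc[h] * humic[1]),
                "hu": float(oc[h] * humic[2]),
                "sand": float(texture[0]),
                "silt": float(texture[1]),
                "clay": float(texture[2]),
                "al_t": float(_lognormal(rng, cfg.al_t_median, cfg.metal_sigma_log, None)),
                "fe_t": float(_lognormal(rng, cfg.fe_t_median, cfg.metal_sigma_log, None)),
            }
            for col, frac in zip(pore_class_columns(cfg.pore_edges), pore_frac):
                row[col] = float(total_area * frac)
            rows.append(row)
            k += 1
    soils = pd.DataFrame(rows)
    soils = add_accessibility_variables(soils, edges=cfg.pore_edges)

    # Potential-acidity components from the reference models, optionally
    # perturbed multiplicatively; zero perturbation round-trips exactly.
    al_pa = np.array([predict_al_pa(r, cfg.al_pa_model) for _, r in soils.iterrows()])
    h_pa = np.array([predict_h_pa(r, cfg.h_pa_model) for _, r in soils.iterrows()])
    if cfg.acidity_perturbation_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.acidity_perturbation_cv**2))
        al_pa = al_pa * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
        h_pa = h_pa * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    soils["al_pa"] = al_pa
    soils["h_pa"] = h_pa
    soils["pa"] = al_pa + h_pa
    # Exchangeable acidity: the readily-displaced share of the potential pool.
    soils["al_ea"] = 0.5 * al_pa
    soils["h_ea"] = 0.2 * h_pa
    soils["ea"] = soils["al_ea"] + soils["h_ea"]
    return soils


def simulate_kd(
    soils: pd.DataFrame,
    herbicide: Herbicide,
    truth: MechanisticKdParams | SimulationTruth = DEFAULT_TRUTH,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Simulate Kd for every soil from the mechanistic forward model.

    Kd_i = forward(soil_i, pH_i) * lognormal(mean 1, CV noise_cv); noise_cv=0
    returns the exact forward values.  Requires the accessibility variable
    used by the truth parameters to be present (run the pore allocation
    first).
    """
    if isinstance(truth, SimulationTruth):
        params = truth.params
        noise_cv = truth.noise_cv
        seed = truth.seed
    else:
        params = truth
    if params.fa_variable not in soils.columns:
        raise KeyError(
            f"missing derived variable {params.fa_variable!r}; "
            "run pore_allocation.add_accessibility_variables first"
        )
    kd = np.array(
        [
            predict_kd_mechanistic(row, float(row["ph"]), herbicide, params)
            for _, row in soils.iterrows()
        ]
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        kd = kd * np.exp(rng.normal(-sigma**2 / 2, sigma, len(kd)))
    index = soils["sample_id"] if "sample_id" in soils.columns else soils.index
    return pd.Series(kd, index=pd.Index(index, name="sample_id"), name=herbicide.name)


def simulate_edge(
    params: EdgeModelParams,
    x: float,
    ph_grid,
    herbicide: Herbicide,
    noise_cv: float = 0.0,
    seed: int = 0,
    sorbent: str = "synthetic",
    x_unit: str = "mg OC/g",
) -> EdgeDataset:
    """Simulate a single-sorbent adsorption edge from a model form."""
    ph_arr = np.asarray(ph_grid, dtype=float)
    kd = np.atleast_1d(predict_edge(params, x, ph_arr, herbicide)).astype(float)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        kd = kd * np.exp(rng.normal(-sigma**2 / 2, sigma, len(kd)))
    return EdgeDataset(
        sorbent=sorbent,
        x_value=x,
        x_unit=x_unit,
        records=pd.DataFrame({"ph": ph_arr, "kd": kd}),
    )
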