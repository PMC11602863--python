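"""Allocation of fulvic acids over BJH pore-size classes.

Fulvic acids (and, optionally, humic acids) coat the internal surface of soil
pores.  Herbicide molecules are ~1 nm long, so the coating inside the
narrowest pores is inaccessible to them.  Two allocation models produce the
accessible-content variables used as regression predictors:

* constant thickness ("C" variables, e.g. FA_>3.5C): the surface density of
  the coating is uniform, so the content above a radius cutoff is simply
  proportional to the pore surface area above the cutoff;
* logistic ("L" variables, e.g. FA_>2.5L): the surface density decreases with
  pore radius following S(r) = S_min + S_max / 2**((r/r_half)**2), a
  lognormal-like profile reflecting preferential accumulation of the
  low-molecular-weight fraction in the finest pores.

With the ratio S_max/S_min and the half-content radius r_half fixed on a
small grid, the only free scale is S_min, and the mass-balance fit
(FA_total - sum_i area_i * S(r_i))**2 = 0 has a closed-form solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PoreClass",
    "PoreProfile",
    "OrganicFractions",
    "RATIO_GRID",
    "R_HALF_GRID",
    "DEFAULT_RATIO",
    "DEFAULT_R_HALF",
    "DEFAULT_CUTOFF",
    "logistic_pore_content",
    "fit_pore_profile",
    "fa_above_cutoff_constant",
    "fa_above_cutoff_logistic",
    "add_accessibility_variables",
    "pore_classes_from_row",
]

# Grids used when screening the allocation parameters, and the headline
# values retained for the accessibility predictors.
RATIO_GRID: tuple[float, ...] = (1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5)
R_HALF_GRID: tuple[float, ...] = (2.0, 2.5, 3.5, 5.0)
DEFAULT_RATIO = 6.0
DEFAULT_R_HALF = 3.5
DEFAULT_CUTOFF = 2.5

# Default BJH class boundaries (nm); the last class is open-ended.
DEFAULT_PORE_EDGES: tuple[float, ...] = (1.5, 1.8, 2.0, 2.5, 3.5, 5.0, 30.0)


@dataclass(frozen=True)
class PoreClass:
    """One BJH desorption pore-size class, half-open [r_lower, r_upper).

    ``area`` is the BJH surface area within the class (m2/g).  The class is
    represented in the logistic model by its lower-bound radius.
    """

    r_lower: float
    r_upper: float  # math.inf for the terminal open class
    area: float
    fraction: float | None = None  # % of total pore surface, optional

    def __post_init__(self) -> None:
        if not self.r_lower < self.r_upper:
            raise ValueError(
                f"pore class requires r_lower < r_upper, got [{self.r_lower}, {self.r_upper})"
            )
        if self.area < 0:
            raise ValueError(f"pore-class area must be >= 0, got {self.area}")


@dataclass
class OrganicFractions:
    """Humic-substance fractionation of soil organic carbon (mg OC/g soil)."""

    fa: float
    ha: float
    hu: float
    oc: float

    def __post_init__(self) -> None:
        if min(self.fa, self.ha, self.hu, self.oc) < 0:
            raise ValueError("organic fractions must be non-negative")
        if self.fa + self.ha + self.hu > self.oc * (1 + 1e-9) + 1e-12:
            raise ValueError("FA + HA + HU must not exceed OC")


@dataclass
class PoreProfile:
    """Fitted logistic allocation of one organic fraction over pore classes."""

    s_min: float  # mg/m2
    s_max: float  # mg/m2
    r_half: float  # nm
    ratio: float  # s_max / s_min
    class_contents: list[tuple[PoreClass, float]]  # (class, content mg/g)

    @property
    def total(self) -> float:
        return float(sum(c for _, c in self.class_contents))


def logistic_pore_content(r, s_min: float, s_max: float, r_half: float):
    """Surface density (mg/m2) of the coating in pores of radius *r* (nm).

    S(r) = s_min + s_max / 2**((r/r_half)**2): equals s_min + s_max at r = 0,
    s_min + s_max/2 at r = r_half, and decays to s_min for wide pores.
    """
    if r_half <= 0:
        raise ValueError(f"r_half must be > 0, got {r_half}")
    if s_min < 0 or s_max < 0:
        raise ValueError("s_min and s_max must be >= 0")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("pore radius must be >= 0")
    out = s_min + s_max * np.exp2(-((r_arr / r_half) ** 2))
    return float(out) if np.isscalar(r) else out


def _weights(classes: Sequence[PoreClass], r_half: float) -> np.ndarray:
    radii = np.array([c.r_lower for c in classes], dtype=float)
    return np.exp2(-((radii / r_half) ** 2))


def fit_pore_profile(
    fa_total: float,
    classes: Sequence[PoreClass],
    ratio: float = DEFAULT_RATIO,
    r_half: float = DEFAULT_R_HALF,
) -> PoreProfile:
    """Fit the logistic allocation to one soil by mass balance.

    With ratio = s_max/s_min and r_half fixed, solving
    sum_i area_i * (s_min + ratio * s_min * w_i) = fa_total
    for the single free scale gives
    s_min = fa_total / sum_i area_i * (1 + ratio * w_i), where
    w_i = 2**(-(r_i/r_half)**2) at the class lower-bound radius r_i.
    Class contents (mg/g) then sum to fa_total exactly.
    """
    if fa_total <= 0:
        raise ValueError(f"fa_total must be > 0, got {fa_total}")
    if r_half <= 0:
        raise ValueError(f"r_half must be > 0, got {r_half}")
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    classes = list(classes)
    areas = np.array([c.area for c in classes], dtype=float)
    if not classes or not np.any(areas > 0):
        raise ValueError("no allocation possible: all pore-class areas are zero")
    w = _weights(classes, r_half)
    denom = float(np.sum(areas * (1.0 + ratio * w)))
    s_min = fa_total / denom
    s_max = ratio * s_min
    contents = areas * (s_min + s_max * w)
    return PoreProfile(
        s_min=s_min,
        s_max=s_max,
        r_half=r_half,
        ratio=ratio,
        class_contents=list(zip(classes, contents.tolist())),
    )


def fa_above_cutoff_constant(
    fa_total: float, classes: Sequence[PoreClass], cutoff: float
) -> float:
    """Accessible content under uniform surface density (the "C" variables).

    Returns fa_total scaled by the share of pore surface area residing in
    classes whose lower bound is at or above *cutoff* (nm).
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    classes = list(classes)
    total_area = sum(c.area for c in classes)
    if total_area <= 0:
        raise ValueError("no allocation possible: total pore area is zero")
    above = sum(c.area for c in classes if c.r_lower >= cutoff)
    return fa_total * above / total_area


def fa_above_cutoff_logistic(profile: PoreProfile, cutoff: float) -> float:
    """Accessible content under the fitted logistic profile (the "L" variables)."""
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    return float(
        sum(content for cls, content in profile.class_contents if cls.r_lower >= cutoff)
    )


# ---------------------------------------------------------------------------
# Soil-table helpers


def pore_class_columns(edges: Sequence[float] = DEFAULT_PORE_EDGES) -> list[str]:
    """Column names used for per-class BJH areas in soil tables."""
    cols = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        cols.append(f"pore_area_{lo:g}_{hi:g}")
    cols.append(f"pore_area_{edges[-1]:g}_inf")
    return cols


def pore_classes_from_row(
    row: pd.Series, edges: Sequence[float] = DEFAULT_PORE_EDGES
) -> list[PoreClass]:
    """Build PoreClass objects from the per-class area columns of a soil row."""
    cols = pore_class_columns(edges)
    bounds = list(zip(edges[:-1], edges[1:])) + [(edges[-1], math.inf)]
    classes = []
    for col, (lo, hi) in zip(cols, bounds):
        if col not in row:
            raise KeyError(f"missing pore-class column {col!r}")
        classes.append(PoreClass(r_lower=lo, r_upper=hi, area=float(row[col])))
    return classes


def add_accessibility_variables(
    soils: pd.DataFrame,
    ratio: float = DEFAULT_RATIO,
    r_half: float = DEFAULT_R_HALF,
    cutoffs_logistic: Iterable[float] = (2.0, 2.5, 3.5),
    cutoffs_constant: Iterable[float] = (1.8, 2.0, 2.5, 3.5, 5.0),
    fraction: str = "fa",
    edges: Sequence[float] = DEFAULT_PORE_EDGES,
) -> pd.DataFrame:
    """Append accessible-content predictor columns to a soil table.

    Adds ``{FRAC}_gt{cutoff}L`` columns from the fitted logistic profile and
    ``{FRAC}_gt{cutoff}C`` columns from the constant-thickness allocation,
    e.g. ``fa_gt2.5L`` and ``fa_gt3.5C``.  ``fraction`` may be "fa" or "ha";
    the HA analogues use the same machinery.
    """
    out = soils.copy()
    names_l = [f"{fraction}_gt{c:g}L" for c in cutoffs_logistic]
    names_c = [f"{fraction}_gt{c:g}C" for c in cutoffs_constant]
    for name in names_l + names_c:
        out[name] = np.nan
    for idx, row in soils.iterrows():
        classes = pore_classes_from_row(row, edges)
        total = float(row[fraction])
        if total <= 0:
            for name in names_l + names_c:
                out.loc[idx, name] = 0.0
            continue
        profile = fit_pore_profile(total, classes, ratio=ratio, r_half=r_half)
        for c, name in zip(cutoffs_logistic, names_l):
            out.loc[idx, name] = fa_above_cutoff_logistic(profile, c)
        for c, name in zip(cutoffs_constant, names_c):
            out.loc[idx, name] = fa_above_cutoff_constant(total, classes, c)
    return out
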