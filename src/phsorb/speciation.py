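"""Acid-base speciation of herbicides and of sorbent surface sites.

Monoprotic phenoxyalkanoic acid herbicides partition between a neutral
(protonated) and an anionic form according to the Henderson–Hasselbalch
relation; soil sorbents expose pH-dependent site populations described by a
generalised logistic with slope 1/eta.  Both are evaluated here in a
numerically safe form: the exponent ``(pH - pKa)/eta`` can reach +-50 for
small eta, so the logistic is computed via ``scipy.special.expit`` and the
result clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "Herbicide",
    "SpeciesFractions",
    "SiteFractionParams",
    "neutral_fraction",
    "anionic_fraction",
    "species_fractions",
    "site_fraction",
]

_LN10 = math.log(10.0)

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class Herbicide:
    """An ionizable herbicide: identity plus the dissociation constant.

    pKa is the negative decadic log of the acid dissociation constant and is
    the single property that drives speciation.  The remaining fields are
    optional metadata (octanol-water logP, GUS leaching index, molecular
    dimensions in nm) carried through reports but never used in the models.
    """

    name: str
    pka: float
    acid_class: Literal["acetic", "propionic", "butyric"] = "acetic"
    logp: float | None = None
    gus: float | None = None
    length_nm: float | None = None
    width_nm: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.pka) or not (0.0 < self.pka < 14.0):
            raise ValueError(f"pKa must be finite and in (0, 14), got {self.pka!r}")
        for attr in ("length_nm", "width_nm"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive when present, got {v!r}")


@dataclass(frozen=True)
class SpeciesFractions:
    """Neutral and anionic fractions of a herbicide at one pH; sums to 1."""

    phi_n: float
    phi_an: float


@dataclass(frozen=True)
class SiteFractionParams:
    """Parameters of the logistic describing pH-dependent sorbent sites.

    ``pka_site`` is the midpoint (the mean site dissociation constant on the
    -log10 scale) and ``eta`` flattens (eta > 1) or sharpens (eta < 1) the
    transition; eta -> 0 approaches a step at pka_site.  The conventional
    organic-matter default is (pKa 5, eta 2).
    """

    pka_site: float = 5.0
    eta: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta) or self.eta <= 0:
            raise ValueError(f"eta must be finite and > 0, got {self.eta!r}")
        if not np.isfinite(self.pka_site):
            raise ValueError(f"pka_site must be finite, got {self.pka_site!r}")


def _check_finite(name: str, value: ArrayLike) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def _logistic10(x: ArrayLike) -> ArrayLike:
    """1 / (1 + 10**x), overflow-safe, clamped to [0, 1]."""
    out = expit(-_LN10 * np.asarray(x, dtype=float))
    out = np.clip(out, 0.0, 1.0)
    return out


def neutral_fraction(ph: ArrayLike, pka: ArrayLike) -> ArrayLike:
    """Fraction of the herbicide in the neutral (protonated) form.

    Phi_n = 1 / (1 + 10**(pH - pKa)); strictly decreasing in pH.
    Accepts scalars or arrays (broadcast).
    """
    ph_a = _check_finite("pH", ph)
    pka_a = _check_finite("pKa", pka)
    out = _logistic10(ph_a - pka_a)
    if np.isscalar(ph) and np.isscalar(pka):
        return float(out)
    return out


def anionic_fraction(ph: ArrayLike, pka: ArrayLike) -> ArrayLike:
    """Fraction in the anionic (dissociated) form: 1 - Phi_n."""
    out = 1.0 - np.asarray(neutral_fraction(ph, pka))
    if np.isscalar(ph) and np.isscalar(pka):
        return float(out)
    return out


def species_fractions(ph: float, herbicide: Herbicide) -> SpeciesFractions:
    """Both species fractions of *herbicide* at suspension pH."""
    phi_n = neutral_fraction(ph, herbicide.pka)
    return SpeciesFractions(phi_n=phi_n, phi_an=1.0 - phi_n)


def site_fraction(
    ph: ArrayLike,
    params: SiteFractionParams,
    polarity: Literal["neutral_vs_anionic", "positive_vs_neutral"] = "neutral_vs_anionic",
) -> ArrayLike:
    """Fraction of sorbent sites on the protonated side of the transition.

    f = 1 / (1 + 10**((pH - pKa_site)/eta)).  With
    ``polarity="neutral_vs_anionic"`` the value is the neutral-site fraction
    f_n of acidic (carboxyl/phenol) groups; with ``polarity=
    "positive_vs_neutral"`` the same quantity is read as the positive-site
    fraction f_p of amine groups or oxide surfaces.  The complementary
    fraction is ``1 - f`` in either reading.
    """
    if polarity not in ("neutral_vs_anionic", "positive_vs_neutral"):
        raise ValueError(f"unknown polarity {polarity!r}")
    ph_a = _check_finite("pH", ph)
    out = _logistic10((ph_a - params.pka_site) / params.eta)
    if np.isscalar(ph):
        return float(out)
    return out
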