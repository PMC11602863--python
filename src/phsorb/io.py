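"""Tabular I/O, batch-experiment arithmetic, and the herbicide registry.

All exchange formats are plain CSV with UTF-8 and documented column
dictionaries; the reader accepts a comma decimal separator via an explicit
``decimal`` flag (the source tables are of Polish origin).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sorption_models import FitResult
from .speciation import Herbicide

__all__ = [
    "BatchExperiment",
    "kd_from_batch",
    "koc_from_kd",
    "read_soil_table",
    "read_kd_table",
    "read_edge_table",
    "read_herbicide_config",
    "write_fit_report",
    "DEFAULT_HERBICIDES",
]

# Placeholder literature pKa values for the six PAAHs (the experimentally
# determined values are not machine-readable from the source); override by
# supplying a herbicide config.  logP/GUS omitted: metadata only.
DEFAULT_HERBICIDES: dict[str, Herbicide] = {
    "2,4-D": Herbicide("2,4-D", pka=2.73, acid_class="acetic"),
    "MCPA": Herbicide("MCPA", pka=3.07, acid_class="acetic"),
    "DCPP-P": Herbicide("DCPP-P", pka=3.00, acid_class="propionic"),
    "MCPP-P": Herbicide("MCPP-P", pka=3.11, acid_class="propionic"),
    "2,4-DB": Herbicide("2,4-DB", pka=4.80, acid_class="butyric"),
    "MCPB": Herbicide("MCPB", pka=4.84, acid_class="butyric"),
}

OECD_MIN_REMAINING = 0.10  # OECD 106: >= 10% of c0 should stay in solution


@dataclass(frozen=True)
class BatchExperiment:
    """One OECD-106 batch equilibration record."""

    c0: float  # initial concentration, mg/L (study default 3.0)
    ce: float  # equilibrium concentration, mg/L
    solution_volume: float  # mL
    soil_mass: float  # g
    ratio_label: str = ""

    def __post_init__(self) -> None:
        if self.soil_mass <= 0 or self.solution_volume <= 0:
            raise ValueError("soil mass and solution volume must be positive")
        if self.ce < 0 or self.c0 < 0:
            raise ValueError("concentrations must be non-negative")


def kd_from_batch(exp: BatchExperiment) -> float:
    """Kd (mL/g) from the depletion of solution concentration.

    Kd = (c0 - ce) V / (ce m).  ce = 0 is undefined; ce > c0 (apparent
    negative adsorption) and ce below 10% of c0 (outside the OECD-106
    acceptability range) are flagged with warnings.
    """
    if exp.ce == 0:
        raise ValueError("equilibrium concentration is zero; Kd undefined")
    if exp.ce > exp.c0:
        warnings.warn(
            f"ce ({exp.ce}) exceeds c0 ({exp.c0}): negative apparent adsorption",
            stacklevel=2,
        )
    elif exp.ce < OECD_MIN_REMAINING * exp.c0:
        warnings.warn(
            f"ce ({exp.ce}) below 10% of c0 ({exp.c0}): outside the OECD-106 "
            "acceptability range",
            stacklevel=2,
        )
    return (exp.c0 - exp.ce) * exp.solution_volume / (exp.ce * exp.soil_mass)


def koc_from_kd(kd: float, oc_percent: float) -> float:
    """Organic-carbon normalized coefficient: KOC = 100 Kd / OC%."""
    if oc_percent <= 0:
        raise ValueError("OC percent must be positive")
    return 100.0 * kd / oc_percent


# ---------------------------------------------------------------------------
# Table readers

SOIL_REQUIRED = ["sample_id", "ph", "oc", "fa", "ha", "hu", "sand", "silt", "clay"]
KD_REQUIRED = ["sample_id", "herbicide", "ph", "kd"]
EDGE_REQUIRED = ["ph", "kd"]


def _read_csv(path: str | Path, required: list[str], decimal: str = ".") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, decimal=decimal)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing} ({len(df)} rows read)"
        )
    return df


def _require_numeric(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            )
        df[col] = coerced


def read_soil_table(path: str | Path, decimal: str = ".", validate: bool = True) -> pd.DataFrame:
    """Read a soil-property table; unknown columns are preserved.

    Validation checks texture closure (sand + silt + clay = 100 +- 0.5), the
    pH range, and the humic mass balance, reporting offending sample ids.
    """
    df = _read_csv(path, SOIL_REQUIRED, decimal)
    numeric = [c for c in df.columns if c not in ("sample_id", "profile_id", "horizon")]
    _require_numeric(df, numeric, path)
    if validate:
        texture = df["sand"] + df["silt"] + df["clay"]
        bad = df.loc[(texture - 100.0).abs() > 0.5, "sample_id"]
        if len(bad) > 0:
            raise ValueError(
                f"{path}: sand+silt+clay != 100 +- 0.5 for sample(s) {list(bad)}"
            )
        bad = df.loc[(df["ph"] < 3) | (df["ph"] > 9), "sample_id"]
        if len(bad) > 0:
            raise ValueError(f"{path}: pH outside [3, 9] for sample(s) {list(bad)}")
        excess = df["fa"] + df["ha"] + df["hu"] - df["oc"]
        bad = df.loc[excess > 1e-6 + 1e-6 * df["oc"], "sample_id"]
        if len(bad) > 0:
            raise ValueError(f"{path}: FA+HA+HU exceeds OC for sample(s) {list(bad)}")
    return df


def read_kd_table(path: str | Path, decimal: str = ".") -> pd.DataFrame:
    """Read a measured-Kd table (one row per soil x herbicide)."""
    df = _read_csv(path, KD_REQUIRED, decimal)
    _require_numeric(df, ["ph", "kd"], path)
    if (df["kd"] < 0).any():
        bad = df.loc[df["kd"] < 0, "sample_id"]
        raise ValueError(f"{path}: negative Kd for sample(s) {list(bad)}")
    return df


def read_edge_table(path: str | Path, decimal: str = ".") -> pd.DataFrame:
    """Read a single-sorbent edge table (columns ph, kd, optional x, loading)."""
    df = _read_csv(path, EDGE_REQUIRED, decimal)
    _require_numeric(df, ["ph", "kd"], path)
    return df


def read_herbicide_config(path: str | Path, decimal: str = ".") -> dict[str, Herbicide]:
    """Read a herbicide config CSV (name, pka, acid_class, optional metadata)."""
    df = _read_csv(path, ["name", "pka"], decimal)
    _require_numeric(df, ["pka"], path)
    herbicides = {}
    for _, row in df.iterrows():
        kwargs = {}
        for opt in ("logp", "gus", "length_nm", "width_nm"):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[opt] = float(row[opt])
        herbicides[str(row["name"])] = Herbicide(
            name=str(row["name"]),
            pka=float(row["pka"]),
            acid_class=str(row.get("acid_class", "acetic")),
            **kwargs,
        )
    return herbicides


def write_fit_report(
    results: list[FitResult], path: str | Path, seed: int | None = None
) -> None:
    """Write fitted models to JSON (or CSV for a flat coefficient table)."""
    path = Path(path)
    payload = {
        "seed": seed,
        "models": [
            {
                "herbicide": r.herbicide,
                "label": r.label,
                "penalty": r.fit.penalty,
                "lambda_optimal": r.fit.lambda_optimal,
                "r2": r.fit.r2,
                "r2_adj": None if np.isnan(r.fit.r2_adj) else r.fit.r2_adj,
                "cv_folds": r.fit.cv_folds,
                "cv_seed": r.fit.seed,
                "coefficients": r.coefficients,
                "std_coefficients": dict(
                    zip(r.fit.names, r.fit.std_coefficients.tolist())
                ),
            }
            for r in results
        ],
    }
    if path.suffix.lower() == ".csv":
        rows = []
        for m in payload["models"]:
            for name, coef in m["coefficients"].items():
                rows.append(
                    {
                        "herbicide": m["herbicide"],
                        "label": m["label"],
                        "term": name,
                        "coefficient": coef,
                        "std_coefficient": m["std_coefficients"][name],
                        "lambda_optimal": m["lambda_optimal"],
                        "r2": m["r2"],
                        "r2_adj": m["r2_adj"],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(payload, indent=2))
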