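"""Derivation of performance and tolerance traits from raw plant records.

Four measurements per experimental group:

* **Fv/Fm** — maximum quantum yield of photosystem II from dark-adapted
  chlorophyll fluorescence, ``(Fm − F0) / Fm``; healthy leaves sit near
  0.83 and the ratio declines under stress.
* **Survival percentage** — ``100 × S / N`` over the plants of a group.
* **Thousand-seed weight (TSW)** — ISTA-style estimate: ten times the mean
  mass of 100-seed samples (eight samples per plant by default).
* **Soluble seed protein** — Bradford assay: a linear BSA standard curve
  ``A595 = a + b·C`` fitted by least squares and inverted for unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyGroupError,
    InvalidFluorescenceError,
    UninformativeStandardsError,
)
from .simulate import DEFAULT_BRADFORD_CURVE

__all__ = [
    "fvfm",
    "survival_percentage",
    "thousand_seed_weight",
    "bradford_protein",
    "BradfordResult",
    "DEFAULT_BRADFORD_STANDARDS",
    "summarize_plants",
    "GROUP_COLS",
]

GROUP_COLS = ["genotype", "latitude_deg_s", "ecotype", "endophyte", "nacl_mM"]

#: BSA standards (concentration, A595) lying exactly on the calibration line
#: used by the synthetic read-out; replace with measured standards for real data.
DEFAULT_BRADFORD_STANDARDS: tuple[tuple[float, float], ...] = tuple(
    (c, DEFAULT_BRADFORD_CURVE[0] + DEFAULT_BRADFORD_CURVE[1] * c)
    for c in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
)


def fvfm(fm: float, f0: float) -> float:
    """Maximum quantum yield of PSII, (Fm − F0)/Fm.

    Scale-invariant in the raw fluorescence units: only the ratio F0/Fm
    matters.

    Raises
    ------
    InvalidFluorescenceError
        Unless ``fm > f0 > 0``.
    """
    if not (f0 > 0) or not (fm > f0):
        raise InvalidFluorescenceError(f"need fm > f0 > 0, got fm={fm}, f0={f0}")
    return (fm - f0) / fm


def survival_percentage(survivors: int, total: int) -> float:
    """Final survival as a percentage, 100 × S/N.

    Computed in exact rational arithmetic before conversion to float, so
    e.g. 10 of 12 is exactly 250/3 % and N of N is exactly 100.
    """
    if total == 0:
        raise EmptyGroupError("survival percentage undefined for an empty group")
    if not (0 <= survivors <= total):
        raise ValueError(f"need 0 <= survivors <= total, got {survivors}/{total}")
    return float(Fraction(100) * Fraction(int(survivors), int(total)))


def thousand_seed_weight(masses: Sequence[float]) -> float:
    """TSW in grams: 10 × mean mass of the 100-seed samples.

    Unrounded; round to the balance precision (0.01 g) only when reporting.
    """
    arr = np.asarray(masses, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one 100-seed sample mass is required")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("sample masses must be finite and positive")
    return float(10.0 * arr.mean())


@dataclass(frozen=True)
class BradfordResult:
    """Inverted Bradford standard curve applied to unknown absorbances."""

    concentrations: np.ndarray    # per unknown, dilution-corrected
    extrapolated: np.ndarray      # bool per unknown: outside standards' A range
    slope: float
    intercept: float
    r_squared: float


def bradford_protein(
    standards: Sequence[tuple[float, float]],
    unknowns: Sequence[float],
    dilution_factor: float = 1.0,
) -> BradfordResult:
    """Protein concentrations from A595 readings via a linear BSA curve.

    Fits ``A = a + b·C`` to the standards by least squares, inverts for each
    unknown, multiplies by the dilution factor, and reports the curve R².
    Unknown absorbances outside the standards' absorbance range are flagged
    as extrapolated (not rejected).

    Raises
    ------
    UninformativeStandardsError
        Fewer than 3 standards, all-equal concentrations, or a singular fit.
    """
    std = np.asarray(standards, dtype=float)
    if std.ndim != 2 or std.shape[0] < 3 or std.shape[1] != 2:
        raise UninformativeStandardsError("need >= 3 (concentration, absorbance) standards")
    conc, absorb = std[:, 0], std[:, 1]
    if np.any(conc < 0):
        raise UninformativeStandardsError("standard concentrations must be non-negative")
    if np.ptp(conc) == 0:
        raise UninformativeStandardsError("standard concentrations are all equal")
    if dilution_factor <= 0:
        raise ValueError(f"dilution_factor must be positive, got {dilution_factor}")
    slope, intercept = np.polyfit(conc, absorb, 1)
    if abs(slope) < 1e-12 * max(1.0, float(np.ptp(absorb)), 1e-12):
        raise UninformativeStandardsError("standard curve slope is ~0; cannot invert")
    fitted = intercept + slope * conc
    ss_res = float(np.sum((absorb - fitted) ** 2))
    ss_tot = float(np.sum((absorb - absorb.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    a_unknown = np.asarray(unknowns, dtype=float)
    conc_unknown = (a_unknown - intercept) / slope * dilution_factor
    lo, hi = float(absorb.min()), float(absorb.max())
    extrapolated = (a_unknown < lo) | (a_unknown > hi)
    return BradfordResult(
        concentrations=conc_unknown,
        extrapolated=extrapolated,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


def summarize_plants(
    plants: pd.DataFrame,
    bradford_standards: Sequence[tuple[float, float]] = DEFAULT_BRADFORD_STANDARDS,
    dilution_factor: float = 1.0,
) -> pd.DataFrame:
    """Aggregate per-plant records into the group summary table.

    One row per genotype × endophyte × salinity with mean Fv/Fm (over all
    plants — fluorescence is measured before any death), survival %, mean
    thousand-seed weight and mean protein concentration (survivors only;
    NaN for groups with no survivors — missingness is informative and left
    visible), and the group sizes.
    """
    df = plants.copy()
    bad = ~((df["f0"] > 0) & (df["fm"] > df["f0"]))
    if bad.any():
        raise InvalidFluorescenceError(
            f"{int(bad.sum())} plants violate fm > f0 > 0"
        )
    df["fvfm"] = (df["fm"] - df["f0"]) / df["fm"]

    seed_cols = [c for c in df.columns if c.startswith("seed_mass_g_")]
    abs_cols = [c for c in df.columns if c.startswith("abs595_")]
    if not seed_cols or not abs_cols:
        raise ValueError("plant table lacks seed_mass_g_* / abs595_* columns")

    df["tsw_g"] = 10.0 * df[seed_cols].mean(axis=1)
    mean_abs = df[abs_cols].mean(axis=1)
    fit = bradford_protein(
        bradford_standards,
        mean_abs.fillna(mean_abs.median() if mean_abs.notna().any() else 0.0).to_numpy(),
        dilution_factor=dilution_factor,
    )
    protein = pd.Series(fit.concentrations, index=df.index)
    protein[mean_abs.isna()] = np.nan
    df["protein"] = protein

    rows = []
    for key, g in df.groupby(GROUP_COLS, sort=True):
        n_total = int(len(g))
        n_alive = int(g["alive"].sum())
        alive = g[g["alive"] == 1]
        rows.append(
            {
                **dict(zip(GROUP_COLS, key)),
                "mean_fvfm": float(g["fvfm"].mean()),
                "survival_pct": survival_percentage(n_alive, n_total),
                "tsw_g": float(alive["tsw_g"].mean()) if n_alive else np.nan,
                "protein": float(alive["protein"].mean()) if n_alive else np.nan,
                "n_alive": n_alive,
                "n_total": n_total,
            }
        )
    return pd.DataFrame(rows)
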