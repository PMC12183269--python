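"""Relative gene-expression quantification from qPCR Ct tables.

Two estimators of the fold change of a target gene (here CqNHX1) relative to
a reference gene (EF-1α), comparing a sample condition against a calibrator
condition:

* **Livak 2^−ΔΔCt** — assumes perfect doubling per cycle:
  ``FC = 2^−[(Ct_t − Ct_r)_sample − (Ct_t − Ct_r)_calibrator]``.
* **Pfaffl efficiency-corrected ratio** — uses measured per-gene
  amplification efficiencies E (amplification factor per cycle, in [1, 2]):
  ``FC = E_t^ΔCP_t / E_r^ΔCP_r`` with ``ΔCP = Ct_calibrator − Ct_sample``.

With both efficiencies equal to 2 the Pfaffl ratio reduces exactly to the
Livak estimator.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompletePairError,
    InvalidEfficiencyError,
    MissingCalibratorError,
)

__all__ = [
    "delta_delta_ct",
    "pfaffl_ratio",
    "summarize_expression",
    "DEFAULT_CALIBRATOR",
]

#: Calibrator rule: within each genotype, the endophyte-free unstressed group.
DEFAULT_CALIBRATOR: dict[str, object] = {"endophyte": "E-", "nacl_mM": 0.0}

_CONDITION_COLS = ["genotype", "endophyte", "nacl_mM"]


def _check_pair(pair: Sequence[float], name: str) -> tuple[float, float]:
    try:
        ct_target, ct_reference = pair
    except (TypeError, ValueError) as exc:
        raise IncompletePairError(f"{name} must be a (Ct_target, Ct_reference) pair") from exc
    for label, value in (("target", ct_target), ("reference", ct_reference)):
        if value is None or not math.isfinite(value):
            raise IncompletePairError(f"{name} {label} Ct is missing or non-finite: {value!r}")
    return float(ct_target), float(ct_reference)


def delta_delta_ct(sample: Sequence[float], calibrator: Sequence[float]) -> float:
    """Livak fold change 2^−ΔΔCt of a sample against a calibrator.

    Parameters
    ----------
    sample, calibrator
        ``(Ct_target, Ct_reference)`` pairs; all four Ct values must be
        finite.

    Returns
    -------
    float
        Fold change; 1.0 means no regulation relative to the calibrator.
    """
    st, sr = _check_pair(sample, "sample")
    ct, cr = _check_pair(calibrator, "calibrator")
    ddct = (st - sr) - (ct - cr)
    return float(2.0 ** (-ddct))


def pfaffl_ratio(
    sample: Sequence[float],
    calibrator: Sequence[float],
    e_target: float,
    e_ref: float,
) -> float:
    """Efficiency-corrected expression ratio E_t^ΔCP_t / E_r^ΔCP_r.

    ``ΔCP = Ct_calibrator − Ct_sample`` per gene. Efficiencies are
    amplification factors per cycle and must lie in (0, 2]; the biologically
    meaningful range is [1, 2] (no amplification to perfect doubling).
    """
    for name, e in (("e_target", e_target), ("e_ref", e_ref)):
        if e is None or not math.isfinite(e) or e <= 0:
            raise InvalidEfficiencyError(f"{name} must be positive and finite, got {e!r}")
        if e > 2.0:
            raise InvalidEfficiencyError(f"{name}={e} exceeds the perfect-doubling bound 2")
    st, sr = _check_pair(sample, "sample")
    ct, cr = _check_pair(calibrator, "calibrator")
    return float(e_target ** (ct - st) / e_ref ** (cr - sr))


def _pivot_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-biological-replicate table: one row per condition × rep."""
    required = set(_CONDITION_COLS + ["bio_rep", "gene", "ct", "efficiency"])
    missing = required - set(ct_table.columns)
    if missing:
        raise IncompletePairError(f"ct table missing columns: {sorted(missing)}")
    bad = ~np.isfinite(ct_table["ct"]) | (ct_table["ct"] <= 0)
    if bad.any():
        raise IncompletePairError(
            f"{int(bad.sum())} Ct values are non-finite or non-positive"
        )
    eff = ct_table["efficiency"]
    if ((eff < 1.0) | (eff > 2.0)).any():
        raise InvalidEfficiencyError("efficiency column must lie in [1, 2]")
    wide = ct_table.pivot_table(
        index=_CONDITION_COLS + ["bio_rep"],
        columns="gene",
        values=["ct", "efficiency"],
        aggfunc="first",
    )
    for gene in ("target", "reference"):
        if ("ct", gene) not in wide.columns or wide[("ct", gene)].isna().any():
            raise IncompletePairError(
                f"some biological replicates lack a {gene}-gene Ct"
            )
    return wide.reset_index()


def summarize_expression(
    ct_table: pd.DataFrame,
    method: str = "livak",
    calibrator: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Per-condition relative expression of target vs reference gene.

    For every genotype × endophyte × salinity condition, each biological
    replicate's ratio is computed against the *replicate-mean* Ct of that
    genotype's calibrator condition (default: same genotype, E−, 0 mM);
    the table reports the mean ratio, its SD over biological replicates,
    n, and log2 of the mean ratio.

    Parameters
    ----------
    ct_table
        Long table with columns genotype, endophyte, nacl_mM, bio_rep,
        gene ∈ {target, reference}, ct, efficiency.
    method
        ``"livak"`` (2^−ΔΔCt) or ``"pfaffl"`` (efficiency-corrected).
    calibrator
        Column → value mapping selecting the calibrator condition within
        each genotype.

    Raises
    ------
    MissingCalibratorError
        If any genotype lacks the calibrator condition.
    """
    if method not in ("livak", "pfaffl"):
        raise ValueError(f"method must be 'livak' or 'pfaffl', got {method!r}")
    rule = dict(DEFAULT_CALIBRATOR if calibrator is None else calibrator)
    wide = _pivot_ct(ct_table)

    counts = wide.groupby(_CONDITION_COLS, sort=False).size()
    if (counts < 2).any():
        low = counts[counts < 2].index.tolist()
        raise IncompletePairError(f"conditions with < 2 biological replicates: {low}")

    results = []
    for genotype, gdf in wide.groupby("genotype", sort=False):
        mask = np.ones(len(gdf), dtype=bool)
        for col, val in rule.items():
            mask &= (gdf[col] == val).to_numpy()
        cal = gdf[mask]
        if cal.empty:
            raise MissingCalibratorError(
                f"calibrator condition {rule} absent for genotype {genotype!r}"
            )
        cal_ct_t = float(cal[("ct", "target")].mean())
        cal_ct_r = float(cal[("ct", "reference")].mean())
        for key, cdf in gdf.groupby(["endophyte", "nacl_mM"], sort=False):
            ct_t = cdf[("ct", "target")].to_numpy(float)
            ct_r = cdf[("ct", "reference")].to_numpy(float)
            if method == "livak":
                ratios = 2.0 ** (-((ct_t - ct_r) - (cal_ct_t - cal_ct_r)))
            else:
                e_t = cdf[("efficiency", "target")].to_numpy(float)
                e_r = cdf[("efficiency", "reference")].to_numpy(float)
                ratios = e_t ** (cal_ct_t - ct_t) / e_r ** (cal_ct_r - ct_r)
            mean = float(np.mean(ratios))
            results.append(
                {
                    "genotype": genotype,
                    "endophyte": key[0],
                    "nacl_mM": key[1],
                    "method": method,
                    "ratio": mean,
                    "log2_ratio": float(np.log2(mean)),
                    "sd": float(np.std(ratios, ddof=1)),
                    "n": int(len(ratios)),
                }
            )
    return pd.DataFrame(results)
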