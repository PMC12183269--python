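"""Latitudinal trend inference per endophyte × salinity group.

Each genotype originates from one latitude, so latitude effects can only be
estimated at the genotype level: slopes are ordinary least squares fits on
genotype-level means (one point per genotype), and inference on E+ vs E−
slope differences uses a permutation test that reshuffles endophyte labels
*within* genotypes, respecting the clustering of plants in genotypes.

Provided:

* :func:`fit_latitude_slope` — OLS slope/intercept with a two-sided t test
  of slope = 0 and a Filliben probability-plot residual-normality flag.
* :func:`compare_slopes` — all pairwise slope contrasts among the six
  endophyte × salinity groups, Holm-adjusted, with a compact letter display.
* :func:`permutation_slope_test` — cluster-respecting permutation p-value
  for the E+/E− slope difference within one salinity level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientGradientError, MixedResponseError

__all__ = [
    "SlopeFit",
    "PermutationResult",
    "fit_latitude_slope",
    "fit_group_slopes",
    "compare_slopes",
    "compact_letters",
    "permutation_slope_test",
    "residual_normality",
    "FILLIBEN_CRITICAL",
]

#: Default critical value for the Filliben probability-plot correlation
#: (approximately the 5% point for n = 5); below it residuals are flagged.
FILLIBEN_CRITICAL = 0.879


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of a genotype-mean response against latitude of origin."""

    response: str
    endophyte: str
    nacl_mM: float
    slope: float           # per degree latitude
    intercept: float
    stderr: float
    tstat: float
    pvalue: float
    n: int                 # genotype-level points
    normality_r: float     # Filliben correlation of the residuals
    normality_flag: bool   # True = residuals look non-normal


@dataclass(frozen=True)
class PermutationResult:
    observed: float        # E+ slope minus E− slope
    p_value: float
    n_perm: int


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple linear regression.

    Returns (slope, intercept, stderr, t, p). Degenerate edges: zero
    residual variance gives stderr 0, with p = 1 for a zero slope and p = 0
    for a nonzero one.
    """
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    if n > 2:
        se = float(np.sqrt(ssr / (n - 2) / sxx))
    else:
        se = np.nan
    if se == 0.0:
        t = 0.0 if slope == 0.0 else np.inf * np.sign(slope)
        p = 1.0 if slope == 0.0 else 0.0
    elif np.isnan(se):
        t, p = np.nan, np.nan
    else:
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return slope, intercept, se, float(t), p


def residual_normality(residuals, critical: float = FILLIBEN_CRITICAL) -> tuple[float, bool]:
    """Filliben probability-plot correlation coefficient and a flag.

    Correlates the ordered residuals with normal order-statistic medians
    (Filliben's approximation). The flag is True when r falls below the
    critical value, i.e. the residuals deviate from normality. Flag-only:
    this never gates any downstream analysis.
    """
    r_sorted = np.sort(np.asarray(residuals, dtype=float))
    n = len(r_sorted)
    if n < 3 or np.ptp(r_sorted) == 0:
        return 1.0, False
    m = np.empty(n)
    i = np.arange(2, n)  # interior ranks (1-based 2..n-1)
    m[1:-1] = (i - 0.3175) / (n + 0.365)
    m[-1] = 0.5 ** (1.0 / n)
    m[0] = 1.0 - m[-1]
    quantiles = stats.norm.ppf(m)
    r = float(np.corrcoef(r_sorted, quantiles)[0, 1])
    return r, r < critical


def fit_latitude_slope(
    data: pd.DataFrame,
    response: str,
    endophyte: str | None = None,
    nacl_mM: float | None = None,
    normality_critical: float = FILLIBEN_CRITICAL,
) -> SlopeFit:
    """Latitude slope of a response within one endophyte × salinity group.

    ``data`` may be plant-level or group-summary-level; rows are first
    filtered to the group, then averaged to one point per genotype (each
    genotype contributes one latitude), and the slope is the closed-form
    least-squares solution over those points.

    Raises
    ------
    InsufficientGradientError
        With fewer than 3 distinct latitudes after filtering.
    """
    df = data
    if endophyte is not None:
        df = df[df["endophyte"] == endophyte]
    if nacl_mM is not None:
        df = df[df["nacl_mM"] == nacl_mM]
    df = df.dropna(subset=[response])
    by_gen = df.groupby(["genotype", "latitude_deg_s"], sort=True)[response].mean()
    lats = by_gen.index.get_level_values("latitude_deg_s").to_numpy(float)
    if len(np.unique(lats)) < 3:
        raise InsufficientGradientError(
            f"need >= 3 distinct latitudes for a slope, got {sorted(set(lats))}"
        )
    y = by_gen.to_numpy(float)
    slope, intercept, se, t, p = _ols_line(lats, y)
    resid = y - (intercept + slope * lats)
    r, flag = residual_normality(resid, critical=normality_critical)
    return SlopeFit(
        response=response,
        endophyte=endophyte if endophyte is not None else "all",
        nacl_mM=nacl_mM if nacl_mM is not None else float("nan"),
        slope=slope,
        intercept=intercept,
        stderr=se,
        tstat=t,
        pvalue=p,
        n=len(y),
        normality_r=r,
        normality_flag=flag,
    )


def fit_group_slopes(data: pd.DataFrame, response: str) -> list[SlopeFit]:
    """One :class:`SlopeFit` per endophyte × salinity group, in display order
    (E+ before E−, ascending salinity)."""
    fits = []
    levels = sorted(data["nacl_mM"].unique())
    for endo in ("E+", "E-"):
        for nacl in levels:
            fits.append(fit_latitude_slope(data, response, endophyte=endo, nacl_mM=nacl))
    return fits


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _group_label(fit: SlopeFit) -> str:
    return f"{fit.endophyte}:{int(fit.nacl_mM)}mM"


def compare_slopes(fits: list[SlopeFit], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise slope contrasts among a set of group fits.

    Differences use pooled standard errors ``sqrt(se_a² + se_b²)`` with
    ``n_a + n_b − 4`` degrees of freedom, two-sided p-values, and Holm
    adjustment across the contrasts. Degenerate zero-SE pairs follow the
    same edge rules as the slope t test.

    Raises
    ------
    MixedResponseError
        If the fits were computed on different responses.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to contrast")
    responses = {f.response for f in fits}
    if len(responses) != 1:
        raise MixedResponseError(f"fits mix responses: {sorted(responses)}")
    rows = []
    for a, b in itertools.combinations(fits, 2):
        diff = a.slope - b.slope
        se = float(np.hypot(a.stderr, b.stderr))
        df = a.n + b.n - 4
        if se == 0.0:
            t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "group_a": _group_label(a),
                "group_b": _group_label(b),
                "slope_diff": diff,
                "stderr": se,
                "tstat": float(t),
                "df": df,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = holm_adjust(table["p_raw"].to_numpy())
    table["adjustment"] = "holm"
    table["significant"] = table["p_adj"] < alpha
    return table


def compact_letters(fits: list[SlopeFit], contrasts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Compact letter display from the adjusted-p significance graph.

    Greedy assignment in display order: each group joins every existing
    letter whose members are all non-significantly different from it, and
    opens a new letter if it joins none. Groups sharing a letter are
    therefore pairwise non-significant.
    """
    labels = [_group_label(f) for f in fits]
    sig = {
        frozenset((r["group_a"], r["group_b"])): bool(r["p_adj"] < alpha)
        for _, r in contrasts.iterrows()
    }

    def differ(a: str, b: str) -> bool:
        return sig.get(frozenset((a, b)), False)

    letter_groups: list[list[str]] = []
    for lab in labels:
        joined = False
        for group in letter_groups:
            if not any(differ(lab, member) for member in group):
                group.append(lab)
                joined = True
        if not joined:
            letter_groups.append([lab])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {lab: "" for lab in labels}
    for i, group in enumerate(letter_groups):
        for lab in group:
            assignment[lab] += alphabet[i % len(alphabet)]
    return pd.DataFrame({"group": labels, "letters": [assignment[l] for l in labels]})


# ---------------------------------------------------------------------------
# cluster-respecting permutation inference


def _slope_np(lat: np.ndarray, y: np.ndarray) -> float:
    xc = lat - lat.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def permutation_slope_test(
    plant_table: pd.DataFrame,
    response: str,
    nacl_mM: float,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation p-value for the E+ vs E− latitude-slope difference.

    The statistic is ``slope_E+ − slope_E−`` over genotype-level means of a
    plant-level response within one salinity level. The null distribution is
    built by permuting endophyte labels among the plants of each genotype
    (cluster-respecting: labels never cross genotypes), and the p-value uses
    the add-one estimator ``(1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm)``.

    Rows with a missing response (e.g. seed traits of dead plants) are
    dropped before permutation.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    df = plant_table[plant_table["nacl_mM"] == nacl_mM].dropna(subset=[response])
    if df.empty:
        raise InsufficientGradientError(f"no data at {nacl_mM} mM")
    genotypes, gidx = np.unique(df["genotype"].to_numpy(), return_inverse=True)
    lat_per_g = (
        df.groupby("genotype", sort=True)["latitude_deg_s"].first().to_numpy(float)
    )
    if len(np.unique(lat_per_g)) < 3:
        raise InsufficientGradientError(
            f"need >= 3 distinct latitudes, got {sorted(set(lat_per_g))}"
        )
    values = df[response].to_numpy(float)
    labels = (df["endophyte"] == "E+").to_numpy().astype(np.int64)
    n_groups = len(genotypes)

    counts = np.bincount(gidx * 2 + labels, minlength=2 * n_groups).astype(float)
    if np.any(counts == 0):
        raise InsufficientGradientError(
            "every genotype needs plants of both symbiotic statuses"
        )

    def statistic(lab: np.ndarray) -> float:
        sums = np.bincount(gidx * 2 + lab, weights=values, minlength=2 * n_groups)
        means = sums / counts
        return _slope_np(lat_per_g, means[1::2]) - _slope_np(lat_per_g, means[0::2])

    observed = statistic(labels)
    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(gidx == g) for g in range(n_groups)]
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        for idx in members:
            perm[idx] = labels[idx][rng.permutation(len(idx))]
        if abs(statistic(perm)) >= abs(observed):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(observed=observed, p_value=float(p), n_perm=n_perm)
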