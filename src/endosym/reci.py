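"""Plant Response score and Relative Endophyte Contribution Index (RECI).

The composite Plant Response of a genotype × endophyte × salinity group is a
weighted sum of four trait components, each first scaled to the [0, 1]
interval:

    PR = 0.3·(Fv/Fm) + 0.3·(TSW/10) + 0.3·(survival%/100) + 0.1·(protein/10)

(default weights and divisors; both configurable).  The contribution of the
native endophytes is then the paired difference, in percentage points:

    RECI (%) = (PR_E+ − PR_E−) × 100

Positive RECI means the endophytes improved the composite response; values
near zero mean they contributed little.  PR is computed on group means
because survival exists only at the group level.  Components that scale
outside [0, 1] are flagged, never silently clamped — a divisor
misconfiguration must surface in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, MissingComponentError

__all__ = [
    "ComponentWeights",
    "ComponentDivisors",
    "ScaledComponents",
    "PRScore",
    "RECIResult",
    "scale_components",
    "plant_response",
    "reci",
    "reci_table",
]

COMPONENTS = ("fvfm", "seed", "survival", "protein")


@dataclass(frozen=True)
class ComponentWeights:
    """Weights of the four PR components; defaults sum to 1."""

    fvfm: float = 0.3
    seed: float = 0.3
    survival: float = 0.3
    protein: float = 0.1

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            w = getattr(self, name)
            if not (w >= 0) or not np.isfinite(w):
                raise ConfigurationError(f"weight {name} must be finite and >= 0, got {w}")

    @property
    def total(self) -> float:
        return self.fvfm + self.seed + self.survival + self.protein

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS], dtype=float)


@dataclass(frozen=True)
class ComponentDivisors:
    """Divisors mapping raw group summaries onto the [0, 1] component scale.

    Survival is a percentage (÷100); thousand-seed weight and protein are
    order-10 quantities in their working units (÷10); Fv/Fm is already a
    ratio in (0, 1) (÷1).
    """

    fvfm: float = 1.0
    seed: float = 10.0
    survival: float = 100.0
    protein: float = 10.0

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            d = getattr(self, name)
            if not (d > 0) or not np.isfinite(d):
                raise ConfigurationError(f"divisor {name} must be finite and > 0, got {d}")


@dataclass(frozen=True)
class ScaledComponents:
    """The four dimensionless components of one group, with range flags."""

    fvfm_s: float
    seed_s: float
    survival_s: float
    protein_s: float
    divisors: ComponentDivisors = field(default_factory=ComponentDivisors)
    out_of_range: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.fvfm_s, self.seed_s, self.survival_s, self.protein_s], dtype=float
        )


@dataclass(frozen=True)
class PRScore:
    """Weighted Plant Response of one genotype × endophyte × salinity group."""

    genotype: str
    endophyte: str
    nacl_mM: float
    pr: float
    components: ScaledComponents
    weights: ComponentWeights = field(default_factory=ComponentWeights)


@dataclass(frozen=True)
class RECIResult:
    """Endophyte contribution for one genotype × salinity, in % points."""

    genotype: str
    nacl_mM: float
    pr_eplus: float
    pr_eminus: float
    reci: float


def scale_components(
    summary: dict | pd.Series,
    divisors: ComponentDivisors | None = None,
) -> ScaledComponents:
    """Scale one group-summary row onto the [0, 1] component scale.

    ``summary`` must provide mean_fvfm, tsw_g, survival_pct and protein.
    Results outside [0, 1] are recorded in ``out_of_range`` (and kept as-is).
    """
    div = divisors or ComponentDivisors()
    raw = {
        "fvfm": summary["mean_fvfm"],
        "seed": summary["tsw_g"],
        "survival": summary["survival_pct"],
        "protein": summary["protein"],
    }
    scaled = {}
    flags = []
    for name, value in raw.items():
        v = float(value) / getattr(div, name) if value is not None else np.nan
        scaled[name] = v
        if np.isfinite(v) and not (0.0 <= v <= 1.0):
            flags.append(name)
    return ScaledComponents(
        fvfm_s=scaled["fvfm"],
        seed_s=scaled["seed"],
        survival_s=scaled["survival"],
        protein_s=scaled["protein"],
        divisors=div,
        out_of_range=tuple(flags),
    )


def plant_response(
    components: ScaledComponents,
    weights: ComponentWeights | None = None,
    genotype: str = "",
    endophyte: str = "",
    nacl_mM: float = float("nan"),
) -> PRScore:
    """Weighted Plant Response: the exact dot product weights · components.

    Raises
    ------
    MissingComponentError
        If any component is NaN — missing trait data is never imputed.
    """
    w = weights or ComponentWeights()
    vec = components.as_array()
    if not np.all(np.isfinite(vec)):
        missing = [c for c, v in zip(COMPONENTS, vec) if not np.isfinite(v)]
        raise MissingComponentError(
            f"missing components {missing} for {genotype or '<group>'}"
            f" {endophyte} {nacl_mM} mM"
        )
    # pairwise summation: with the default weights this makes unit components
    # sum to exactly 1.0 ((0.3 + 0.3) + (0.3 + 0.1) is exact in binary64)
    terms = w.as_array() * vec
    pr = float((terms[0] + terms[1]) + (terms[2] + terms[3]))
    return PRScore(genotype, endophyte, nacl_mM, pr, components, w)


def reci(pr_eplus: PRScore, pr_eminus: PRScore) -> RECIResult:
    """RECI (%) = (PR_E+ − PR_E−) × 100 for one genotype × salinity.

    Antisymmetric under swapping the two symbiotic statuses.

    Raises
    ------
    AlignmentError
        If the two scores do not share genotype and salinity.
    """
    same_nacl = (pr_eplus.nacl_mM == pr_eminus.nacl_mM) or (
        np.isnan(pr_eplus.nacl_mM) and np.isnan(pr_eminus.nacl_mM)
    )
    if pr_eplus.genotype != pr_eminus.genotype or not same_nacl:
        raise AlignmentError(
            f"cannot difference {pr_eplus.genotype}@{pr_eplus.nacl_mM} "
            f"against {pr_eminus.genotype}@{pr_eminus.nacl_mM}"
        )
    return RECIResult(
        genotype=pr_eplus.genotype,
        nacl_mM=pr_eplus.nacl_mM,
        pr_eplus=pr_eplus.pr,
        pr_eminus=pr_eminus.pr,
        reci=(pr_eplus.pr - pr_eminus.pr) * 100.0,
    )


def reci_table(
    summaries: pd.DataFrame,
    weights: ComponentWeights | None = None,
    divisors: ComponentDivisors | None = None,
    extinct_yield_is_zero: bool = True,
) -> pd.DataFrame:
    """RECI for every genotype × salinity cell of a group-summary table.

    Parameters
    ----------
    summaries
        Output of :func:`endosym.traits.summarize_plants` (one row per
        genotype × endophyte × salinity).
    extinct_yield_is_zero
        A group with zero survivors yields no seed, so its seed and protein
        summaries are NaN.  When True (default) those two components are set
        to 0 for such groups — no yield, rather than unknown yield — and the
        row is flagged; when False the NaN propagates to a
        :class:`MissingComponentError`.

    Returns
    -------
    DataFrame
        genotype, latitude_deg_s, nacl_mM, pr_eplus, pr_eminus, reci_pct,
        flags (semicolon-joined out-of-range / extinct markers).
    """
    w = weights or ComponentWeights()
    div = divisors or ComponentDivisors()
    rows = []
    for (genotype, nacl), g in summaries.groupby(["genotype", "nacl_mM"], sort=True):
        scores = {}
        flags: list[str] = []
        for endo in ("E+", "E-"):
            sub = g[g["endophyte"] == endo]
            if len(sub) != 1:
                raise AlignmentError(
                    f"expected exactly one {endo} summary row for "
                    f"{genotype} @ {nacl} mM, found {len(sub)}"
                )
            row = sub.iloc[0]
            comp = scale_components(row, div)
            if extinct_yield_is_zero and row["n_alive"] == 0:
                comp = ScaledComponents(
                    fvfm_s=comp.fvfm_s,
                    seed_s=0.0,
                    survival_s=comp.survival_s,
                    protein_s=0.0,
                    divisors=div,
                    out_of_range=comp.out_of_range,
                )
                flags.append(f"extinct:{endo}")
            flags.extend(f"out_of_range:{endo}:{c}" for c in comp.out_of_range)
            scores[endo] = plant_response(comp, w, str(genotype), endo, float(nacl))
        res = reci(scores["E+"], scores["E-"])
        rows.append(
            {
                "genotype": genotype,
                "latitude_deg_s": float(g["latitude_deg_s"].iloc[0]),
                "nacl_mM": float(nacl),
                "pr_eplus": res.pr_eplus,
                "pr_eminus": res.pr_eminus,
                "reci_pct": res.reci,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows).sort_values(["genotype", "nacl_mM"]).reset_index(drop=True)


def plot_reci(reci_df: pd.DataFrame, path) -> None:
    """Grouped bar chart of RECI (%) per genotype, one bar per NaCl level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genotypes = list(dict.fromkeys(reci_df["genotype"]))
    levels = sorted(reci_df["nacl_mM"].unique())
    x = np.arange(len(genotypes), dtype=float)
    width = 0.8 / max(len(levels), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, lev in enumerate(levels):
        sub = reci_df[reci_df["nacl_mM"] == lev].set_index("genotype")
        vals = [sub.loc[g, "reci_pct"] if g in sub.index else np.nan for g in genotypes]
        ax.bar(x + (i - (len(levels) - 1) / 2) * width, vals, width,
               label=f"{int(lev)} mM NaCl")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x, genotypes)
    ax.set_ylabel("RECI (%)")
    ax.set_xlabel("Genotype")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
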