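"""End-to-end orchestration: simulate → quantify → summarize → score → trend.

A run is described by a :class:`RunConfig` (validated against a versioned
schema; unknown keys are rejected), executed stage by stage with every
intermediate table persisted as CSV, and closed with a markdown report and a
provenance manifest.  Rerunning the same config and seed reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .errors import InsufficientGradientError, PipelineError
from .qpcr import summarize_expression
from .reci import ComponentDivisors, ComponentWeights, plot_reci, reci_table
from .simulate import (
    EffectModel,
    Genotype,
    StudyDesign,
    simulate_dataset,
    write_dataset,
)
from .traits import summarize_plants
from .trends import compact_letters, compare_slopes, fit_group_slopes, permutation_slope_test

__all__ = ["RunConfig", "run_all", "load_config", "RESPONSE_COLUMNS"]

#: User-facing response names → group-summary columns.
RESPONSE_COLUMNS = {
    "fvfm": "mean_fvfm",
    "survival": "survival_pct",
    "tsw": "tsw_g",
    "protein": "protein",
    "nhx1": "log2_ratio",
}

#: Plant-level columns backing the permutation test (nhx1 has no plant-level
#: record: expression is measured on pooled biological replicates).
PLANT_LEVEL_COLUMNS = {
    "fvfm": "fvfm",
    "survival": "alive",
    "tsw": "tsw_g",
    "protein": "protein",
}


class GenotypeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    latitude_deg_s: float
    ecotype: str


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    genotypes: list[GenotypeConfig] | None = None
    salinity_levels: list[float] = [0.0, 200.0, 400.0]
    replicates_per_cell: int = 12
    qpcr_replicates: int = 5


class ScoreConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weights: dict[str, float] = {"fvfm": 0.3, "seed": 0.3, "survival": 0.3, "protein": 0.1}
    divisors: dict[str, float] = {"fvfm": 1.0, "seed": 10.0, "survival": 100.0, "protein": 10.0}


class TrendConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 499
    alpha: float = 0.05
    adjustment: Literal["holm"] = "holm"
    responses: list[str] = ["fvfm", "survival", "tsw", "protein", "nhx1"]

    @field_validator("responses")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(RESPONSE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown responses: {sorted(unknown)}")
        return v


class RunConfig(BaseModel):
    """Versioned configuration of a full analysis run."""

    model_config = ConfigDict(extra="forbid")
    schema_version: Literal["1.0"] = "1.0"
    seed: int = 0
    design: DesignConfig = Field(default_factory=DesignConfig)
    effects: dict[str, float] = {}   # overrides of EffectModel fields
    null_effects: bool = False       # start from the zero-benefit model
    score: ScoreConfig = Field(default_factory=ScoreConfig)
    trend: TrendConfig = Field(default_factory=TrendConfig)
    qpcr_method: Literal["livak", "pfaffl"] = "livak"
    make_figure: bool = True

    def study_design(self) -> StudyDesign:
        gens = (
            tuple(Genotype(g.name, g.latitude_deg_s, g.ecotype) for g in self.design.genotypes)
            if self.design.genotypes
            else None
        )
        kwargs = dict(
            salinity_levels=tuple(self.design.salinity_levels),
            replicates_per_cell=self.design.replicates_per_cell,
            qpcr_replicates=self.design.qpcr_replicates,
            seed=self.seed,
        )
        if gens is not None:
            kwargs["genotypes"] = gens
        return StudyDesign(**kwargs)

    def effect_model(self) -> EffectModel:
        base = EffectModel.null() if self.null_effects else EffectModel()
        overrides = dict(self.effects)
        if "ct_range" in overrides or "bradford_curve" in overrides:
            raise ValueError("tuple-valued effect fields cannot be overridden via config")
        return dataclasses.replace(base, **overrides)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return decorate


def _write_csv(df: pd.DataFrame, path: Path, run_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# endosym run {run_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, tolerating the provenance comment header.

    ``float_precision="round_trip"`` makes CSV round-trips lossless.
    """
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _md_table(df: pd.DataFrame, floatfmt: str = ".4f") -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""

    def fmt(v) -> str:
        if isinstance(v, float):
            return format(v, floatfmt)
        return str(v)

    cols = list(df.columns)
    lines = [
        "| " + " | ".join(map(str, cols)) + " |",
        "|" + "|".join("---" for _ in cols) + "|",
    ]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Stages: simulate (plants + qPCR plate) → quantify (relative expression)
    → summarize (group means) → score (PR and RECI) → trend (slopes,
    contrasts, letters, permutation tests) → report.

    Returns the run directory. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_hash = config.config_hash()

    design = config.study_design()
    effects = config.effect_model()

    @_stage("simulate")
    def s_simulate():
        tables = simulate_dataset(design, effects, seed=config.seed)
        write_dataset(tables, outdir, design=design, effects=effects, seed=config.seed)
        return tables

    tables = s_simulate()
    plants, plate = tables["plants"], tables["qpcr"]

    @_stage("quantify")
    def s_quantify():
        expr = summarize_expression(plate, method=config.qpcr_method)
        _write_csv(expr, outdir / "expression.csv", run_hash)
        return expr

    expression = s_quantify()

    @_stage("summarize")
    def s_summarize():
        summary = summarize_plants(plants)
        _write_csv(summary, outdir / "group_summary.csv", run_hash)
        return summary

    summary = s_summarize()

    @_stage("score")
    def s_score():
        weights = ComponentWeights(**config.score.weights)
        divisors = ComponentDivisors(**config.score.divisors)
        table = reci_table(summary, weights, divisors)
        _write_csv(table, outdir / "reci.csv", run_hash)
        if config.make_figure:
            plot_reci(table, outdir / "reci.png")
        return table

    reci_df = s_score()

    @_stage("trend")
    def s_trend():
        # plant-level derived columns for permutation inference
        pl = plants.copy()
        pl["fvfm"] = (pl["fm"] - pl["f0"]) / pl["fm"]
        seed_cols = [c for c in pl.columns if c.startswith("seed_mass_g_")]
        pl["tsw_g"] = 10.0 * pl[seed_cols].mean(axis=1)
        from .traits import DEFAULT_BRADFORD_STANDARDS, bradford_protein

        abs_cols = [c for c in pl.columns if c.startswith("abs595_")]
        mean_abs = pl[abs_cols].mean(axis=1)
        fit = bradford_protein(DEFAULT_BRADFORD_STANDARDS, mean_abs.fillna(0.0).to_numpy())
        pl["protein"] = fit.concentrations
        pl.loc[mean_abs.isna(), "protein"] = float("nan")

        trend_source = {
            **{r: summary for r in ("fvfm", "survival", "tsw", "protein")},
            "nhx1": expression.merge(
                summary[["genotype", "latitude_deg_s"]].drop_duplicates(),
                on="genotype",
            ),
        }
        slope_rows, contrast_frames, letter_frames, perm_rows = [], [], [], []
        for resp in config.trend.responses:
            col = RESPONSE_COLUMNS[resp]
            fits = fit_group_slopes(trend_source[resp], col)
            for f in fits:
                row = dataclasses.asdict(f)
                row["response"] = resp
                slope_rows.append(row)
            contr = compare_slopes(fits, alpha=config.trend.alpha)
            contr.insert(0, "response", resp)
            contrast_frames.append(contr)
            letters = compact_letters(fits, contr, alpha=config.trend.alpha)
            letters.insert(0, "response", resp)
            letter_frames.append(letters)
            if resp in PLANT_LEVEL_COLUMNS:
                for nacl in sorted(pl["nacl_mM"].unique()):
                    row = {"response": resp, "nacl_mM": nacl,
                           "slope_diff_eplus_minus_eminus": float("nan"),
                           "p_value": float("nan"), "n_perm": config.trend.n_perm,
                           "status": "ok"}
                    try:
                        res = permutation_slope_test(
                            pl,
                            PLANT_LEVEL_COLUMNS[resp],
                            nacl_mM=nacl,
                            n_perm=config.trend.n_perm,
                            seed=config.seed + int(nacl),
                        )
                    except InsufficientGradientError as exc:
                        # e.g. every plant of a genotype × status cell died at
                        # severe stress, so a yield trait has no data there
                        row["status"] = f"skipped: {exc}"
                    else:
                        row["slope_diff_eplus_minus_eminus"] = res.observed
                        row["p_value"] = res.p_value
                    perm_rows.append(row)
        slopes = pd.DataFrame(slope_rows)
        slopes = slopes[["response"] + [c for c in slopes.columns if c != "response"]]
        contrasts = pd.concat(contrast_frames, ignore_index=True)
        letters = pd.concat(letter_frames, ignore_index=True)
        perms = pd.DataFrame(perm_rows)
        _write_csv(slopes, outdir / "slopes.csv", run_hash)
        _write_csv(contrasts, outdir / "contrasts.csv", run_hash)
        _write_csv(letters, outdir / "letters.csv", run_hash)
        _write_csv(perms, outdir / "permutation_tests.csv", run_hash)
        return slopes, contrasts, letters, perms

    slopes, contrasts, letters, perms = s_trend()

    @_stage("report")
    def s_report():
        lines = [
            "# endosym run report",
            "",
            f"- config hash: `{run_hash}`",
            f"- seed: {config.seed}",
            f"- endosym version: {__version__}",
            f"- plants simulated: {len(plants)}",
            "",
            "## Relative Endophyte Contribution Index (%)",
            "",
            _md_table(reci_df, ".3f"),
            "",
            "## Latitude slopes per endophyte × salinity group",
            "",
            _md_table(slopes),
            "",
            "## Slope contrast letters (groups sharing a letter do not differ)",
            "",
            _md_table(letters),
            "",
            "## Cluster permutation tests of the E+/E− slope difference",
            "",
            _md_table(perms),
            "",
        ]
        (outdir / "report.md").write_text("\n".join(lines))
        provenance = {
            "config": config.model_dump(mode="json"),
            "config_hash": run_hash,
            "endosym_version": __version__,
        }
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    s_report()
    return outdir
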