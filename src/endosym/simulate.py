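"""Synthetic factorial greenhouse experiment generator.

Emulates a salinity × endophyte × genotype experiment on quinoa: five
genotypes originating along a latitudinal gradient (19–39 °S, Salares and
Lowlands ecotypes), with (E+) and without (E−) their native fungal
endophytes, watered at 0 / 200 / 400 mM NaCl, twelve replicate plants per
cell (360 plants total), plus a qPCR plate quantifying the vacuolar
Na+/H+ antiporter gene *CqNHX1* against the *EF-1α* housekeeping gene with
five biological replicates per condition.

The effect model encodes the habitat-adapted-symbiosis hypothesis the
experiment tests: the endophyte benefit to *stress tolerance* traits
(survival, Fv/Fm, NHX1 induction) is largest at the lowest (northern)
latitude and decays southward, while the benefit to *seed quality* traits
(seed mass, protein) grows with latitude.  All endophyte effects scale with
salinity, so under non-saline control conditions E+ and E− are exchangeable
in expectation (no symbiosis cost without stress).

Noise families respect each trait's support: Fv/Fm is logit-normal on
(0, 1), seed mass and protein are lognormal (strictly positive), Ct values
are Gaussian within a plausible cycle range, and survival is Bernoulli on a
logistic scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InvalidDesignError

__all__ = [
    "Genotype",
    "StudyDesign",
    "EffectModel",
    "DEFAULT_GENOTYPES",
    "PRIMERS",
    "DEFAULT_BRADFORD_CURVE",
    "generate_design",
    "simulate_traits",
    "simulate_qpcr_plate",
    "write_dataset",
]

#: Published qRT-PCR primer pairs (5'→3'): target CqNHX1 and reference EF-1α.
PRIMERS: dict[str, dict[str, str]] = {
    "CqNHX1": {
        "sense": "GCACTTCTGTTGCTGTGAGTTCCA",
        "antisense": "TGTGCCCTGACCTCGTAAACTGAT",
    },
    "EF-1a": {
        "sense": "GTACGCATGGGTGCTTGACAAACTC",
        "antisense": "ATCAGCCTGGGAGGTACCAGTAAT",
    },
}

#: Linear Bradford calibration used to turn simulated true protein
#: concentrations into A595 readings: A = intercept + slope * C.
DEFAULT_BRADFORD_CURVE: tuple[float, float] = (0.05, 0.08)

N_SEED_SAMPLES = 8   # 100-seed samples weighed per surviving plant
N_ABS_READINGS = 3   # A595 readings per protein extract


@dataclass(frozen=True)
class Genotype:
    """A quinoa genotype and its geographic origin."""

    name: str
    latitude_deg_s: float
    ecotype: str


DEFAULT_GENOTYPES: tuple[Genotype, ...] = (
    Genotype("Pandela", 19.0, "Salares"),
    Genotype("Paihuano", 29.0, "Salares"),
    Genotype("PRP", 34.0, "Lowlands"),
    Genotype("UdeC9", 35.0, "Lowlands"),
    Genotype("BO78", 39.0, "Lowlands"),
)

ENDOPHYTE_LEVELS = ("E+", "E-")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the greenhouse experiment.

    Defaults reproduce the full design: 5 genotypes × 2 symbiotic statuses ×
    3 NaCl levels × 12 replicate plants = 360 plants, and 5 qPCR biological
    replicates per genotype × condition.
    """

    genotypes: tuple[Genotype, ...] = DEFAULT_GENOTYPES
    salinity_levels: tuple[float, ...] = (0.0, 200.0, 400.0)
    replicates_per_cell: int = 12
    qpcr_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell <= 0:
            raise InvalidDesignError(
                f"replicates_per_cell must be positive, got {self.replicates_per_cell}"
            )
        if not self.genotypes:
            raise InvalidDesignError("at least one genotype is required")
        if not self.salinity_levels:
            raise InvalidDesignError("at least one salinity level is required")
        names = [g.name for g in self.genotypes]
        if len(set(names)) != len(names):
            raise InvalidDesignError(f"duplicate genotype names: {names}")

    @property
    def n_plants(self) -> int:
        return (
            len(self.genotypes)
            * len(ENDOPHYTE_LEVELS)
            * len(self.salinity_levels)
            * self.replicates_per_cell
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genotypes"] = [dataclasses.asdict(g) for g in self.genotypes]
        return d


# ln(15) puts E+ survival at exactly 5/6 when the E− logit is ln(1/3);
# -(3 + ln 3) puts E− survival at exactly 1/4 at 400 mM from a 0-mM base of 3.
_SURV_SALT = -(3.0 + math.log(3.0))
_SURV_BENEFIT = math.log(15.0)


@dataclass(frozen=True)
class EffectModel:
    """Trait baselines, endophyte effect functions, and noise magnitudes.

    Endophyte effects enter as ``benefit × s × shape(latitude)`` where
    ``s = NaCl / salt_ref`` is the relative salinity dose, so every effect
    vanishes at 0 mM (the neutrality property).  ``shape`` is a southward
    decay for tolerance traits and a southward ramp for seed-quality traits,
    both anchored at ``lat_ref`` (the northernmost origin).

    The default calibration makes expected survival at 400 mM for the
    19 °S genotype exactly 5/6 (E+) and 1/4 (E−) — the 83.3 % vs 25 %
    contrast of the severe-stress condition.
    """

    # geography of the effect gradient
    lat_ref: float = 19.0        # °S, northernmost origin
    decay_per_deg: float = 0.045  # tolerance benefit lost per degree south
    ramp_span_deg: float = 20.0   # degrees over which seed benefit reaches 1
    salt_ref: float = 400.0       # mM, dose at which s = 1

    # survival (logistic scale)
    survival_logit_base: float = 3.0
    survival_logit_salt: float = _SURV_SALT
    survival_logit_benefit: float = _SURV_BENEFIT

    # Fv/Fm (logit scale; base expit(1.586) ≈ 0.830, the healthy-leaf value)
    fvfm_logit_base: float = 1.586
    fvfm_logit_salt: float = -0.9
    fvfm_logit_benefit: float = 0.6
    fvfm_logit_sd: float = 0.15

    # per-100-seed mass (log grams)
    seed_mass_base_g: float = 0.30
    seed_log_salt: float = -0.35
    seed_log_benefit: float = 0.15
    seed_log_sd: float = 0.08
    seed_sample_log_sd: float = 0.03  # within-plant, across the 8 samples

    # soluble seed protein (log scale; concentration units matched to the
    # Bradford standards, order 10 so the downstream ÷10 scaling lands in [0,1])
    protein_base: float = 7.0
    protein_log_salt: float = -0.15
    protein_log_benefit: float = 0.08
    protein_log_sd: float = 0.08

    # raw fluorescence scale (arbitrary fluorometer units)
    fm_mean: float = 30000.0
    fm_sd: float = 2000.0

    # qPCR: reference gene condition-invariant; target induced by salt,
    # more strongly in E+ plants at northern latitudes
    ct_reference_mean: float = 20.0
    ct_target_base: float = 24.0
    log2fc_salt: float = 1.5
    log2fc_benefit: float = 1.0
    ct_sd: float = 0.2
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0
    ct_range: tuple[float, float] = (10.0, 40.0)

    # Bradford read-out
    bradford_curve: tuple[float, float] = DEFAULT_BRADFORD_CURVE
    absorbance_sd: float = 0.005
    dilution_factor: float = 1.0

    # nuisance structure
    block_sd: float = 0.0  # additive latent block effect (plants were rotated)
    neutrality_bound: float = 1e-9

    def __post_init__(self) -> None:
        sds = {
            "fvfm_logit_sd": self.fvfm_logit_sd,
            "seed_log_sd": self.seed_log_sd,
            "seed_sample_log_sd": self.seed_sample_log_sd,
            "protein_log_sd": self.protein_log_sd,
            "ct_sd": self.ct_sd,
            "fm_sd": self.fm_sd,
            "absorbance_sd": self.absorbance_sd,
            "block_sd": self.block_sd,
        }
        for name, value in sds.items():
            if not (value >= 0.0) or not np.isfinite(value):
                raise ConfigurationError(f"{name} must be finite and >= 0, got {value}")
        for name, value in (
            ("seed_mass_base_g", self.seed_mass_base_g),
            ("protein_base", self.protein_base),
            ("fm_mean", self.fm_mean),
            ("salt_ref", self.salt_ref),
        ):
            if not (value > 0.0) or not np.isfinite(value):
                raise ConfigurationError(f"{name} must be finite and > 0, got {value}")
        for name, value in (
            ("efficiency_target", self.efficiency_target),
            ("efficiency_reference", self.efficiency_reference),
        ):
            if not (1.0 <= value <= 2.0):
                raise ConfigurationError(
                    f"{name} must lie in [1, 2] (amplification factor/cycle), got {value}"
                )
        lo, hi = self.ct_range
        if not (0.0 < lo < hi):
            raise ConfigurationError(f"ct_range must satisfy 0 < low < high, got {self.ct_range}")
        if not (lo <= self.ct_reference_mean <= hi and lo <= self.ct_target_base <= hi):
            raise ConfigurationError("mean Ct values must lie inside ct_range")
        # Fv/Fm means must stay inside (0, 1): the logit parameterisation
        # guarantees this for finite parameters; reject non-finite ones.
        for name in ("fvfm_logit_base", "fvfm_logit_salt", "fvfm_logit_benefit"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite (keeps E[Fv/Fm] in (0,1))")

    @classmethod
    def null(cls, **overrides) -> "EffectModel":
        """Effect model with every endophyte effect set to zero (E+ ≡ E−)."""
        zeros = dict(
            survival_logit_benefit=0.0,
            fvfm_logit_benefit=0.0,
            seed_log_benefit=0.0,
            protein_log_benefit=0.0,
            log2fc_benefit=0.0,
        )
        zeros.update(overrides)
        return cls(**zeros)

    # -- effect geometry -------------------------------------------------
    def dose(self, nacl_mM) -> np.ndarray:
        return np.asarray(nacl_mM, dtype=float) / self.salt_ref

    def tolerance_shape(self, latitude) -> np.ndarray:
        """Southward decay of the stress-tolerance benefit (1 at lat_ref)."""
        lat = np.asarray(latitude, dtype=float)
        return np.clip(1.0 - self.decay_per_deg * (lat - self.lat_ref), 0.0, None)

    def seed_shape(self, latitude) -> np.ndarray:
        """Southward ramp of the seed-quality benefit (0 at lat_ref)."""
        lat = np.asarray(latitude, dtype=float)
        return np.clip((lat - self.lat_ref) / self.ramp_span_deg, 0.0, None)

    def neutrality_gap(self, latitude: float = 19.0) -> dict[str, float]:
        """Expected |E+ − E−| latent-scale gap per trait at 0 mM NaCl.

        Structurally zero here because every benefit term is multiplied by the
        salinity dose; reported so a reparameterised model can be audited
        against ``neutrality_bound``.
        """
        s = self.dose(0.0)
        shape_t = self.tolerance_shape(latitude)
        shape_s = self.seed_shape(latitude)
        return {
            "survival": float(abs(self.survival_logit_benefit * s * shape_t)),
            "fvfm": float(abs(self.fvfm_logit_benefit * s * shape_t)),
            "seed": float(abs(self.seed_log_benefit * s * shape_s)),
            "protein": float(abs(self.protein_log_benefit * s * shape_s)),
            "nhx1": float(abs(self.log2fc_benefit * s * shape_t)),
        }

    def survival_probability(self, latitude, nacl_mM, endophyte) -> np.ndarray:
        """Expected survival probability for a condition (vectorised)."""
        s = self.dose(nacl_mM)
        eplus = (np.asarray(endophyte) == "E+").astype(float)
        logit = (
            self.survival_logit_base
            + self.survival_logit_salt * s
            + self.survival_logit_benefit * s * self.tolerance_shape(latitude) * eplus
        )
        return expit(logit)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ct_range"] = list(self.ct_range)
        d["bradford_curve"] = list(self.bradford_curve)
        return d


def _check_neutrality(effects: EffectModel, design: StudyDesign) -> None:
    for g in design.genotypes:
        gaps = effects.neutrality_gap(g.latitude_deg_s)
        for trait, gap in gaps.items():
            if gap > effects.neutrality_bound:
                raise ConfigurationError(
                    f"expected E+/E− {trait} gap at 0 mM is {gap:.3g} > "
                    f"neutrality_bound {effects.neutrality_bound:.3g}"
                )


def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Expand a :class:`StudyDesign` into one row per experimental plant.

    Block labels (1..replicates) are assigned by randomised permutation
    within each genotype × endophyte × salinity cell under the design seed,
    mimicking a completely randomised block layout.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0,)))
    rows = []
    plant = 0
    for g in design.genotypes:
        for endo in ENDOPHYTE_LEVELS:
            for nacl in design.salinity_levels:
                blocks = rng.permutation(design.replicates_per_cell) + 1
                for r in range(design.replicates_per_cell):
                    plant += 1
                    rows.append(
                        {
                            "plant_id": f"P{plant:04d}",
                            "genotype": g.name,
                            "latitude_deg_s": g.latitude_deg_s,
                            "ecotype": g.ecotype,
                            "endophyte": endo,
                            "nacl_mM": float(nacl),
                            "block": int(blocks[r]),
                        }
                    )
    table = pd.DataFrame(rows)
    assert len(table) == design.n_plants
    return table


def simulate_traits(
    design_table: pd.DataFrame,
    effects: EffectModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-plant trait measurements for every row of a design table.

    Adds raw fluorescence (fm, f0), the survival flag, eight 100-seed sample
    masses, and three Bradford A595 readings.  Dead plants keep their
    fluorescence record (measured before death) but carry no seed or protein
    measurements, so downstream yield summaries must average over survivors.
    """
    if effects is None:
        effects = EffectModel()
    design = design_table.reset_index(drop=True)
    n = len(design)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    lat = design["latitude_deg_s"].to_numpy(float)
    s = effects.dose(design["nacl_mM"].to_numpy(float))
    eplus = (design["endophyte"] == "E+").to_numpy().astype(float)
    shape_tol = effects.tolerance_shape(lat)
    shape_seed = effects.seed_shape(lat)

    # latent block effects shared across traits within a block
    blocks = design["block"].to_numpy()
    uniq = np.unique(blocks)
    block_eff = dict(zip(uniq, rng.normal(0.0, effects.block_sd, len(uniq))))
    b = np.array([block_eff[x] for x in blocks])

    # survival
    logit_surv = (
        effects.survival_logit_base
        + effects.survival_logit_salt * s
        + effects.survival_logit_benefit * s * shape_tol * eplus
    )
    p_surv = expit(logit_surv)
    alive = rng.random(n) < p_surv

    # Fv/Fm via logit-normal, then decompose into Fm and F0
    mu_fvfm = (
        effects.fvfm_logit_base
        + effects.fvfm_logit_salt * s
        + effects.fvfm_logit_benefit * s * shape_tol * eplus
        + b
    )
    fvfm = expit(mu_fvfm + rng.normal(0.0, effects.fvfm_logit_sd, n))
    fm = np.abs(rng.normal(effects.fm_mean, effects.fm_sd, n))
    fm = np.maximum(fm, 1e-6)
    f0 = fm * (1.0 - fvfm)

    # seed mass: plant-level lognormal mean, 8 lognormal samples around it
    log_mu_seed = (
        np.log(effects.seed_mass_base_g)
        + effects.seed_log_salt * s
        + effects.seed_log_benefit * s * shape_seed * eplus
        + b
    )
    plant_log_seed = log_mu_seed + rng.normal(0.0, effects.seed_log_sd, n)
    seed_masses = np.exp(
        plant_log_seed[:, None]
        + rng.normal(0.0, effects.seed_sample_log_sd, (n, N_SEED_SAMPLES))
    )

    # protein: lognormal true concentration read out through the Bradford line
    log_mu_prot = (
        np.log(effects.protein_base)
        + effects.protein_log_salt * s
        + effects.protein_log_benefit * s * shape_seed * eplus
        + b
    )
    protein_true = np.exp(log_mu_prot + rng.normal(0.0, effects.protein_log_sd, n))
    a0, b1 = effects.bradford_curve
    absorb = (
        a0
        + b1 * (protein_true / effects.dilution_factor)[:, None]
        + rng.normal(0.0, effects.absorbance_sd, (n, N_ABS_READINGS))
    )

    out = design.copy()
    out["fm"] = fm
    out["f0"] = f0
    out["alive"] = alive.astype(int)
    dead = ~alive
    for j in range(N_SEED_SAMPLES):
        col = seed_masses[:, j].copy()
        col[dead] = np.nan
        out[f"seed_mass_g_{j + 1}"] = col
    for j in range(N_ABS_READINGS):
        col = absorb[:, j].copy()
        col[dead] = np.nan
        out[f"abs595_{j + 1}"] = col
    return out


def simulate_qpcr_plate(
    design_table: pd.DataFrame,
    effects: EffectModel | None = None,
    seed: int = 0,
    qpcr_replicates: int = 5,
) -> pd.DataFrame:
    """Simulate Ct values for CqNHX1 (target) and EF-1α (reference).

    One plate row per genotype × endophyte × salinity condition × biological
    replicate × gene.  The reference gene's Ct distribution is
    condition-invariant (housekeeping assumption); the target Ct shifts by
    ``−log2FC / log2(E_target)`` cycles relative to the unstressed E−
    calibrator, so downstream ratio methods recover the configured fold
    change in expectation.  Primer sequences travel in ``DataFrame.attrs``.
    """
    if effects is None:
        effects = EffectModel()
    if qpcr_replicates < 2:
        raise InvalidDesignError(
            f"qpcr_replicates must be >= 2 for replicate SDs, got {qpcr_replicates}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    conditions = (
        design_table[["genotype", "latitude_deg_s", "endophyte", "nacl_mM"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    lo, hi = effects.ct_range
    rows = []
    for _, cond in conditions.iterrows():
        s = float(effects.dose(cond["nacl_mM"]))
        shape = float(effects.tolerance_shape(cond["latitude_deg_s"]))
        eplus = 1.0 if cond["endophyte"] == "E+" else 0.0
        log2fc = effects.log2fc_salt * s + effects.log2fc_benefit * s * shape * eplus
        ct_target_mu = effects.ct_target_base - log2fc / math.log2(effects.efficiency_target)
        for rep in range(1, qpcr_replicates + 1):
            sample_id = f"{cond['genotype']}_{cond['endophyte']}_{int(cond['nacl_mM'])}_r{rep}"
            ct_t = float(np.clip(rng.normal(ct_target_mu, effects.ct_sd), lo, hi))
            ct_r = float(np.clip(rng.normal(effects.ct_reference_mean, effects.ct_sd), lo, hi))
            common = {
                "sample_id": sample_id,
                "genotype": cond["genotype"],
                "latitude_deg_s": cond["latitude_deg_s"],
                "endophyte": cond["endophyte"],
                "nacl_mM": float(cond["nacl_mM"]),
                "bio_rep": rep,
            }
            rows.append({**common, "gene": "target", "ct": ct_t,
                         "efficiency": effects.efficiency_target})
            rows.append({**common, "gene": "reference", "ct": ct_r,
                         "efficiency": effects.efficiency_reference})
    plate = pd.DataFrame(rows)
    plate.attrs["primers"] = PRIMERS
    plate.attrs["target_gene"] = "CqNHX1"
    plate.attrs["reference_gene"] = "EF-1a"
    return plate


def simulate_dataset(
    design: StudyDesign | None = None,
    effects: EffectModel | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Convenience wrapper: design → plants + qPCR plate in one call."""
    if design is None:
        design = StudyDesign()
    if effects is None:
        effects = EffectModel()
    if seed is None:
        seed = design.seed
    _check_neutrality(effects, design)
    table = generate_design(dataclasses.replace(design, seed=seed))
    plants = simulate_traits(table, effects, seed=seed)
    qpcr = simulate_qpcr_plate(table, effects, seed=seed,
                               qpcr_replicates=design.qpcr_replicates)
    return {"plants": plants, "qpcr": qpcr}


def write_dataset(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    design: StudyDesign | None = None,
    effects: EffectModel | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write plants.csv / qpcr.csv plus a manifest.json recording provenance.

    The CSVs round-trip losslessly through :func:`pandas.read_csv` (float
    repr is exact via the default C writer's shortest-repr formatting).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        p = directory / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    manifest = {
        "schema_version": "1.0",
        "seed": seed if seed is not None else (design.seed if design else None),
        "design": design.to_dict() if design else None,
        "effects": effects.to_dict() if effects else None,
        "primers": PRIMERS,
        "tables": {k: v.name for k, v in paths.items()},
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths
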