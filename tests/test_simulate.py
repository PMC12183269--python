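"""Generator: factorial structure, invariants, calibration, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from endosym import (
    EffectModel,
    Genotype,
    StudyDesign,
    generate_design,
    simulate_dataset,
    simulate_qpcr_plate,
    simulate_traits,
    write_dataset,
)
from endosym.errors import ConfigurationError, InvalidDesignError
from endosym.qpcr import summarize_expression

ONE_GENOTYPE = (Genotype("Pandela", 19.0, "Salares"),)
THREE_GENOTYPES = (
    Genotype("Pandela", 19.0, "Salares"),
    Genotype("Paihuano", 29.0, "Salares"),
    Genotype("BO78", 39.0, "Lowlands"),
)


class TestDesign:
    def test_full_factorial_counts(self):
        table = generate_design(StudyDesign())
        assert len(table) == 360
        assert (table.groupby(["genotype", "endophyte"]).size() == 36).all()
        assert (table.groupby(["genotype", "endophyte", "nacl_mM"]).size() == 12).all()

    def test_minimal_factorial(self):
        design = StudyDesign(
            genotypes=ONE_GENOTYPE, salinity_levels=(0.0,), replicates_per_cell=1
        )
        table = generate_design(design)
        assert len(table) == 2
        assert set(table["endophyte"]) == {"E+", "E-"}

    def test_nonpositive_replicates_rejected(self):
        with pytest.raises(InvalidDesignError):
            StudyDesign(replicates_per_cell=0)

    def test_blocks_are_permutations_within_cells(self):
        table = generate_design(StudyDesign(replicates_per_cell=5))
        for _, cell in table.groupby(["genotype", "endophyte", "nacl_mM"]):
            assert sorted(cell["block"]) == [1, 2, 3, 4, 5]

    @given(
        n_geno=st.integers(1, 4),
        n_salt=st.integers(1, 3),
        reps=st.integers(1, 6),
    )
    def test_row_count_is_design_product(self, n_geno, n_salt, reps):
        genotypes = tuple(
            Genotype(f"G{i}", 19.0 + 5 * i, "Salares") for i in range(n_geno)
        )
        design = StudyDesign(
            genotypes=genotypes,
            salinity_levels=tuple(200.0 * j for j in range(n_salt)),
            replicates_per_cell=reps,
        )
        assert len(generate_design(design)) == n_geno * 2 * n_salt * reps

    def test_deterministic_under_seed(self):
        a = generate_design(StudyDesign(seed=11))
        b = generate_design(StudyDesign(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestTraits:
    def test_plant_record_invariants(self, plants):
        assert (plants["f0"] > 0).all()
        assert (plants["fm"] > plants["f0"]).all()
        assert set(plants["alive"].unique()) <= {0, 1}
        seed_cols = [c for c in plants.columns if c.startswith("seed_mass_g_")]
        abs_cols = [c for c in plants.columns if c.startswith("abs595_")]
        alive = plants["alive"] == 1
        assert len(seed_cols) == 8
        assert (plants.loc[alive, seed_cols] > 0).all().all()
        assert plants.loc[~alive, seed_cols].isna().all().all()
        assert plants.loc[~alive, abs_cols].isna().all().all()

    def test_fvfm_values_in_unit_interval(self, plants):
        ratio = (plants["fm"] - plants["f0"]) / plants["fm"]
        assert ((ratio > 0) & (ratio < 1)).all()

    def test_null_effects_zero_noise_groups_identical(self):
        effects = EffectModel.null(
            fvfm_logit_sd=0.0,
            seed_log_sd=0.0,
            seed_sample_log_sd=0.0,
            protein_log_sd=0.0,
            fm_sd=0.0,
            absorbance_sd=0.0,
            survival_logit_base=math.inf,  # everyone survives
        )
        design = StudyDesign(genotypes=THREE_GENOTYPES, replicates_per_cell=3)
        plants = simulate_traits(generate_design(design), effects, seed=3)
        means = plants.groupby(["genotype", "nacl_mM", "endophyte"])[
            ["fm", "f0", "seed_mass_g_1", "abs595_1"]
        ].mean()
        eplus = means.xs("E+", level="endophyte")
        eminus = means.xs("E-", level="endophyte")
        pd.testing.assert_frame_equal(eplus, eminus)

    def test_saturated_survival(self):
        effects = EffectModel(survival_logit_base=math.inf)
        plants = simulate_traits(generate_design(StudyDesign()), effects, seed=0)
        assert (plants["alive"] == 1).all()

    def test_survival_calibration_severe_stress(self):
        # 400 mM at 19 deg S: configured expectations are exactly 5/6 and 1/4
        effects = EffectModel()
        p_eplus = effects.survival_probability(19.0, 400.0, "E+")
        p_eminus = effects.survival_probability(19.0, 400.0, "E-")
        assert p_eplus == pytest.approx(5.0 / 6.0, abs=1e-12)
        assert p_eminus == pytest.approx(0.25, abs=1e-12)
        # Monte-Carlo draw at >= 200 plants per arm stays within binomial error
        design = StudyDesign(
            genotypes=ONE_GENOTYPE, salinity_levels=(400.0,), replicates_per_cell=300
        )
        plants = simulate_traits(generate_design(design), effects, seed=5)
        obs = plants.groupby("endophyte")["alive"].mean()
        assert obs["E+"] == pytest.approx(5.0 / 6.0, abs=3 * math.sqrt(5 / 36 / 300))
        assert obs["E-"] == pytest.approx(0.25, abs=3 * math.sqrt(0.1875 / 300))

    def test_no_endophyte_effect_without_salt(self):
        gaps = EffectModel().neutrality_gap(latitude=19.0)
        assert all(g <= EffectModel().neutrality_bound for g in gaps.values())

    def test_bad_effect_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectModel(fvfm_logit_sd=-0.1)
        with pytest.raises(ConfigurationError):
            EffectModel(efficiency_target=2.5)
        with pytest.raises(ConfigurationError):
            EffectModel(fvfm_logit_base=math.inf)
        with pytest.raises(ConfigurationError):
            EffectModel(ct_range=(40.0, 10.0))

    def test_deterministic_under_seed(self):
        design = generate_design(StudyDesign(genotypes=THREE_GENOTYPES, replicates_per_cell=2))
        a = simulate_traits(design, seed=9)
        b = simulate_traits(design, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_traits(design, seed=10)
        assert not a["fm"].equals(c["fm"])


class TestQpcrPlate:
    def test_replicate_structure(self, plate):
        per_gene = plate.groupby(["genotype", "endophyte", "nacl_mM", "gene"]).size()
        assert (per_gene == 5).all()
        assert set(plate["gene"]) == {"target", "reference"}
        assert plate.attrs["primers"]["CqNHX1"]["sense"].startswith("GCACTT")

    def test_reference_gene_condition_invariant(self, plate):
        ref = plate[plate["gene"] == "reference"]
        cond_means = ref.groupby(["endophyte", "nacl_mM"])["ct"].mean()
        assert cond_means.max() - cond_means.min() < 0.5  # noise only, no signal

    def test_too_few_replicates_rejected(self):
        design = generate_design(StudyDesign(genotypes=ONE_GENOTYPE))
        with pytest.raises(InvalidDesignError):
            simulate_qpcr_plate(design, qpcr_replicates=1)

    def test_zero_noise_null_effects_gives_unit_ratios(self):
        effects = EffectModel.null(ct_sd=0.0, log2fc_salt=0.0)
        design = generate_design(StudyDesign(genotypes=THREE_GENOTYPES, replicates_per_cell=1))
        plate = simulate_qpcr_plate(design, effects, seed=0, qpcr_replicates=3)
        expr = summarize_expression(plate, method="livak")
        assert expr["ratio"].to_numpy() == pytest.approx(1.0, abs=1e-12)

    def test_configured_fold_change_recovered_without_noise(self):
        # 400 mM, lat 19, E-: log2FC = 1.5 exactly -> ratio 2^1.5
        effects = EffectModel(ct_sd=0.0)
        design = generate_design(
            StudyDesign(genotypes=ONE_GENOTYPE, salinity_levels=(0.0, 400.0), replicates_per_cell=1)
        )
        plate = simulate_qpcr_plate(design, effects, seed=0, qpcr_replicates=2)
        expr = summarize_expression(plate, method="livak").set_index(["endophyte", "nacl_mM"])
        assert expr.loc[("E-", 400.0), "ratio"] == pytest.approx(2**1.5, rel=1e-12)
        # E+ adds the full benefit at the reference latitude: 2^(1.5 + 1.0)
        assert expr.loc[("E+", 400.0), "ratio"] == pytest.approx(2**2.5, rel=1e-12)


def test_write_dataset_roundtrip(tmp_path, default_dataset):
    design = StudyDesign(seed=7)
    effects = EffectModel()
    paths = write_dataset(default_dataset, tmp_path, design=design, effects=effects, seed=7)
    back = pd.read_csv(paths["plants"], float_precision="round_trip")
    pd.testing.assert_frame_equal(back, default_dataset["plants"], check_exact=True)
    import json

    manifest = json.loads(paths["manifest"].read_text())
    assert manifest["seed"] == 7
    assert manifest["design"]["replicates_per_cell"] == 12
    assert manifest["effects"]["seed_mass_base_g"] == effects.seed_mass_base_g
    assert "CqNHX1" in manifest["primers"]


def test_dataset_byte_identical_under_seed(tmp_path):
    design = StudyDesign(genotypes=THREE_GENOTYPES, replicates_per_cell=2, seed=4)
    for sub in ("a", "b"):
        write_dataset(simulate_dataset(design, seed=4), tmp_path / sub, design=design, seed=4)
    for name in ("plants.csv", "qpcr.csv", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
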