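"""Latitude slope estimation, contrasts, letters, and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from endosym import EffectModel, StudyDesign, generate_design, simulate_traits
from endosym.errors import InsufficientGradientError, MixedResponseError
from endosym.trends import (
    SlopeFit,
    compact_letters,
    compare_slopes,
    fit_group_slopes,
    fit_latitude_slope,
    holm_adjust,
    permutation_slope_test,
    residual_normality,
)

LATS = [19.0, 29.0, 34.0, 35.0, 39.0]


def _frame(values, lats=LATS, endophyte="E+", nacl=400.0):
    return pd.DataFrame(
        {
            "genotype": [f"G{i}" for i in range(len(lats))],
            "latitude_deg_s": lats,
            "endophyte": endophyte,
            "nacl_mM": nacl,
            "y": values,
        }
    )


class TestSlopeFit:
    def test_constant_response(self):
        fit = fit_latitude_slope(_frame([7.0] * 5), "y")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_perfect_line(self):
        fit = fit_latitude_slope(_frame([2 * l for l in LATS]), "y")
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)
        assert fit.pvalue == pytest.approx(0.0, abs=1e-9)

    def test_worked_example(self):
        # oracle: closed-form least squares on the listed pairs
        fit = fit_latitude_slope(_frame([10.0, 8.0, 7.0, 7.0, 6.0]), "y")
        assert fit.slope == pytest.approx(-0.19679054054054052, rel=1e-10)

    def test_matches_independent_implementations(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            y = rng.normal(size=5) * rng.uniform(0.5, 20)
            fit = fit_latitude_slope(_frame(list(y)), "y")
            x = np.array(LATS)
            # brute-force normal equations
            X = np.column_stack([np.ones(5), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.slope == pytest.approx(beta[1], rel=1e-12, abs=1e-12)
            assert fit.intercept == pytest.approx(beta[0], rel=1e-12, abs=1e-12)
            # scipy as a second, independent route
            lr = stats.linregress(x, y)
            assert fit.stderr == pytest.approx(lr.stderr, rel=1e-10)
            assert fit.pvalue == pytest.approx(lr.pvalue, rel=1e-9)

    def test_aggregates_plants_to_genotype_means(self):
        df = pd.concat([_frame([10.0, 8.0, 7.0, 7.0, 6.0])] * 3, ignore_index=True)
        noisy = df.copy()
        noisy.loc[0:4, "y"] += 1.0   # per-genotype means shift by 1/3 uniformly?
        fit_rep = fit_latitude_slope(df, "y")
        fit_single = fit_latitude_slope(_frame([10.0, 8.0, 7.0, 7.0, 6.0]), "y")
        assert fit_rep.slope == pytest.approx(fit_single.slope, rel=1e-12)

    def test_insufficient_gradient(self):
        with pytest.raises(InsufficientGradientError):
            fit_latitude_slope(_frame([1.0, 2.0], lats=[19.0, 29.0]), "y")


class TestHolmAndContrasts:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=15))
    def test_holm_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-15).all()

    def _six_fits(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        fits = []
        for endo in ("E+", "E-"):
            for nacl in (0.0, 200.0, 400.0):
                shift = effect if (endo == "E+" and nacl == 400.0) else 0.0
                y = [10 - (0.1 + shift) * l + rng.normal(0, 0.3) for l in LATS]
                fits.append(
                    fit_latitude_slope(_frame(y, endophyte=endo, nacl=nacl), "y",
                                       endophyte=endo, nacl_mM=nacl)
                )
        return fits

    def test_fifteen_pairs_and_symmetry(self):
        fits = self._six_fits()
        table = compare_slopes(fits)
        assert len(table) == 15
        rev = compare_slopes(list(reversed(fits)))
        merged = table.merge(
            rev,
            left_on=["group_a", "group_b"],
            right_on=["group_b", "group_a"],
            suffixes=("", "_rev"),
        )
        assert len(merged) == 15
        np.testing.assert_allclose(merged["slope_diff"], -merged["slope_diff_rev"], atol=1e-12)
        np.testing.assert_allclose(merged["p_raw"], merged["p_raw_rev"], atol=1e-12)

    def test_adjusted_p_dominates_raw(self):
        table = compare_slopes(self._six_fits(seed=3, effect=0.3))
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_mixed_responses_rejected(self):
        fits = self._six_fits()
        other = SlopeFit("other", "E+", 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 5, 1.0, False)
        with pytest.raises(MixedResponseError):
            compare_slopes([fits[0], other])

    def test_letters_encode_significance_graph(self):
        fits = self._six_fits(seed=5, effect=2.0)  # one clearly divergent slope
        table = compare_slopes(fits)
        letters = compact_letters(fits, table).set_index("group")["letters"]
        assert (letters.str.len() >= 1).all()
        sig = {
            frozenset((r["group_a"], r["group_b"])): r["p_adj"] < 0.05
            for _, r in table.iterrows()
        }
        for pair, is_sig in sig.items():
            a, b = tuple(pair)
            shares = set(letters[a]) & set(letters[b])
            if is_sig:
                assert not shares, f"{a} vs {b} differ but share {shares}"

    def test_no_differences_one_letter(self):
        fits = self._six_fits(seed=1, effect=0.0)
        table = compare_slopes(fits)
        if not table["significant"].any():
            letters = compact_letters(fits, table)
            assert set(letters["letters"]) == {"a"}


class TestResidualNormality:
    def test_matches_scipy_probplot_correlation(self):
        rng = np.random.default_rng(1)
        for n in (5, 10, 40):
            resid = rng.normal(size=n)
            r, _ = residual_normality(resid)
            (_, _), (_, _, r_scipy) = stats.probplot(resid, dist="norm")
            assert r == pytest.approx(r_scipy, abs=1e-10)

    def test_flags_gross_nonnormality(self):
        resid = np.array([0.0, 0.001, 0.002, 0.003, 100.0] * 4)
        r, flag = residual_normality(resid)
        assert flag and r < 0.879

    def test_normal_residuals_pass(self):
        rng = np.random.default_rng(2)
        r, flag = residual_normality(rng.normal(size=50))
        assert not flag


class TestPermutation:
    def _plants(self, effects, seed, reps=6):
        design = StudyDesign(
            genotypes=(
                # three distinct latitudes suffice for a slope
                *[g for g in StudyDesign().genotypes if g.name in ("Pandela", "Paihuano", "BO78")],
            ),
            salinity_levels=(200.0,),
            replicates_per_cell=reps,
        )
        plants = simulate_traits(generate_design(design), effects, seed=seed)
        plants["fvfm"] = (plants["fm"] - plants["f0"]) / plants["fm"]
        return plants

    def test_all_ties_give_p_one(self):
        plants = self._plants(EffectModel.null(fvfm_logit_sd=0.0), seed=0)
        res = permutation_slope_test(plants, "fvfm", 200.0, n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_nperm_floor(self):
        plants = self._plants(EffectModel(), seed=0)
        with pytest.raises(ValueError):
            permutation_slope_test(plants, "fvfm", 200.0, n_perm=50, seed=0)

    def test_strong_effect_detected(self):
        # make the E+ benefit decline steeply with latitude, tiny noise
        effects = EffectModel(
            fvfm_logit_benefit=3.0, decay_per_deg=0.05, fvfm_logit_sd=0.02
        )
        rejections = 0
        for seed in range(20):
            plants = self._plants(effects, seed=seed, reps=6)
            res = permutation_slope_test(plants, "fvfm", 200.0, n_perm=199, seed=seed)
            rejections += res.p_value <= 0.01
        assert rejections >= 19

    def test_deterministic_under_seed(self):
        plants = self._plants(EffectModel(), seed=3)
        a = permutation_slope_test(plants, "fvfm", 200.0, n_perm=199, seed=11)
        b = permutation_slope_test(plants, "fvfm", 200.0, n_perm=199, seed=11)
        assert a == b

    def test_group_slopes_order(self, plants):
        from endosym.traits import summarize_plants

        fits = fit_group_slopes(summarize_plants(plants), "mean_fvfm")
        assert [(f.endophyte, f.nacl_mM) for f in fits] == [
            ("E+", 0.0), ("E+", 200.0), ("E+", 400.0),
            ("E-", 0.0), ("E-", 200.0), ("E-", 400.0),
        ]
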