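import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dupdiv.expression import (contribution_partition, correlate_expression,
                               fit_trait_model, genotype_group_summary,
                               pearson_correlation)
from dupdiv.io import TraitTable
from dupdiv.simulate import ExprSimParams, simulate_expression_trait


def table_from_arrays(expr, trait, genes=("g1", "g2", "g3"), genotype=None):
    expr = np.asarray(expr, dtype=float)
    df = pd.DataFrame({
        "cultivar": [f"c{i}" for i in range(len(trait))],
        "replicate": 1,
        "trait": trait,
    })
    for j, g in enumerate(genes):
        df[g] = expr[:, j]
    if genotype is not None:
        df["genotype"] = genotype
    return TraitTable(df, genes=list(genes), trait="trait",
                      genotype="genotype" if genotype is not None else None)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(res.r ** 2, abs=1e-15)

    def test_constant_input_flagged_undefined(self):
        res = pearson_correlation(np.ones(5), np.arange(5.0))
        assert not res.defined
        assert np.isnan(res.r)

    def test_hand_computed_five_points(self):
        res = pearson_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res = pearson_correlation(x, y)
        dx, dy = x - x.mean(), y - y.mean()
        expected = (dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy))
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_replicates_averaged_before_correlation(self):
        t = simulate_expression_trait(ExprSimParams(n_cultivars=12, seed=0))
        res = correlate_expression(t)
        assert all(c.n == 12 for c in res)


class TestModelFit:
    def test_exact_single_gene_recovery(self):
        rng = np.random.default_rng(0)
        expr = rng.lognormal(0, 0.4, size=(20, 3))
        trait = 5.0 + 2.5 * expr[:, 0]
        fit = fit_trait_model(table_from_arrays(expr, trait))
        assert fit.coefficients["g1"] == pytest.approx(2.5, abs=1e-6)
        for term in ("g2", "g3", "g1:g2", "g1:g3", "g2:g3"):
            assert fit.coefficients[term] == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_saturated_design_rejected(self):
        rng = np.random.default_rng(1)
        expr = rng.lognormal(0, 0.4, size=(7, 3))
        with pytest.raises(ValueError, match="cultivars"):
            fit_trait_model(table_from_arrays(expr, rng.normal(size=7)))

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        expr = rng.lognormal(0, 0.4, size=(20, 3))
        expr[:, 2] = 2.0 * expr[:, 1]  # g3 duplicates g2
        with pytest.raises(ValueError, match="g2"):
            fit_trait_model(table_from_arrays(expr, rng.normal(size=20)))

    def test_normal_equations_hold(self):
        t = simulate_expression_trait(ExprSimParams(betas=(1.0, -0.5, 0.3), seed=7))
        fit = fit_trait_model(t)
        means = t.cultivar_means()
        X = np.column_stack([
            np.ones(len(means)),
            *(means[g] for g in t.genes),
            means[t.genes[0]] * means[t.genes[1]],
            means[t.genes[0]] * means[t.genes[2]],
            means[t.genes[1]] * means[t.genes[2]],
        ])
        beta = np.array(list(fit.coefficients.values()))
        resid = means["trait"].to_numpy() - X @ beta
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_coefficient_calibration_within_3se(self):
        true = np.array([2.0, -1.0, 0.5])
        ok = 0
        n_checks = 0
        for seed in range(100):
            t = simulate_expression_trait(
                ExprSimParams(betas=tuple(true), noise_sd=0.5, replicate_cv=0.0, seed=seed))
            fit = fit_trait_model(t)
            for g, b in zip(t.genes, true):
                n_checks += 1
                if abs(fit.coefficients[g] - b) <= 3 * fit.std_errors[g]:
                    ok += 1
        assert ok / n_checks >= 0.95


class TestContributions:
    def test_lmg_sums_to_main_effects_r2(self):
        for seed in range(10):
            t = simulate_expression_trait(
                ExprSimParams(betas=(1.0, 0.5, -0.3), noise_sd=1.0, seed=seed))
            res = contribution_partition(t)
            assert sum(res.contributions.values()) / 100 == pytest.approx(
                res.main_effects_r2, abs=1e-8)

    def test_orthogonal_design_gives_marginal_r2(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(24, 4))
        raw[:, 0] = 1.0
        q, _ = np.linalg.qr(raw)
        expr = 0.2 * q[:, 1:4] + 1.0  # centered-orthogonal, shifted positive
        trait = 3.0 + 2.0 * expr[:, 0] + 1.0 * expr[:, 1] + rng.normal(0, 0.05, 24)
        t = table_from_arrays(expr, trait)
        res = contribution_partition(t)
        y = trait
        tss = ((y - y.mean()) ** 2).sum()
        for j, g in enumerate(t.genes):
            x = expr[:, j]
            r = np.corrcoef(x, y)[0, 1]
            assert res.contributions[g] / 100 == pytest.approx(r ** 2, abs=1e-10)

    def test_permutation_symmetry(self):
        t = simulate_expression_trait(ExprSimParams(betas=(1.5, 0.2, -0.7), seed=11))
        res = contribution_partition(t)
        perm = TraitTable(
            t.data.rename(columns={t.genes[0]: "x", t.genes[2]: t.genes[0]})
                  .rename(columns={"x": t.genes[2]}),
            genes=t.genes, trait="trait")
        res_perm = contribution_partition(perm)
        assert res.contributions[t.genes[0]] == pytest.approx(
            res_perm.contributions[t.genes[2]], abs=1e-10)
        assert res.contributions[t.genes[2]] == pytest.approx(
            res_perm.contributions[t.genes[0]], abs=1e-10)

    def test_single_informative_gene_limit(self):
        rng = np.random.default_rng(4)
        expr = rng.lognormal(0, 0.5, size=(200, 3))
        trait = 1.0 + 3.0 * expr[:, 0] + rng.normal(0, 0.5, 200)
        t = table_from_arrays(expr, trait)
        res = contribution_partition(t)
        r = np.corrcoef(expr[:, 0], trait)[0, 1]
        assert res.contributions["g1"] / 100 == pytest.approx(r ** 2, abs=0.02)
        assert res.contributions["g2"] < 2.0 and res.contributions["g3"] < 2.0


class TestGenotypeGroups:
    def test_toy_table_group_means(self):
        expr = np.array([[1.0, 1, 1], [2.0, 1, 1], [3.0, 1, 1],
                         [5.0, 1, 1], [6.0, 1, 1], [7.0, 1, 1]])
        trait = np.array([10.0, 11, 12, 20, 21, 22])
        genotype = ["G1"] * 3 + ["G2"] * 3
        t = table_from_arrays(expr, trait, genotype=genotype)
        summary, pairwise = genotype_group_summary(t)
        assert summary.loc["G1", ("trait", "mean")] == pytest.approx(11.0)
        assert summary.loc["G2", ("trait", "mean")] == pytest.approx(21.0)
        assert summary.loc["G1", ("g1", "mean")] == pytest.approx(2.0)
        assert set(pairwise["measure"]) == {"trait", "g1", "g2", "g3"}

    def test_single_group_rejected(self):
        expr = np.ones((5, 3))
        t = table_from_arrays(expr, np.arange(5.0), genotype=["G1"] * 5)
        with pytest.raises(ValueError, match="2 genotype groups"):
            genotype_group_summary(t)

    def test_null_groups_rarely_significant(self):
        n_sig = 0
        for seed in range(50):
            t = simulate_expression_trait(
                ExprSimParams(genotype_groups=2, genotype_shift=0.0, seed=seed))
            _, pairwise = genotype_group_summary(t)
            p = pairwise.loc[pairwise["measure"] == t.genes[0], "p_value"].iloc[0]
            if p < 0.01:
                n_sig += 1
        assert n_sig <= 3

    def test_shifted_groups_detected(self):
        n_sig = 0
        for seed in range(50):
            t = simulate_expression_trait(
                ExprSimParams(n_cultivars=30, genotype_groups=2, genotype_shift=3.0,
                              seed=seed))
            _, pairwise = genotype_group_summary(t)
            p = pairwise.loc[pairwise["measure"] == t.genes[0], "p_value"].iloc[0]
            if p < 0.01:
                n_sig += 1
        assert n_sig >= 48
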