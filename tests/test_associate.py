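"""Rank-inverse-normal transform, variant filters, OLS association, PheWAS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from dgrpkit.associate import (
    AssocConfig,
    P_FLOOR,
    PhewasStore,
    bonferroni_threshold,
    covariate_screen,
    filter_variants,
    fit_single_variant,
    genotype_group_values,
    phewas_lookup,
    qq_data,
    rank_inverse_normal,
    run_gwas,
    significance_summary,
)
from dgrpkit.errors import (
    ConfigError,
    DegeneratePhenotypeError,
    InsufficientDataError,
    MonomorphicVariantError,
)
from dgrpkit.genotypes import CovariateTable, GenotypePanel
from dgrpkit.simulate import SimConfig, simulate_covariates, simulate_genotypes


def make_panel(calls, lines=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    lines = lines or [f"DGRP_{i:03d}" for i in range(1, n + 1)]
    variants = pd.DataFrame({
        "variant_id": [f"2L:{1000 + j}" for j in range(m)],
        "chrom": "2L", "pos": [1000 + j for j in range(m)],
        "ref": "A", "alt": "T", "vclass": "SNP",
    })
    return GenotypePanel(lines=lines, variants=variants, calls=calls)


class TestRankInverseNormal:
    def test_blom_quantiles_for_five_distinct_values(self):
        z = rank_inverse_normal([10.0, 20.0, 30.0, 40.0, 50.0])
        expected = stats.norm.ppf((np.arange(1, 6) - 0.375) / (5 - 0.75 + 1))
        np.testing.assert_allclose(z, expected, atol=1e-12)
        np.testing.assert_allclose(
            stats.norm.cdf(expected), [0.119, 0.310, 0.5, 0.690, 0.881], atol=5e-4)

    def test_symmetric_input_centred(self):
        z = rank_inverse_normal([1.0, 2.0, 3.0])
        assert z[1] == 0.0
        assert z[0] == pytest.approx(-z[2])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        np.testing.assert_allclose(rank_inverse_normal(y),
                                   rank_inverse_normal(np.exp(y)), atol=1e-12)

    def test_missing_preserved_and_errors(self):
        y = np.array([1.0, np.nan, 2.0, 3.0])
        z = rank_inverse_normal(y)
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3]]).any()
        with pytest.raises(InsufficientDataError):
            rank_inverse_normal([1.0, 2.0])
        with pytest.raises(DegeneratePhenotypeError):
            rank_inverse_normal([2.0, 2.0, 2.0])


class TestFilterVariants:
    def test_stated_cutoffs(self):
        n = 100
        calls = np.zeros((n, 3))
        calls[:50, 0] = 1.0                  # MAF 0.5, clean -> retained
        calls[:21, 1] = np.nan               # 21% missing -> excluded
        calls[0, 2] = 1.0                    # alt freq 0.01 ... wait 1/100
        calls[1, 2] = 1.0                    # never mind: alt 2/100 = 0.02 kept
        panel = make_panel(calls)
        report = filter_variants(panel, AssocConfig())
        assert list(report.reasons) == ["retained", "missingness", "retained"]

    def test_minor_allele_folding(self):
        calls = np.ones((1000, 1))
        calls[:5, 0] = 0.0                   # alt freq 0.995 -> MAF 0.005
        report = filter_variants(make_panel(calls), AssocConfig())
        assert list(report.reasons) == ["maf"]

    def test_constructed_counts_conserved(self):
        rng = np.random.default_rng(0)
        n, m = 50, 100
        calls = (rng.random((n, m)) < 0.3).astype(float)
        bad_missing = [3, 10, 47]
        for j in bad_missing:
            calls[: int(0.25 * n), j] = np.nan
        bad_maf = [5, 20, 60, 99]
        for j in bad_maf:
            calls[:, j] = 0.0
        report = filter_variants(make_panel(calls), AssocConfig())
        counts = report.counts
        assert counts["missingness"] == 3 and counts["maf"] == 4
        assert counts["retained"] == m - 7
        assert sum(counts.values()) == m


class TestFitSingleVariant:
    def test_exact_fit_floors_p(self):
        g = np.array([0, 0, 0, 1, 1, 1.0, 0, 1])
        res = fit_single_variant(2.0 * g, g, variant_id="2L:1")
        assert res.beta == pytest.approx(2.0)
        assert res.p == P_FLOOR

    def test_matches_closed_form_simple_regression(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 30
            g = (rng.random(n) < 0.4).astype(float)
            y = 0.5 * g + rng.normal(size=n)
            res = fit_single_variant(y, g)
            gc = g - g.mean()
            beta = float(gc @ y) / float(gc @ gc)
            resid = y - y.mean() - beta * gc
            s2 = float(resid @ resid) / (n - 2)
            se = np.sqrt(s2 / float(gc @ gc))
            t = beta / se
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)
            assert res.tstat == pytest.approx(t, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        cfg = SimConfig(n_lines=80, seed=3)
        cov = simulate_covariates(cfg)
        rng = np.random.default_rng(3)
        g = (rng.random(80) < 0.5).astype(float)
        y = 0.3 * g + rng.normal(size=80)
        res = fit_single_variant(y, g, cov=cov, lines=cov.lines, variant_id="X:1")
        from dgrpkit.associate import covariate_design
        X = sm.add_constant(np.column_stack(
            [g, covariate_design(cov.aligned(cov.lines))]))
        fit = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicVariantError):
            fit_single_variant(np.arange(5.0), np.zeros(5))


class TestRunGwas:
    @pytest.fixture()
    def small_run(self):
        cfg = SimConfig(n_lines=120, n_variants=60, seed=4, missing_rate=0.05)
        panel = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=120), index=panel.lines)
        return y, panel, cov

    def test_deterministic(self, small_run):
        y, panel, cov = small_run
        a = run_gwas(y, panel, cov)
        b = run_gwas(y, panel, cov)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_fast_path_equals_per_variant_ols(self, small_run):
        """The batched Frisch-Waugh path must agree with the per-variant fit."""
        y, panel, cov = small_run
        run = run_gwas(y, panel, cov)
        yv = y.to_numpy()
        z = rank_inverse_normal(yv)
        for _, row in run.results.head(8).iterrows():
            g = panel.column(row["variant_id"])
            ref = fit_single_variant(z, g, cov=cov, lines=panel.lines)
            assert row["beta"] == pytest.approx(ref.beta, abs=1e-9)
            assert row["se"] == pytest.approx(ref.se, abs=1e-9)
            assert row["p"] == pytest.approx(ref.p, abs=1e-9)
            assert row["n_used"] == ref.n_used

    def test_transform_invariance_of_pvalues(self, small_run):
        y, panel, cov = small_run
        a = run_gwas(y, panel, cov)
        b = run_gwas(np.exp(y), panel, cov)
        pd.testing.assert_series_equal(a.results["p"], b.results["p"])

    def test_filter_conservation(self, small_run):
        y, panel, cov = small_run
        run = run_gwas(y, panel, cov)
        counts = run.filter_report.counts
        assert sum(counts.values()) == panel.n_variants

    def test_insufficient_lines_error(self):
        cfg = SimConfig(n_lines=5, n_variants=4, seed=1)
        panel = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        y = pd.Series(np.arange(5.0), index=panel.lines)
        with pytest.raises(InsufficientDataError):
            run_gwas(y, panel, cov)

    def test_permuted_phenotype_kills_causal_hit(self):
        from dgrpkit.simulate import SpikedEffect, simulate_panel
        base = SimConfig(n_lines=200, n_variants=300, seed=6)
        maf = np.nanmean(simulate_genotypes(base).calls, axis=0)
        causal = int(np.argmin(np.abs(np.minimum(maf, 1 - maf) - 0.25)))
        cfg = SimConfig(n_lines=200, n_variants=300, seed=6,
                        causal_effects=(SpikedEffect(causal, 1.5),))
        panel, cov, reg = simulate_panel(cfg)
        y = reg.tables["S1"].values_for("p1", "F")
        run = run_gwas(y, panel, cov)
        causal_id = panel.variant_ids[causal]
        assert run.results.iloc[0]["variant_id"] == causal_id
        assert run.results.iloc[0]["p"] < 1e-6
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        run_perm = run_gwas(y_perm, panel, cov)
        hit = run_perm.results[run_perm.results["variant_id"] == causal_id]
        assert hit["p"].iloc[0] > 1e-6


class TestSummaries:
    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        with pytest.raises(ConfigError):
            bonferroni_threshold(0.05, 0)

    def test_threshold_counts(self):
        results = pd.DataFrame({"p": [1e-7, 1e-6, 1e-4, 0.02, 1.0]})
        summ = significance_summary(results, AssocConfig())
        assert summ["counts"] == {1e-3: 3, 1e-5: 2, 1e-6: 2}
        assert summ["bonferroni_threshold"] == pytest.approx(0.01)
        assert summ["bonferroni_count"] == 3

    def test_all_p_one_counts_zero(self):
        results = pd.DataFrame({"p": [1.0, 1.0]})
        summ = significance_summary(results)
        assert all(v == 0 for v in summ["counts"].values())

    def test_qq_uniform_grid_on_diagonal(self):
        m = 100
        p = (np.arange(1, m + 1) - 0.5) / m
        expected, observed = qq_data(pd.DataFrame({"p": p}))
        np.testing.assert_allclose(expected, observed, atol=1e-12)
        e1, o1 = qq_data(pd.DataFrame({"p": [0.5]}))
        assert len(e1) == len(o1) == 1


class TestCovariateScreen:
    def test_shifted_symbiont_detected(self):
        cfg = SimConfig(n_lines=100, seed=5, symbiont_prevalence=0.5)
        cov = simulate_covariates(cfg)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=100) + 3.0 * cov.data["symbiont"].to_numpy(),
                      index=cov.lines)
        screen = covariate_screen(y, cov)
        assert screen.kruskal["symbiont"][1] < 0.01
        sym = cov.data["symbiont"].to_numpy()
        yv = y.to_numpy()
        assert screen.kruskal["symbiont"][0] == pytest.approx(
            stats.kruskal(yv[sym == 0], yv[sym == 1])[0])
        assert "C(symbiont)" in screen.anova.index

    def test_flat_phenotype_statistic_zero(self):
        cfg = SimConfig(n_lines=60, seed=6)
        cov = simulate_covariates(cfg)
        rng = np.random.default_rng(6)
        base = rng.normal(size=60)
        # identical distribution across symbiont groups by construction:
        y = pd.Series(np.where(cov.data["symbiont"] == 1, base, base), index=cov.lines)
        stat, p = covariate_screen(y, cov).kruskal["symbiont"]
        assert p > 0.01 or stat < 5

    def test_shapiro_p_uniform_under_gaussian(self):
        pvals = []
        for seed in range(40):
            cfg = SimConfig(n_lines=100, seed=seed)
            cov = simulate_covariates(cfg)
            rng = np.random.default_rng(100 + seed)
            y = pd.Series(rng.normal(size=100), index=cov.lines)
            pvals.append(covariate_screen(y, cov).shapiro[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGroupsAndPhewas:
    def test_group_values_partition(self):
        g = np.array([0, 0, 0, 1, 1, np.nan])
        lines = [f"DGRP_{i:03d}" for i in range(1, 7)]
        y = pd.Series(np.arange(6.0), index=lines)
        groups = genotype_group_values(y, g, lines)
        assert len(groups["ref"]) == 3 and len(groups["alt"]) == 2
        assert len(groups["missing"]) == 1
        assert sum(len(v) for v in groups.values()) == 6

    def test_lookup_sorted_and_bounded(self):
        store = PhewasStore()
        row = {"beta": 1.0, "se": 0.1, "tstat": 10.0, "n_used": 50, "maf": 0.3}
        store.add("A", pd.DataFrame([{"variant_id": "2R:1", "p": 1e-8, **row}]))
        store.add("B", pd.DataFrame([{"variant_id": "2R:1", "p": 1e-3, **row}]))
        store.add("C", pd.DataFrame([{"variant_id": "3L:9", "p": 0.5, **row}]))
        res = phewas_lookup("2R:1", store)
        assert list(res.rows["phenotype"]) == ["A", "B"]
        assert len(res.rows) <= len(store.phenotypes)
        empty = phewas_lookup("X:404", store)
        assert empty.rows.empty and empty.notice
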