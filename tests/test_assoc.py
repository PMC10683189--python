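"""Unit tests for the association layer: GWAS scan, Brown aggregation,
burden / SKAT / SKAT-O, and the quadratic-form machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corac import (
    ArchitectureParams,
    assign_causal_genes,
    build_gene_table,
    build_genome_map,
    burden_test,
    combine_rare,
    draw_effects,
    gene_test_common,
    gwas_scan,
    maf_weights,
    simulate_genotypes,
    simulate_phenotype,
    skat_test,
    skato_test,
)
from corac._quadform import liu_quantile, liu_sf, rho_lambdas, skato_omnibus_p
from corac.assoc import rare_gene_scan


@pytest.fixture(scope="module")
def small_cohort():
    genome = build_genome_map(30, 1, 4, 6, seed=10)
    panel = simulate_genotypes(genome, 800, seed=11)
    params = ArchitectureParams()
    cset, rset = assign_causal_genes(genome, params, seed=12)
    eff = draw_effects(panel, cset, rset, params, seed=13)
    phen = simulate_phenotype(panel, eff, params, seed=14)
    return genome, panel, phen


class TestGwasScan:
    def test_matches_scipy_linregress(self, small_cohort):
        genome, panel, phen = small_cohort
        out = gwas_scan(panel, phen)
        col_of = {v: i for i, v in enumerate(genome.variants["variant_id"])}
        for _, row in out.head(5).iterrows():
            g = panel.genotypes[:, col_of[row.variant_id]].astype(float)
            ref = stats.linregress(g, phen.values)
            assert row.beta_hat == pytest.approx(ref.slope, rel=1e-9)
            assert row.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_only_polymorphic_common(self, small_cohort):
        genome, panel, _ = small_cohort
        out = gwas_scan(panel, np.random.default_rng(0).standard_normal(800))
        v = genome.variants.set_index("variant_id")
        assert (v.loc[out.variant_id, "vclass"] == "common").all()

    def test_covariates_remove_confounding(self, small_cohort):
        genome, panel, _ = small_cohort
        rng = np.random.default_rng(1)
        conf = panel.scaled(np.array([0]))[:, 0]
        y = 0.5 * conf + rng.standard_normal(800)
        raw = gwas_scan(panel, y)
        adj = gwas_scan(panel, y, covariates=conf[:, None])
        v0 = genome.variants["variant_id"].iloc[0]
        p_raw = raw.set_index("variant_id").loc[v0, "p"]
        p_adj = adj.set_index("variant_id").loc[v0, "p"]
        assert p_raw < 1e-6
        assert p_adj > 1e-4


class TestBrown:
    def test_single_snp_gene_passthrough(self, small_cohort):
        genome, panel, phen = small_cohort
        snp = gwas_scan(panel, phen)
        one = snp.groupby("gene_id").head(1).groupby("gene_id").first()
        sub = snp[snp.gene_id == snp.gene_id.iloc[0]].head(1)
        out = gene_test_common(sub, genome, panel)
        got = out.set_index("gene_id").loc[sub.gene_id.iloc[0], "p_common"]
        assert got == pytest.approx(sub.p.iloc[0], rel=1e-12)

    def test_independent_snps_reduce_to_fisher(self):
        """With uncorrelated SNPs Brown's scaled chi-square reduces to
        Fisher's chi2_{2k} combination."""
        genome = build_genome_map(4, 1, 1, 1, seed=3)
        panel = simulate_genotypes(genome, 3000, seed=4)
        # treat the 4 independent blocks' common SNPs as one synthetic gene
        pvals = np.array([0.02, 0.2, 0.5, 0.9])
        t = float(-2 * np.log(pvals).sum())
        fisher = stats.chi2.sf(t, 8)
        common_cols = np.flatnonzero(
            (genome.variants["vclass"] == "common").to_numpy()
        )
        snp = pd.DataFrame(
            {
                "variant_id": genome.variants["variant_id"].iloc[common_cols].to_numpy(),
                "gene_id": "g00000",
                "p": pvals,
            }
        )
        gmap = genome  # block structure irrelevant for the correlation lookup
        out = gene_test_common(snp, gmap, panel)
        got = out.set_index("gene_id").loc["g00000", "p_common"]
        # empirical correlations are near but not exactly zero
        assert got == pytest.approx(fisher, rel=0.15)

    def test_worked_fisher_arithmetic(self):
        # T = -2(ln .1 + ln .7) = 5.318; chi2_4 upper tail
        t = -2 * (np.log(0.1) + np.log(0.7))
        assert stats.chi2.sf(t, 4) == pytest.approx(0.2561, abs=5e-4)

    def test_perfectly_duplicated_snps(self):
        """At r = 1 the Kost-McDermott covariance is exact: two copies of one
        p-value must give back (approximately) that p-value's scale."""
        genome = build_genome_map(1, 1, 2, 1, seed=5)
        panel = simulate_genotypes(genome, 400, seed=6)
        panel.genotypes[:, 1] = panel.genotypes[:, 0]
        panel.freq[1] = panel.freq[0]
        p0 = 0.05
        snp = pd.DataFrame(
            {
                "variant_id": genome.variants["variant_id"].iloc[:2].to_numpy(),
                "gene_id": "g00000",
                "p": [p0, p0],
            }
        )
        out = gene_test_common(snp, genome, panel)
        got = out.set_index("gene_id").loc["g00000", "p_common"]
        # var T = 8 + 2*(3.263+0.710+0.027) = 16, c = 2, f = 2: chi2_2(T/2)
        expected = stats.chi2.sf(-2 * np.log(p0), 2)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_missing_genes_get_nan(self, small_cohort):
        genome, panel, phen = small_cohort
        snp = gwas_scan(panel, phen)
        snp = snp[snp.gene_id != "g00000"]
        out = gene_test_common(snp, genome, panel)
        assert np.isnan(out.set_index("gene_id").loc["g00000", "p_common"])
        assert len(out) == genome.n_genes


class TestLiu:
    def test_single_chi2(self):
        lam = np.array([2.0])
        q = 7.0
        assert liu_sf(q, lam) == pytest.approx(stats.chi2.sf(q / 2, 1), rel=1e-6)

    def test_monte_carlo_oracle(self):
        """Moment matching is tight where tests operate (tail p <= 0.25) and
        has the documented ~0.03 body error for skewed eigenvalue sets."""
        rng = np.random.default_rng(0)
        lam = np.array([3.0, 1.0, 0.5])
        draws = (lam * rng.standard_normal((500_000, 3)) ** 2).sum(axis=1)
        for q in (6.0, 12.0, 20.0, 30.0):
            emp = (draws > q).mean()
            assert liu_sf(q, lam) == pytest.approx(emp, abs=0.01)
        emp_body = (draws > 2.0).mean()
        assert liu_sf(2.0, lam) == pytest.approx(emp_body, abs=0.04)

    def test_quantile_inverts_sf(self):
        lam = np.array([2.0, 1.0, 0.3])
        for p in (0.5, 0.1, 0.01):
            q = liu_quantile(p, lam)
            assert liu_sf(q, lam) == pytest.approx(p, rel=1e-3)

    def test_rho_lambdas_endpoints(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((50, 4))
        k = z.T @ z
        lam0 = rho_lambdas(k, 0.0)
        assert np.allclose(np.sort(lam0), np.sort(np.linalg.eigvalsh(k)))
        lam1 = rho_lambdas(k, 1.0)
        # rho=1 collapses to the burden direction: one dominant eigenvalue
        assert (lam1 > 1e-8 * lam1.max()).sum() == 1


class TestRareTests:
    def test_maf_weights_shape(self):
        w = maf_weights(np.array([0.001, 0.01, 0.05]))
        assert w[0] > w[1] > w[2]
        assert np.allclose(w, stats.beta.pdf([0.001, 0.01, 0.05], 1, 25))

    def test_burden_matches_manual_ols(self, small_cohort):
        genome, panel, phen = small_cohort
        gene = genome.genes["gene_id"].iloc[0]
        p = burden_test(panel, phen, gene)
        v = genome.variants
        cols = np.flatnonzero(
            (v.gene_id == gene).to_numpy()
            & (v.vclass == "rare").to_numpy()
            & ~panel.monomorphic
        )
        w = maf_weights(panel.maf[cols])
        score = panel.genotypes[:, cols].astype(float) @ w
        ref = stats.linregress(score, phen.values).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_empty_category_nan(self, small_cohort):
        genome, panel, phen = small_cohort
        gene = genome.genes["gene_id"].iloc[0]
        assert np.isnan(burden_test(panel, phen, gene, category="nonexistent"))
        assert np.isnan(skat_test(panel, phen, gene, category="nonexistent"))

    def test_skato_bounded_by_minp(self, small_cohort):
        """SKAT-O p >= min over the rho grid and <= Bonferroni bound."""
        genome, panel, phen = small_cohort
        for gene in genome.genes["gene_id"].head(8):
            p_o = skato_test(panel, phen, gene)
            p_s = skat_test(panel, phen, gene)
            p_b = burden_test(panel, phen, gene)
            if np.isnan(p_o):
                continue
            floor = min(x for x in (p_s, p_b) if np.isfinite(x))
            assert p_o >= floor * 0.5  # omnibus cannot beat min-p materially
            assert p_o <= 1.0

    def test_combine_rare_minimum(self):
        p, n, tie = combine_rare({"a": 0.5, "b": 0.01, "c": np.nan})
        assert p == 0.01
        assert n == 2
        assert not tie
        p, n, tie = combine_rare({"a": 0.01, "b": 0.01})
        assert tie
        p, n, _ = combine_rare({"a": np.nan})
        assert np.isnan(p) and n == 0

    def test_scan_matches_per_gene_calls(self, small_cohort):
        genome, panel, phen = small_cohort
        scan = rare_gene_scan(panel, phen).set_index("gene_id")
        for gene in genome.genes["gene_id"].head(4):
            for cat in ("pLoF", "missense_LC", "synonymous"):
                pb = burden_test(panel, phen, gene, category=cat)
                ps = skato_test(panel, phen, gene, category=cat)
                got_b = scan.loc[gene, f"p_burden_{cat}"]
                got_s = scan.loc[gene, f"p_skato_{cat}"]
                if np.isnan(pb):
                    assert np.isnan(got_b)
                else:
                    assert got_b == pytest.approx(pb, rel=1e-9)
                if np.isnan(ps):
                    assert np.isnan(got_s)
                else:
                    assert got_s == pytest.approx(ps, rel=1e-6)


class TestSkatoOmnibus:
    def test_null_calibration_monte_carlo(self):
        """Type-I error of the omnibus p-value under a Gaussian null."""
        rng = np.random.default_rng(7)
        n, m = 400, 5
        g = rng.binomial(2, 0.03, size=(n, m)).astype(float)
        g -= g.mean(axis=0)
        kernel = g.T @ g
        grid = np.array([0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0])
        ps = []
        for _ in range(400):
            y = rng.standard_normal(n)
            r = y - y.mean()
            sigma = np.sqrt(float(r @ r) / (n - 1))
            scores = (g.T @ r) / sigma
            p, _, _ = skato_omnibus_p(kernel, scores, grid)
            ps.append(p)
        ps = np.asarray(ps)
        assert 0.01 <= (ps < 0.05).mean() <= 0.10

    def test_detects_burden_signal(self):
        rng = np.random.default_rng(8)
        n, m = 400, 5
        g = rng.binomial(2, 0.05, size=(n, m)).astype(float)
        y = g.sum(axis=1) * 0.4 + rng.standard_normal(n)
        gc = g - g.mean(axis=0)
        r = y - y.mean()
        sigma = np.sqrt(float(r @ r) / (n - 1))
        kernel = gc.T @ gc
        scores = (gc.T @ r) / sigma
        grid = np.array([0.0, 0.25, 0.5, 1.0])
        p, p_each, fallback = skato_omnibus_p(kernel, scores, grid)
        assert p < 1e-4
        # signal is in the burden direction: every burden-leaning test beats
        # the pure variance-component test by an order of magnitude (the
        # ranking among the near-tied burden-leaning rhos is approximation
        # noise, so no single argmin is asserted)
        assert p_each[grid >= 0.25].max() < 0.1 * p_each[0]


class TestGeneTable:
    def test_columns_and_completeness(self, small_cohort):
        genome, panel, phen = small_cohort
        table = build_gene_table(panel, phen)
        assert len(table) == genome.n_genes
        for col in ("gene_id", "block_id", "p_common", "p_rare"):
            assert col in table.columns
        ok = table.dropna(subset=["p_common", "p_rare"])
        assert ((ok.p_common > 0) & (ok.p_common <= 1)).all()
        assert ((ok.p_rare > 0) & (ok.p_rare <= 1)).all()

    def test_p_rare_is_min_over_tests(self, small_cohort):
        genome, panel, phen = small_cohort
        table = build_gene_table(panel, phen)
        cols = [c for c in table.columns if c.startswith(("p_burden_", "p_skato_"))]
        sub = table.dropna(subset=["p_rare"])
        assert np.allclose(
            sub["p_rare"], sub[cols].min(axis=1, skipna=True), rtol=1e-12
        )
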