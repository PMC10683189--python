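"""Gene-level association signals from common and rare variants.

Common variants: a per-SNP linear-model scan, then aggregation of the SNP
p-values to one gene p-value by Brown's method — the gene statistic is
T = sum_j -2 ln p_j, referred to a scaled chi-square whose mean and variance
account for the linkage disequilibrium between the gene's SNPs via the
Kost–McDermott polynomial in the genotype correlation.  This is a
transparent stand-in for the snp-wise mean gene model of dedicated gene
analysis tools; a different backend can be swapped in behind the same
signature.

Rare variants: per annotation category, a weighted burden regression and a
variance-component score test (SKAT) combined with the burden direction over
a rho grid (SKAT-O).  The gene-level rare p-value is the unadjusted minimum
over the available (test x category) p-values, mirroring how exome-wide
portals report gene signals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._quadform import liu_sf, skato_omnibus_p
from .architecture import PhenotypeVector
from .simulate import RARE_CATEGORIES, CohortPanel, GenomeMap

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
DEFAULT_WEIGHT_BETA = (1.0, 25.0)


def _as_values(phenotype) -> np.ndarray:
    if isinstance(phenotype, PhenotypeVector):
        return phenotype.values
    return np.asarray(phenotype, dtype=float)


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y on [1, covariates]."""
    n = len(y)
    if covariates is None:
        return y - y.mean()
    x = np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def gwas_scan(
    panel: CohortPanel,
    phenotype,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-common-variant OLS scan.

    Returns one row per polymorphic common variant with the per-allele
    slope, its standard error, the two-sided t p-value, sample size and MAF.
    Covariates (if given) are residualized out of both phenotype and
    genotype before the per-variant fit.
    """
    y = _as_values(phenotype)
    n = panel.n_individuals
    q = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if n < q + 3:
        raise ValueError(f"{n} individuals cannot support {q} covariates")

    keep = np.flatnonzero(
        (panel.genome.variants["vclass"] == "common").to_numpy()
        & ~panel.monomorphic
    )
    g = panel.genotypes[:, keep].astype(np.float64)
    yr = _residualize(y, covariates)
    if covariates is not None:
        x = np.column_stack([np.ones(n), covariates])
        coef, *_ = np.linalg.lstsq(x, g, rcond=None)
        g = g - x @ coef
    else:
        g = g - g.mean(axis=0)

    sxx = (g**2).sum(axis=0)
    sxy = g.T @ yr
    syy = float(yr @ yr)
    beta = sxy / sxx
    df = n - q - 2
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    v = panel.genome.variants.iloc[keep]
    return pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "gene_id": v["gene_id"].to_numpy(),
            "beta_hat": beta,
            "se": se,
            "p": p,
            "n": n,
            "maf": panel.maf[keep],
        }
    )


def _brown_cov(r: np.ndarray) -> np.ndarray:
    """Polynomial approximation to cov(-2 ln p_i, -2 ln p_j) for TWO-SIDED
    p-values of bivariate-normal test statistics with correlation r.

    The covariance is an even function of r (the sign of the correlation is
    irrelevant for |Z|-based p-values), with exact endpoints cov(0) = 0 and
    cov(1) = Var(-2 ln p) = 4.  Coefficients are a least-squares fit to
    Gauss-Legendre quadrature of E[X1 X2] - E[X]^2 on r in [0, 1]
    (max absolute error 0.0017), constrained so the even-power coefficients
    sum to 4 exactly, preserving the duplicated-variant limiting case.
    The familiar one-sided polynomial (3.263|r| + ...) is NOT valid here: it
    grows linearly in |r| near 0, overstating the covariance of two-sided
    terms (which is O(r^2)) and making the combined test conservative.
    """
    r2 = r * r
    return r2 * (3.891476 + r2 * (0.148540 + r2 * (-0.190052 + r2 * 0.150036)))


def gene_test_common(
    snp_table: pd.DataFrame, genome: GenomeMap, panel: CohortPanel
) -> pd.DataFrame:
    """Aggregate SNP p-values to per-gene P_common by Brown's method.

    The covariance between the chi-square contributions of two SNPs is taken
    from the observed genotype correlation; the resulting scaled chi-square
    matches T's first two moments.  Genes with no polymorphic common variant
    in the table get a missing P_common.
    """
    col_of = {v: i for i, v in enumerate(genome.variants["variant_id"])}
    p_by_gene = snp_table.groupby("gene_id", sort=False)

    rows = []
    gene_block = dict(zip(genome.genes["gene_id"], genome.genes["block_id"]))
    for gene_id, sub in p_by_gene:
        pvals = sub["p"].to_numpy()
        k = len(pvals)
        t_sum = float(-2.0 * np.log(pvals).sum())
        if k == 1:
            p_gene = float(pvals[0])
        else:
            cols = np.array([col_of[v] for v in sub["variant_id"]])
            z = panel.scaled(cols)
            r = (z.T @ z) / panel.n_individuals
            cov = _brown_cov(r)
            iu = np.triu_indices(k, 1)
            mean_t = 2.0 * k
            var_t = 4.0 * k + 2.0 * cov[iu].sum()
            c = var_t / (2.0 * mean_t)
            f = 2.0 * mean_t**2 / var_t
            p_gene = float(stats.chi2.sf(t_sum / c, f))
        rows.append((gene_id, gene_block[gene_id], max(p_gene, np.finfo(float).tiny)))

    out = pd.DataFrame(rows, columns=["gene_id", "block_id", "p_common"])
    missing = set(genome.genes["gene_id"]) - set(out["gene_id"])
    if missing:
        extra = pd.DataFrame(
            {
                "gene_id": sorted(missing),
                "block_id": [gene_block[g] for g in sorted(missing)],
                "p_common": np.nan,
            }
        )
        out = pd.concat([out, extra], ignore_index=True)
    return out.sort_values("gene_id", ignore_index=True)


def maf_weights(
    maf: np.ndarray, beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA
) -> np.ndarray:
    """Beta-density MAF weights (the rare-variant test convention)."""
    return stats.beta.pdf(np.clip(maf, 1e-12, 1 - 1e-12), *beta_shape)


def _gene_category_cols(
    panel: CohortPanel, gene: str, category: str | None
) -> np.ndarray:
    v = panel.genome.variants
    mask = (
        (v["gene_id"] == gene).to_numpy()
        & (v["vclass"] == "rare").to_numpy()
        & ~panel.monomorphic
    )
    if category is not None:
        mask &= (v["category"] == category).to_numpy()
    return np.flatnonzero(mask)


def _burden_p(g_raw: np.ndarray, w: np.ndarray, y: np.ndarray) -> float:
    s = g_raw @ w
    sc = s - s.mean()
    sxx = float(sc @ sc)
    if sxx <= 0.0:
        return np.nan
    yc = y - y.mean()
    sxy = float(sc @ yc)
    syy = float(yc @ yc)
    n = len(y)
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se if se > 0 else np.inf
    return float(
        max(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny)
    )


def burden_test(
    panel: CohortPanel,
    phenotype,
    gene: str,
    category: str | None = None,
    beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA,
) -> float:
    """Weighted minor-allele burden regression p-value for one gene/category.

    Returns NaN when no polymorphic variant exists or the burden score is
    constant.
    """
    cols = _gene_category_cols(panel, gene, category)
    if cols.size == 0:
        return np.nan
    y = _as_values(phenotype)
    g = panel.genotypes[:, cols].astype(float)
    return _burden_p(g, maf_weights(panel.maf[cols], beta_shape), y)


def _skat_parts(
    panel: CohortPanel, cols: np.ndarray, y: np.ndarray, beta_shape
) -> tuple[np.ndarray, np.ndarray]:
    """(kernel, scores) scaled by the null residual variance."""
    r = y - y.mean()
    sigma2 = float(r @ r) / (len(y) - 1)
    g = panel.genotypes[:, cols].astype(float)
    g -= g.mean(axis=0)
    z = g * maf_weights(panel.maf[cols], beta_shape)
    kernel = z.T @ z
    scores = (z.T @ r) / np.sqrt(sigma2)
    return kernel, scores


def skat_test(
    panel: CohortPanel,
    phenotype,
    gene: str,
    category: str | None = None,
    beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA,
) -> float:
    """Variance-component score test p-value for one gene/category."""
    cols = _gene_category_cols(panel, gene, category)
    if cols.size == 0:
        return np.nan
    kernel, scores = _skat_parts(panel, cols, _as_values(phenotype), beta_shape)
    if kernel.diagonal().sum() <= 0:
        return np.nan
    lam = np.linalg.eigvalsh(kernel)
    lam = lam[lam > 1e-10 * max(lam.max(), 1.0)]
    return liu_sf(float(scores @ scores), lam)


def skato_test(
    panel: CohortPanel,
    phenotype,
    gene: str,
    category: str | None = None,
    rho_grid=DEFAULT_RHO_GRID,
    beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA,
) -> float:
    """Optimal burden/SKAT combination p-value over the rho grid."""
    cols = _gene_category_cols(panel, gene, category)
    if cols.size == 0:
        return np.nan
    kernel, scores = _skat_parts(panel, cols, _as_values(phenotype), beta_shape)
    if kernel.diagonal().sum() <= 0:
        return np.nan
    p, _, _ = skato_omnibus_p(kernel, scores, np.asarray(rho_grid, float))
    return p


def combine_rare(pvalues: dict[str, float]) -> tuple[float, int, bool]:
    """P_rare = the literal minimum of the available test/category p-values.

    Returns (p_rare, number of contributing tests, tie flag); NaN when every
    test is missing.  No multiplicity adjustment is applied.
    """
    avail = {k: v for k, v in pvalues.items() if v is not None and np.isfinite(v)}
    if not avail:
        return np.nan, 0, False
    vals = np.array(list(avail.values()))
    pmin = float(vals.min())
    tie = int((vals == pmin).sum()) > 1
    return pmin, len(avail), tie


def rare_gene_scan(
    panel: CohortPanel,
    phenotype,
    categories=RARE_CATEGORIES,
    rho_grid=DEFAULT_RHO_GRID,
    beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA,
) -> pd.DataFrame:
    """Burden and SKAT-O per gene x category plus the min-p combination.

    The vectorized hot path behind build_gene_table; equivalent to calling
    burden_test / skato_test gene by gene.
    """
    y = _as_values(phenotype)
    n = len(y)
    r = y - y.mean()
    sigma2 = float(r @ r) / (n - 1)
    sig = np.sqrt(sigma2)
    rho_grid = np.asarray(rho_grid, float)

    variants = panel.genome.variants
    gene_ids = panel.genome.genes["gene_id"].to_numpy()
    gene_block = dict(zip(panel.genome.genes["gene_id"], panel.genome.genes["block_id"]))
    v_gene = variants["gene_id"].to_numpy()
    v_cat = variants["category"].to_numpy()
    rare_ok = (variants["vclass"] == "rare").to_numpy() & ~panel.monomorphic

    rows = []
    for gene in gene_ids:
        in_gene = (v_gene == gene) & rare_ok
        cols_all = np.flatnonzero(in_gene)
        rec = {"gene_id": gene, "block_id": gene_block[gene]}
        pvals = {}
        if cols_all.size:
            g = panel.genotypes[:, cols_all].astype(float)
            w = maf_weights(panel.maf[cols_all], beta_shape)
            gc = g - g.mean(axis=0)
            z = gc * w
            scores_all = (z.T @ r) / sig
            cats_here = v_cat[cols_all]
            for cat in categories:
                sel = cats_here == cat
                if not sel.any():
                    rec[f"p_burden_{cat}"] = np.nan
                    rec[f"p_skato_{cat}"] = np.nan
                    continue
                pb = _burden_p(g[:, sel], w[sel], y)
                zc = z[:, sel]
                kernel = zc.T @ zc
                if kernel.diagonal().sum() <= 0:
                    ps = np.nan
                else:
                    ps, _, _ = skato_omnibus_p(kernel, scores_all[sel], rho_grid)
                rec[f"p_burden_{cat}"] = pb
                rec[f"p_skato_{cat}"] = ps
                pvals[f"burden_{cat}"] = pb
                pvals[f"skato_{cat}"] = ps
        else:
            for cat in categories:
                rec[f"p_burden_{cat}"] = np.nan
                rec[f"p_skato_{cat}"] = np.nan
        p_rare, n_tests, tie = combine_rare(pvals)
        rec["p_rare"] = p_rare
        rec["n_rare_tests"] = n_tests
        rec["rare_tie"] = tie
        rows.append(rec)
    return pd.DataFrame(rows)


def build_gene_table(
    panel: CohortPanel,
    phenotype,
    covariates: np.ndarray | None = None,
    categories=RARE_CATEGORIES,
    rho_grid=DEFAULT_RHO_GRID,
    beta_shape: tuple[float, float] = DEFAULT_WEIGHT_BETA,
) -> pd.DataFrame:
    """Full gene association table: P_common from the Brown-aggregated scan,
    P_rare from the min over burden/SKAT-O x categories."""
    snp = gwas_scan(panel, phenotype, covariates)
    common = gene_test_common(snp, panel.genome, panel)
    rare = rare_gene_scan(panel, phenotype, categories, rho_grid, beta_shape)
    return common.merge(rare.drop(columns="block_id"), on="gene_id", how="left")
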