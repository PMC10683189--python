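"""Synthetic cohort generation with block-diagonal LD structure.

Genotypes are produced by a latent-Gaussian threshold model: each of the two
haplotypes of an individual carries the minor allele wherever a latent
standard-normal variable exceeds the MAF-matched quantile.  Within an LD
block, latent variables share block-level factors so that variant dosages are
positively correlated; variants in different blocks are independent.  This
gives a controllable stand-in for real genotype panels with a known null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RARE_CATEGORIES = ("pLoF", "missense_LC", "synonymous")
DEFAULT_CATEGORY_PROPS = (0.2, 0.5, 0.3)


@dataclass(frozen=True)
class GenomeMap:
    """Gene/block/variant layout of a synthetic genome.

    ``variants`` has one row per variant with columns
    ``variant_id, gene_id, block_id, vclass ({common, rare}), category,
    target_maf``; ``genes`` maps every gene to exactly one block.
    Variants of a block occupy a contiguous index range.
    """

    genes: pd.DataFrame
    variants: pd.DataFrame
    maf_split: float

    @property
    def n_blocks(self) -> int:
        return int(self.genes["block_id"].nunique())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def block_slices(self) -> list[tuple[int, int]]:
        """(start, stop) index pairs per block, in block order."""
        codes = self.variants["block_id"].to_numpy()
        bounds = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1], True])
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def build_genome_map(
    n_blocks: int,
    genes_per_block: int,
    n_common_per_gene: int,
    n_rare_per_gene: int,
    maf_split: float = 0.01,
    seed: int = 0,
    category_props: tuple[float, float, float] = DEFAULT_CATEGORY_PROPS,
    rare_maf_floor: float = 1e-4,
) -> GenomeMap:
    """Lay out a genome of ``n_blocks`` LD blocks, each holding
    ``genes_per_block`` genes with the stated number of common and rare
    variants per gene.

    Target MAFs are drawn uniformly on [maf_split, 0.5] for common variants
    and on [rare_maf_floor, maf_split) for rare variants; cohort simulation
    may raise rare targets to the resolvable 1/(2n) floor.
    """
    for name, v in (
        ("n_blocks", n_blocks),
        ("genes_per_block", genes_per_block),
        ("n_common_per_gene", n_common_per_gene),
        ("n_rare_per_gene", n_rare_per_gene),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if not 0.0 < maf_split < 0.5:
        raise ValueError(f"maf_split must lie in (0, 0.5), got {maf_split}")
    if not np.isclose(sum(category_props), 1.0):
        raise ValueError("category_props must sum to 1")

    rng = np.random.default_rng(seed)
    n_genes = n_blocks * genes_per_block
    per_gene = n_common_per_gene + n_rare_per_gene

    gene_ids = np.array([f"g{str(i).zfill(5)}" for i in range(n_genes)])
    block_ids = np.repeat(np.arange(n_blocks), genes_per_block)
    genes = pd.DataFrame({"gene_id": gene_ids, "block_id": block_ids})

    v_gene = np.repeat(np.arange(n_genes), per_gene)
    is_common = np.tile(
        np.r_[np.ones(n_common_per_gene, bool), np.zeros(n_rare_per_gene, bool)],
        n_genes,
    )
    n_variants = n_genes * per_gene
    target = np.empty(n_variants)
    target[is_common] = rng.uniform(maf_split, 0.5, is_common.sum())
    target[~is_common] = rng.uniform(rare_maf_floor, maf_split, (~is_common).sum())

    category = np.full(n_variants, "", dtype=object)
    category[~is_common] = rng.choice(
        RARE_CATEGORIES, size=(~is_common).sum(), p=category_props
    )

    variants = pd.DataFrame(
        {
            "variant_id": [f"v{str(i).zfill(7)}" for i in range(n_variants)],
            "gene_id": gene_ids[v_gene],
            "block_id": block_ids[v_gene],
            "vclass": np.where(is_common, "common", "rare"),
            "category": category,
            "target_maf": target,
        }
    )
    return GenomeMap(genes=genes, variants=variants, maf_split=maf_split)


@dataclass
class CohortPanel:
    """Genotype dosages (individuals x variants, int8 in {0,1,2}) plus the
    realized per-variant allele frequencies and the genome layout."""

    genotypes: np.ndarray
    freq: np.ndarray  # realized frequency of the modelled (minor-target) allele
    genome: GenomeMap
    ld_scores: np.ndarray | None = field(default=None)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.freq, 1.0 - self.freq)

    @property
    def monomorphic(self) -> np.ndarray:
        return (self.freq <= 0.0) | (self.freq >= 1.0)

    def scaled(self, cols: np.ndarray) -> np.ndarray:
        """Column-standardized (mean 0, variance 1) dosages for ``cols``.

        Monomorphic columns are returned as zeros.
        """
        g = self.genotypes[:, cols].astype(np.float64)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0.0] = 1.0
        return (g - mu) / sd


def simulate_genotypes(
    genome: GenomeMap,
    n_individuals: int,
    seed: int = 0,
    rho_common: float = 0.3,
    rho_rare: float = 0.05,
) -> CohortPanel:
    """Draw a cohort of diploid dosages under the latent threshold model.

    ``rho_common`` is the latent correlation between two common variants of
    the same block; ``rho_rare`` the latent correlation between a rare
    variant and any other variant of its block.  Across blocks, variants are
    independent.  Rare target MAFs are raised to 1/(2 n) where needed so the
    expected minor-allele count is at least one.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not 0.0 <= rho_rare <= rho_common < 1.0:
        raise ValueError("need 0 <= rho_rare <= rho_common < 1")

    rng = np.random.default_rng(seed)
    m = genome.n_variants
    is_common = (genome.variants["vclass"] == "common").to_numpy()

    target = genome.variants["target_maf"].to_numpy().copy()
    floor = 1.0 / (2.0 * n_individuals)
    target[~is_common] = np.clip(target[~is_common], floor, None)
    thresh = stats.norm.isf(target).astype(np.float32)

    # factor loadings: common = sqrt(c)·f_block + sqrt(s)·h_block + noise,
    # rare = sqrt(s)·h_block + noise with s = rho_rare, c = rho_common - s.
    s_shared = np.sqrt(rho_rare, dtype=np.float32)
    s_comm = np.sqrt(rho_common - rho_rare).astype(np.float32)
    resid_c = np.sqrt(1.0 - rho_common).astype(np.float32)
    resid_r = np.sqrt(1.0 - rho_rare).astype(np.float32)

    slices = genome.block_slices()
    dosage = np.zeros((n_individuals, m), dtype=np.int8)
    for _hap in range(2):
        z = rng.standard_normal((n_individuals, m), dtype=np.float32)
        f = rng.standard_normal((n_individuals, len(slices)), dtype=np.float32)
        h = rng.standard_normal((n_individuals, len(slices)), dtype=np.float32)
        for b, (lo, hi) in enumerate(slices):
            blk = z[:, lo:hi]
            common_blk = is_common[lo:hi]
            blk *= np.where(common_blk, resid_c, resid_r)
            blk += h[:, b : b + 1] * s_shared
            blk[:, common_blk] += f[:, b : b + 1] * s_comm
        dosage += z > thresh

    freq = dosage.mean(axis=0, dtype=np.float64) / 2.0
    return CohortPanel(genotypes=dosage, freq=freq, genome=genome)


def compute_ld_scores(panel: CohortPanel) -> np.ndarray:
    """Per-variant LD score l_i = sum over same-block variants j (incl. i)
    of the squared sample Pearson correlation r^2_ij.

    Monomorphic variants get NaN (their correlation is undefined) and do not
    contribute to the sums of their block mates.  The result is cached on the
    panel.
    """
    if panel.n_individuals < 2:
        raise ValueError("need at least 2 individuals for LD scores")
    m = panel.n_variants
    ld = np.full(m, np.nan)
    n = panel.n_individuals
    for lo, hi in panel.genome.block_slices():
        cols = np.arange(lo, hi)
        poly = ~panel.monomorphic[cols]
        if not poly.any():
            continue
        z = panel.scaled(cols[poly])
        r = (z.T @ z) / n
        ld[cols[poly]] = (r**2).sum(axis=0)
    panel.ld_scores = ld
    return ld


def decorrelate_rare(panel: CohortPanel, seed: int = 0) -> CohortPanel:
    """Return a copy of the panel with every rare-variant column independently
    permuted across individuals (common columns bit-identical, marginal
    distributions and allele frequencies preserved)."""
    rng = np.random.default_rng(seed)
    g = panel.genotypes.copy()
    rare_cols = np.flatnonzero(
        (panel.genome.variants["vclass"] == "rare").to_numpy()
    )
    n = panel.n_individuals
    for j in rare_cols:
        g[:, j] = g[rng.permutation(n), j]
    return CohortPanel(genotypes=g, freq=panel.freq.copy(), genome=panel.genome)
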