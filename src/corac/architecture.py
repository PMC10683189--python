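"""Genetic architectures: causal-gene assignment, frequency-dependent effect
sizes, and phenotype simulation at fixed heritability.

The selection model ties the variance of a causal variant's standardized
effect to its allele frequency p and LD score l:

    Var(beta_i) = C * [p_i (1 - p_i)]^e * (1 / (1 + l_i))^r,   C = h2 / N_causal

with exponent ``e`` set by the parameterization: ``frequency-flat-neutral``
uses e = alpha (alpha = 0 makes the standardized effect-size distribution
independent of allele frequency, so per-variant explained heritability is
flat across the frequency spectrum; negative alpha concentrates heritability
in rare variants), while ``per-snp-h2`` uses the alternative e = 1 + alpha
(per-variant heritability proportional to [p(1-p)]^{1+alpha}; there the
neutral point of flat per-variant heritability sits at alpha = -1).  The
baseline mode ignores frequency entirely: Var(beta_i) = h2 / N_causal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .simulate import CohortPanel, GenomeMap, compute_ld_scores

EffectParameterization = Literal["frequency-flat-neutral", "per-snp-h2"]


@dataclass(frozen=True)
class ArchitectureParams:
    """Tunable architecture of the simulated trait."""

    h2_trait: float = 0.30
    prop_causal_genes: float = 0.10
    shared_causal_fraction: float = 0.50
    alpha: float = -0.37
    r: int = 0
    mode: Literal["selection", "baseline"] = "selection"
    causal_variant_fraction: float = 0.5
    effect_parameterization: EffectParameterization = "frequency-flat-neutral"
    n_causal: Optional[int] = None  # override for the C = h2/N scale; else realized

    def __post_init__(self):
        if not 0.0 <= self.h2_trait <= 1.0:
            raise ValueError("h2_trait must lie in [0, 1]")
        if not 0.0 < self.prop_causal_genes <= 1.0:
            raise ValueError("prop_causal_genes must lie in (0, 1]")
        if not 0.0 <= self.shared_causal_fraction <= 1.0:
            raise ValueError("shared_causal_fraction must lie in [0, 1]")
        if self.r not in (0, 1):
            raise ValueError("r must be 0 or 1")
        if self.mode not in ("selection", "baseline"):
            raise ValueError("mode must be 'selection' or 'baseline'")
        if not 0.0 < self.causal_variant_fraction <= 1.0:
            raise ValueError("causal_variant_fraction must lie in (0, 1]")

    def variance_exponent(self) -> float:
        if self.effect_parameterization == "frequency-flat-neutral":
            return self.alpha
        if self.effect_parameterization == "per-snp-h2":
            return 1.0 + self.alpha
        raise ValueError(
            f"unknown effect_parameterization {self.effect_parameterization!r}"
        )


@dataclass
class EffectVector:
    """Per-variant standardized causal effects (zero for non-causal)."""

    beta: np.ndarray
    causal: np.ndarray  # boolean mask

    @property
    def n_causal(self) -> int:
        return int(self.causal.sum())


@dataclass
class PhenotypeVector:
    """Quantitative trait values, standardized to mean 0 / variance 1."""

    values: np.ndarray
    h2_realized: float

    @property
    def n(self) -> int:
        return len(self.values)


def assign_causal_genes(
    genome: GenomeMap, params: ArchitectureParams, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the common-path and rare-path causal gene sets.

    Each set has round(prop_causal_genes * n_genes) genes.  A shared core of
    round(shared_causal_fraction * set_size) genes is causal on both paths;
    the remainders are disjoint.
    """
    rng = np.random.default_rng(seed)
    n_genes = genome.n_genes
    size = int(round(params.prop_causal_genes * n_genes))
    if size < 1:
        raise ValueError("prop_causal_genes * n_genes must be >= 1")
    core = int(round(params.shared_causal_fraction * size))
    needed = 2 * size - core
    if needed > n_genes:
        raise ValueError(
            f"causal construction needs {needed} genes but only {n_genes} exist"
        )
    ids = genome.genes["gene_id"].to_numpy()
    picked = rng.choice(n_genes, size=needed, replace=False)
    shared = picked[:core]
    common_only = picked[core:size]
    rare_only = picked[size:]
    common_set = np.sort(ids[np.r_[shared, common_only]])
    rare_set = np.sort(ids[np.r_[shared, rare_only]])
    return common_set, rare_set


def draw_effects(
    panel: CohortPanel,
    common_genes: np.ndarray,
    rare_genes: np.ndarray,
    params: ArchitectureParams,
    seed: int = 0,
) -> EffectVector:
    """Draw standardized causal effects for the causal genes' variants.

    Common-path causal genes receive effects on a fraction
    (``causal_variant_fraction``) of their polymorphic common variants;
    rare-path genes on their rare variants.  Selection mode applies the
    frequency/LD-dependent variance above; baseline mode draws every causal
    effect from N(0, h2 / N_causal).
    """
    rng = np.random.default_rng(seed)
    variants = panel.genome.variants
    gene = variants["gene_id"].to_numpy()
    vclass = variants["vclass"].to_numpy()
    poly = ~panel.monomorphic

    causal = np.zeros(panel.n_variants, dtype=bool)
    for genes_set, cls in ((common_genes, "common"), (rare_genes, "rare")):
        in_path = np.isin(gene, genes_set) & (vclass == cls) & poly
        idx = np.flatnonzero(in_path)
        if idx.size == 0:
            continue
        # choose the causal fraction within each gene
        order = np.argsort(gene[idx], kind="stable")
        idx = idx[order]
        _, starts = np.unique(gene[idx], return_index=True)
        stops = np.r_[starts[1:], idx.size]
        for lo, hi in zip(starts, stops):
            g_idx = idx[lo:hi]
            n_pick = max(1, int(round(params.causal_variant_fraction * g_idx.size)))
            causal[rng.choice(g_idx, size=n_pick, replace=False)] = True

    n_causal = int(causal.sum())
    if n_causal == 0:
        raise ValueError("no causal variants (N_trait = 0)")
    n_scale = params.n_causal if params.n_causal is not None else n_causal
    c_const = params.h2_trait / n_scale

    beta = np.zeros(panel.n_variants)
    if params.h2_trait == 0.0:
        return EffectVector(beta=beta, causal=causal)

    if params.mode == "baseline":
        var = np.full(n_causal, c_const)
    else:
        p = panel.freq[causal]
        var = c_const * (p * (1.0 - p)) ** params.variance_exponent()
        if params.r == 1:
            if panel.ld_scores is None:
                compute_ld_scores(panel)
            ld = panel.ld_scores[causal]
            if np.isnan(ld).any():
                raise ValueError("LD scores unavailable for some causal variants")
            var = var * (1.0 / (1.0 + ld))
    beta[causal] = rng.standard_normal(n_causal) * np.sqrt(var)
    return EffectVector(beta=beta, causal=causal)


def simulate_phenotype(
    panel: CohortPanel,
    effects: EffectVector,
    params: ArchitectureParams,
    seed: int = 0,
) -> PhenotypeVector:
    """y = G_s beta + eps, with the genetic component rescaled so that its
    realized variance share equals h2_trait exactly, then standardized."""
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    h2 = params.h2_trait

    cols = np.flatnonzero(effects.causal)
    if h2 > 0.0 and cols.size:
        g_scaled = panel.scaled(cols)
        genetic = g_scaled @ effects.beta[cols]
        v = genetic.var()
        if v <= 0.0:
            raise ValueError("genetic component has zero variance")
        genetic = genetic * np.sqrt(h2 / v)
    else:
        if h2 >= 1.0:
            raise ValueError("h2_trait = 1 requires a nonzero genetic component")
        genetic = np.zeros(n)

    noise_sd = np.sqrt(max(1.0 - h2, 0.0))
    y = genetic + rng.standard_normal(n) * noise_sd
    h2_real = genetic.var() / y.var() if y.var() > 0 else 0.0
    y = (y - y.mean()) / y.std()
    return PhenotypeVector(values=y, h2_realized=float(h2_real))
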