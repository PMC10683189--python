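"""Shared, session-scoped simulation fixtures.

The full-size sweeps are expensive (a few seconds per replicate), so each
sweep is run once per session and shared by every test that consumes it.
All fixtures are deterministic: they depend only on the fixed master seed
baked into the default SweepConfig.
"""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from corac import ArchitectureParams, SweepConfig, run_replicate

N_REPLICATES = 20
MASTER_SEED = 20240915


@pytest.fixture(scope="session")
def sweep_config():
    return SweepConfig(n_replicates=N_REPLICATES, master_seed=MASTER_SEED)


def _records(config, n_eff, arch=None, decorrelate=None):
    rows = []
    for rep in range(config.n_replicates):
        rows.append(
            run_replicate(
                config, n_eff, rep, architecture=arch, decorrelate=decorrelate
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def nsweep_records(sweep_config):
    """Sample-size sweep at the default architecture (alpha = -0.37)."""
    frames = [_records(sweep_config, n) for n in sweep_config.n_eff_grid]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def alpha_records(sweep_config, nsweep_records):
    """Selection-exponent sweep at n = 4000; the alpha = -0.37 group is
    reused from the sample-size sweep (identical seeds by construction)."""
    frames = [nsweep_records[nsweep_records.n_eff == 4000]]
    for alpha in (0.5, 0.0, -1.0):
        arch = replace(sweep_config.architecture, alpha=alpha)
        frames.append(_records(sweep_config, 4000, arch=arch))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def poly_records(sweep_config):
    """Polygenicity sweep at n = 2000."""
    frames = []
    for prop in (0.05, 0.20):
        arch = replace(sweep_config.architecture, prop_causal_genes=prop)
        frames.append(_records(sweep_config, 2000, arch=arch))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def decorrelated_records(sweep_config):
    """Decorrelated twin of the n = 4000 sample-size group: same stage seeds,
    rare-variant columns shuffled after the phenotype is drawn."""
    return _records(sweep_config, 4000, decorrelate=True)


@pytest.fixture(scope="session")
def null_gene_pvalues():
    """Gene-test p-values on null cohorts (h2 = 0): 2000 gene tests per
    statistic (burden, SKAT, SKAT-O over all rare variants pooled, and the
    Brown-aggregated common-variant test)."""
    from corac import (
        build_gene_table,
        build_genome_map,
        burden_test,
        simulate_genotypes,
        skat_test,
    )
    from corac.assoc import gene_test_common, gwas_scan, skato_test

    rng = np.random.default_rng(777)
    out = {"burden": [], "skat": [], "skato": [], "common": []}
    n_ind = 1500
    for chunk in range(4):
        genome = build_genome_map(500, 1, 4, 6, seed=1000 + chunk)
        panel = simulate_genotypes(genome, n_ind, seed=2000 + chunk)
        y = rng.standard_normal(n_ind)
        snp = gwas_scan(panel, y)
        common = gene_test_common(snp, genome, panel)
        out["common"].append(common["p_common"].to_numpy())
        for gene in genome.genes["gene_id"]:
            out["burden"].append(burden_test(panel, y, gene))
            out["skat"].append(skat_test(panel, y, gene))
            out["skato"].append(skato_test(panel, y, gene))
    return {
        "burden": np.asarray(out["burden"], float),
        "skat": np.asarray(out["skat"], float),
        "skato": np.asarray(out["skato"], float),
        "common": np.concatenate(out["common"]),
    }
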