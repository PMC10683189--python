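"""Readers and writers for cohort artifacts, gene tables and sweep configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .architecture import ArchitectureParams
from .experiments import SweepConfig
from .simulate import CohortPanel, GenomeMap, compute_ld_scores

PANEL_FORMAT_VERSION = 1


def write_panel(panel: CohortPanel, out_dir) -> None:
    """Write a cohort to ``out_dir``: variants.tsv (variant metadata incl.
    realized MAF and LD score), genotypes.npz (versioned dense dosage
    matrix), phenotype left to the caller."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if panel.ld_scores is None:
        compute_ld_scores(panel)
    v = panel.genome.variants.copy()
    v["maf"] = panel.maf
    v["ld_score"] = panel.ld_scores
    v["monomorphic"] = panel.monomorphic
    v.to_csv(out / "variants.tsv", sep="\t", index=False)
    panel.genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    np.savez_compressed(
        out / "genotypes.npz",
        dosage=panel.genotypes,
        freq=panel.freq,
        format_version=PANEL_FORMAT_VERSION,
    )


def read_panel(in_dir) -> CohortPanel:
    src = Path(in_dir)
    variants = pd.read_csv(src / "variants.tsv", sep="\t")
    genes = pd.read_csv(src / "genes.tsv", sep="\t")
    with np.load(src / "genotypes.npz") as z:
        if int(z["format_version"]) != PANEL_FORMAT_VERSION:
            raise ValueError("unsupported genotype archive version")
        dosage = z["dosage"]
        freq = z["freq"]
    maf_split = float(
        variants.loc[variants["vclass"] == "common", "target_maf"].min()
    )
    genome = GenomeMap(
        genes=genes,
        variants=variants[
            ["variant_id", "gene_id", "block_id", "vclass", "category", "target_maf"]
        ],
        maf_split=maf_split,
    )
    panel = CohortPanel(genotypes=dosage, freq=freq, genome=genome)
    if "ld_score" in variants:
        panel.ld_scores = variants["ld_score"].to_numpy(float)
    return panel


def write_phenotype(values: np.ndarray, path) -> None:
    pd.DataFrame(
        {"individual_id": np.arange(len(values)), "y": values}
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Gene-level association table (synthetic or externally produced);
    requires columns gene_id, block_id, p_common, p_rare."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "block_id", "p_common", "p_rare"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_sweep_config(path) -> SweepConfig:
    """SweepConfig from YAML; the ``architecture`` key maps to
    ArchitectureParams fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    arch = ArchitectureParams(**raw.pop("architecture", {}))
    known = {f.name for f in dataclasses.fields(SweepConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown sweep config keys: {sorted(unknown)}")
    return SweepConfig(architecture=arch, **raw)


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")
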