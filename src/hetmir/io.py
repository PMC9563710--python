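"""Readers/writers for the pipeline's tab-separated interchange files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import ROLES


def read_counts(path) -> pd.DataFrame:
    """miRNA x sample integer count matrix from TSV (first column = miRNA id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "mirna_id"
    return df.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="mirna_id")


def read_samples(path, genotype_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Sample table (sample_id, genotype, replicate); genotypes optionally
    remapped to the canonical roles P1/P2/H12/H21."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    if genotype_map:
        df["genotype"] = df["genotype"].map(lambda g: genotype_map.get(g, g))
    unknown = set(df["genotype"]) - set(ROLES) - {"A"}
    if unknown:
        raise ValueError(f"unmapped genotypes: {sorted(unknown)}")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_lay_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_targets(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"mirna_id": str, "gene_id": str, "aggregate_score": float},
    )


def read_gene_list(path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
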