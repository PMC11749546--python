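"""GWAS-catalog integration: risk genes among differential genes.

Associations from an NHGRI-EBI-style catalog export are filtered at a
genome-wide suggestive threshold (P < 1e-5, strict), monkey gene symbols
are converted to human symbols through a two-column homolog map, and
the surviving associations are joined per trait with the DE table.  The
result carries, per (stratum, gene), the expression log2FC alongside
-log10 of the gene's best retained association p-value — the data
behind a risk-gene dot plot.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import FormatError, ValidationError

CATALOG_COLUMNS = ("trait", "snp_id", "mapped_gene", "p_value")

# accepted aliases for NHGRI-EBI export headers
COLUMN_ALIASES = {
    "trait": ("trait", "DISEASE/TRAIT", "disease_trait"),
    "snp_id": ("snp_id", "SNPS", "snps", "variant_id"),
    "mapped_gene": ("mapped_gene", "MAPPED_GENE", "reported_gene"),
    "p_value": ("p_value", "P-VALUE", "pvalue"),
}


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                rename[alias] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"GWAS catalog lacks columns {missing}")
    return df


def load_catalog(path: str | Path) -> pd.DataFrame:
    """Load and validate a GWAS catalog TSV (unfiltered)."""
    df = _canonicalize_columns(pd.read_csv(path, sep="\t"))
    df = df.copy()
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    n_bad = int(df["p_value"].isna().sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} catalog rows with unparsable p-values",
                      stacklevel=2)
        df = df.dropna(subset=["p_value"])
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ValidationError("catalog p-values must lie in (0, 1]")
    if df["mapped_gene"].isna().any() or (df["mapped_gene"] == "").any():
        raise ValidationError("catalog rows with empty mapped_gene")
    if df.duplicated(subset=["trait", "snp_id"]).any():
        dup = df[df.duplicated(subset=["trait", "snp_id"])].head(3)
        raise ValidationError(
            f"duplicate (trait, snp_id) catalog rows, e.g. {dup[['trait', 'snp_id']].values.tolist()}"
        )
    return df.reset_index(drop=True)


def load_and_filter_catalog(
    path: str | Path,
    p_max: float = 1e-5,
    include_child_traits: bool = True,
) -> pd.DataFrame:
    """Catalog rows with ``p_value < p_max`` (strict).

    When the export carries an ``is_child`` column, child-trait rows are
    kept only if ``include_child_traits`` is set.
    """
    df = load_catalog(path)
    if "is_child" in df.columns and not include_child_traits:
        df = df[~df["is_child"].astype(bool)]
    return df[df["p_value"] < p_max].reset_index(drop=True)


def map_homologs(
    genes, homolog_table: str | Path | pd.DataFrame
) -> dict[str, str]:
    """Map source (monkey) symbols to human symbols via a two-column table.

    Genes absent from the table are dropped (reported via warning).
    Many source genes may share one human target; a source gene with
    conflicting targets in the table is an error.
    """
    if isinstance(homolog_table, pd.DataFrame):
        table = homolog_table.copy()
    else:
        table = pd.read_csv(homolog_table, sep="\t")
    if table.shape[1] < 2:
        raise FormatError("homolog table must have two columns (source, human)")
    table = table.iloc[:, :2]
    table.columns = ["source_gene", "human_gene"]
    table = table.drop_duplicates()
    counts = table["source_gene"].value_counts()
    conflicting = counts[counts > 1].index.tolist()
    if conflicting:
        raise ValidationError(
            f"source genes with conflicting human targets: {conflicting[:5]}"
        )
    lookup = dict(zip(table["source_gene"], table["human_gene"]))
    mapping = {g: lookup[g] for g in genes if g in lookup}
    dropped = [g for g in genes if g not in lookup]
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) absent from homolog table were dropped",
            stacklevel=2,
        )
    return mapping


def intersect_deg_gwas(
    degs: pd.DataFrame,
    catalog: pd.DataFrame,
    mapping: dict[str, str],
    trait: str,
    p_agg: str = "min",
) -> pd.DataFrame:
    """Join DEGs with a trait's (already filtered) associations.

    One output row per (organ, cell_type, gene); ``neg_log10_p`` is
    -log10 of the aggregated catalog p over the gene's retained SNPs
    (minimum by default, median optionally).  DEG statistics pass
    through unchanged; rows are sorted by (organ, cell_type, gene).
    """
    if p_agg not in ("min", "median"):
        raise ValidationError("p_agg must be 'min' or 'median'")
    out_cols = [
        "trait", "organ", "cell_type", "gene_monkey", "gene_human",
        "log2fc", "fdr", "neg_log10_p", "significant",
    ]
    sub = catalog[catalog["trait"] == trait]
    if not len(sub):
        warnings.warn(f"trait '{trait}' absent from filtered catalog", stacklevel=2)
        return pd.DataFrame(columns=out_cols)
    agg = sub.groupby("mapped_gene")["p_value"].min() if p_agg == "min" else (
        sub.groupby("mapped_gene")["p_value"].median()
    )
    degs = degs.copy()
    degs["gene_human"] = degs["gene"].map(mapping)
    joined = degs.dropna(subset=["gene_human"])
    joined = joined[joined["gene_human"].isin(agg.index)]
    if not len(joined):
        return pd.DataFrame(columns=out_cols)
    rows = pd.DataFrame(
        {
            "trait": trait,
            "organ": joined["organ"].values,
            "cell_type": joined["cell_type"].values,
            "gene_monkey": joined["gene"].values,
            "gene_human": joined["gene_human"].values,
            "log2fc": joined["log2fc"].values,
            "fdr": joined["fdr"].values,
            "neg_log10_p": -np.log10(agg.loc[joined["gene_human"]].values),
            "significant": joined["significant"].values,
        }
    )
    rows = rows.sort_values(["organ", "cell_type", "gene_monkey"], kind="mergesort")
    return rows.reset_index(drop=True)
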