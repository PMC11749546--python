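"""Core data containers, on-disk formats and run configuration.

The pipeline exchanges data in plain-text formats throughout: Matrix
Market coordinate files with features/barcodes sidecars for counts
(CellRanger-style triplet layout), and tab-separated tables for cell
metadata, differential-expression results, GWAS associations and
homolog maps.  Counts are always held in memory as a sparse
genes x cells integer matrix regardless of the on-disk orientation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

GROUP_LABELS = ("normal", "estrogen")

META_COLUMNS = ("cell_id", "sample_id", "organ", "group", "cell_type")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DimensionError(ValueError):
    """Matrix dimensions disagree with the sidecar id lists."""


class ValidationError(ValueError):
    """Semantically invalid content (labels, duplicates, missing rows)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CountMatrix:
    """Sparse UMI count matrix (genes x cells) with per-cell metadata.

    ``cell_meta`` is indexed by cell barcode and carries ``sample_id``,
    ``organ``, ``group`` (one of :data:`GROUP_LABELS`) and ``cell_type``,
    aligned with ``cell_ids``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise DimensionError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative count entries")
        missing = [c for c in self.cell_ids if c not in self.cell_meta.index]
        if missing:
            raise ValidationError(
                f"cells absent from metadata: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        for col in META_COLUMNS[1:]:
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell metadata lacks column '{col}'")
        # align metadata rows with matrix columns
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        bad = set(self.cell_meta["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        """Return a new matrix restricted to the given cells (mask or ids)."""
        if isinstance(mask_or_ids, (list, tuple, pd.Index)):
            idx = [self.cell_ids.index(c) for c in mask_or_ids]
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        cell_ids = [self.cell_ids[i] for i in idx]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=cell_ids,
            counts=self.counts[:, idx].tocsr(),
            cell_meta=self.cell_meta.loc[cell_ids],
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta.equals(other.cell_meta)
        )


def _read_id_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_count_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
) -> CountMatrix:
    """Read an MTX triplet file with sidecars and a cell-metadata table.

    The on-disk matrix may be genes x cells or cells x genes; orientation
    is inferred from the lengths of the two id lists and canonicalized to
    genes x cells.
    """
    mtx_path = Path(mtx_path)
    try:
        rows, cols, _entries, fmt, fld, _sym = scipy.io.mminfo(mtx_path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    if fmt != "coordinate" or fld not in ("integer", "real"):
        raise FormatError(
            f"{mtx_path}: expected a coordinate integer matrix, got {fmt}/{fld}"
        )
    mat = sp.coo_matrix(scipy.io.mmread(mtx_path))
    genes = _read_id_column(Path(features_path))
    cells = _read_id_column(Path(barcodes_path))
    if mat.shape == (len(genes), len(cells)):
        counts = mat.tocsr()
    elif mat.shape == (len(cells), len(genes)):
        counts = mat.T.tocsr()
    else:
        raise DimensionError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(genes)} genes x {len(cells)} cells nor its transpose"
        )
    if not np.issubdtype(counts.dtype, np.integer):
        data = counts.data
        if not np.allclose(data, np.round(data)):
            raise ValidationError("non-integer count entries")
        counts = counts.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata table lacks columns {missing_cols}")
    meta = meta.set_index("cell_id")
    return CountMatrix(genes, cells, counts.astype(np.int64), meta)


def write_count_matrix(cm: CountMatrix, outdir: str | Path, prefix: str = "") -> dict:
    """Write MTX + features/barcodes/metadata under ``outdir``; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / f"{prefix}matrix.mtx",
        "features": outdir / f"{prefix}features.tsv",
        "barcodes": outdir / f"{prefix}barcodes.tsv",
        "meta": outdir / f"{prefix}cell_meta.tsv",
    }
    scipy.io.mmwrite(paths["mtx"], cm.counts.tocoo(), field="integer")
    pd.Series(cm.gene_ids).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    cm.cell_meta.reset_index(names="cell_id").to_csv(paths["meta"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
) -> Path:
    """Write a table as UTF-8 TSV with a header and deterministic row order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records.copy()
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their default values.

    Defaults follow the analysis conventions the pipeline implements:
    cells are kept when they detect between 200 and 4000 genes (inclusive)
    and at most 20% mitochondrial UMIs; per-sample NMF genes must have a
    log-expression standard deviation of at least 0.5; DEGs require
    BH-FDR < 0.05 and |log2FC| > 0.25 (both strict); GWAS associations
    are kept at P < 1e-5 (strict).
    """

    # cell QC
    min_genes: int = 200
    max_genes: int = 4000
    max_mito_frac: float = 0.20
    mito_prefix: str = "MT-"
    # per-sample NMF
    k_min: int = 2
    k_max: int = 9
    n_restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-5
    sd_min: float = 0.5
    # meta-programs
    top_n_corr: int = 50
    pool_n: int = 100
    marker_n: int = 30
    cut_distance: float = 0.8
    # differential expression
    fdr_max: float = 0.05
    lfc_min: float = 0.25
    min_cells_per_group: int = 3
    pseudo: float = 1e-9
    # GWAS
    p_max: float = 1e-5
    gwas_p_agg: str = "min"
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "min_genes": self.min_genes,
            "max_genes": self.max_genes,
            "max_mito_frac": self.max_mito_frac,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "sd_min": self.sd_min,
            "top_n_corr": self.top_n_corr,
            "pool_n": self.pool_n,
            "marker_n": self.marker_n,
            "fdr_max": self.fdr_max,
            "lfc_min": self.lfc_min,
            "min_cells_per_group": self.min_cells_per_group,
            "pseudo": self.pseudo,
            "p_max": self.p_max,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValidationError(f"config field {name} must be > 0, got {value}")
        if self.max_genes < self.min_genes:
            raise ValidationError("max_genes < min_genes")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError(
                f"k range [{self.k_min}, {self.k_max}] invalid: need 2 <= k_min <= k_max"
            )
        if self.cut_distance < 0:
            raise ValidationError("cut_distance must be >= 0")
        if self.gwas_p_agg not in ("min", "median"):
            raise ValidationError("gwas_p_agg must be 'min' or 'median'")

    @property
    def k_range(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def write_run_log(path: str | Path, payload: dict) -> Path:
    """Write the machine-readable run log (JSON, sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
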