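"""Cell-level quality control and normalization.

QC keeps cells detecting between ``min_genes`` and ``max_genes`` genes
(inclusive bounds; the removal rules "fewer than 200" / "more than 4000"
are strict) whose mitochondrial UMI fraction does not exceed
``max_mito``.  Normalization is library-size scaling to 10,000 counts
per cell followed by a natural-log ``log1p`` transform (CP10K).  For
program discovery the log-normalized matrix is converted to relative
expression: each gene is centered across cells and negative values are
clipped to zero, giving the non-negative input NMF requires.  Genes
whose log-expression standard deviation (computed before clipping,
within the sample) falls below ``sd_min`` are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_core import CountMatrix, ValidationError

TRANSFORM_LOG1P = "log1p_cp10k"
TRANSFORM_RELATIVE = "relative_nonneg"


@dataclass
class NormalizedMatrix:
    """Dense real-valued genes x cells matrix with a transform tag."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    transform_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match id lists"
            )


def mito_gene_mask(gene_ids: list[str], mito_prefix: str) -> np.ndarray:
    """Boolean mask of mitochondrial genes (case-insensitive prefix match)."""
    prefix = mito_prefix.lower()
    return np.array([g.lower().startswith(prefix) for g in gene_ids], dtype=bool)


def filter_cells(
    m: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 4000,
    max_mito: float = 0.20,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, dict]:
    """Apply the three cell filters; return the filtered matrix and a report.

    A cell is retained iff ``min_genes <= detected genes <= max_genes``
    and its mitochondrial UMI fraction is ``<= max_mito``.  "Detected"
    means count > 0.  The report counts removals per rule (a cell
    violating several rules is counted under each).
    """
    counts = m.counts.tocsc()
    counts.eliminate_zeros()
    detected = np.diff(counts.indptr)  # genes with count > 0, per cell
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito = mito_gene_mask(m.gene_ids, mito_prefix)
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low = detected < min_genes
    high = detected > max_genes
    mito_bad = mito_frac > max_mito
    keep = ~(low | high | mito_bad)
    report = {
        "n_input": int(m.shape[1]),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_high_mito": int(mito_bad.sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    return m.subset_cells(keep), report


def normalize_log1p_cp10k(m: CountMatrix) -> NormalizedMatrix:
    """CP10K + log1p: value(g, c) = ln(1 + 10000 * count(g, c) / total(c))."""
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValidationError(f"zero-total cells cannot be normalized: {names}")
    X = m.counts.astype(float).toarray()
    X = np.log1p(X * (1e4 / totals))
    return NormalizedMatrix(list(m.gene_ids), list(m.cell_ids), X, TRANSFORM_LOG1P)


def relative_expression_nonneg(m: NormalizedMatrix) -> NormalizedMatrix:
    """Center each gene across cells, then clip negatives to zero."""
    if m.transform_tag != TRANSFORM_LOG1P:
        raise ValidationError(
            f"relative expression expects {TRANSFORM_LOG1P} input, got {m.transform_tag}"
        )
    X = m.values - m.values.mean(axis=1, keepdims=True)
    np.clip(X, 0.0, None, out=X)
    return NormalizedMatrix(list(m.gene_ids), list(m.cell_ids), X, TRANSFORM_RELATIVE)


def filter_low_variance_genes(
    m: NormalizedMatrix, sd_min: float = 0.5
) -> NormalizedMatrix:
    """Drop genes whose log-expression SD is strictly below ``sd_min``.

    The SD is a population standard deviation (ddof=0) over the cells of
    this sample, computed on the log-normalized values before any
    centering/clipping.
    """
    if m.transform_tag != TRANSFORM_LOG1P:
        raise ValidationError("SD filter must run on log-normalized (pre-clip) values")
    sd = m.values.std(axis=1, ddof=0)
    keep = sd >= sd_min  # removal rule "sd < sd_min" is strict
    if not keep.any():
        raise ValidationError(f"all genes removed by SD >= {sd_min} filter")
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return NormalizedMatrix(genes, list(m.cell_ids), m.values[keep], m.transform_tag)
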