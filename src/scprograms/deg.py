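"""Differential expression between estrogen and normal groups.

Testing is stratified: within each (organ, cell type) stratum that has
at least ``min_cells_per_group`` cells in both groups, every gene is
tested with the two-sided Wilcoxon rank-sum test on log-normalized
expression, and p-values are BH-adjusted within the stratum.  The
fold change is computed on de-logged expression means:
``log2((mean(expm1(x)) + pseudo) / (mean(expm1(y)) + pseudo))``.
A gene is flagged significant when FDR < ``fdr_max`` and
|log2FC| > ``lfc_min`` (both strict); up/down direction is reported so
either a signed or an absolute fold-change reading can be recovered.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_core import ValidationError
from .qc import TRANSFORM_LOG1P, NormalizedMatrix

EXACT_MAX_N = 12  # exact rank-sum enumeration limit (no ties)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Uses exact enumeration of the rank-sum distribution when the pooled
    sample is small (n1 + n2 <= 12) and tie-free; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    n = x.size + y.size
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_MAX_N and not has_ties:
        return w, _exact_rank_sum_p(w, x.size, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    return w, (1.0 if np.isnan(p) else min(p, 1.0))


def _exact_rank_sum_p(w: float, n1: int, n: int) -> float:
    """P(|W - E[W]| >= |w - E[W]|) over all C(n, n1) rank assignments."""
    mean = n1 * (n + 1) / 2.0
    dev = abs(w - mean)
    total = comb(n, n1)
    extreme = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        if abs(sum(combo) - mean) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def log2_fold_change(x_treated, y_control, pseudo: float = 1e-9) -> float:
    """log2 FC of de-logged mean expression (inputs are log1p-CP10K values)."""
    mx = float(np.expm1(np.asarray(x_treated, dtype=float)).mean())
    my = float(np.expm1(np.asarray(y_control, dtype=float)).mean())
    return float(np.log2((mx + pseudo) / (my + pseudo)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stratum_pvalues(xt: np.ndarray, xc: np.ndarray) -> np.ndarray:
    """Per-gene Wilcoxon p for a treated/control matrix pair (genes x cells)."""
    n = xt.shape[1] + xc.shape[1]
    if n <= EXACT_MAX_N:
        return np.array(
            [wilcoxon_rank_sum(xt[g], xc[g])[1] for g in range(xt.shape[0])]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.mannwhitneyu(
            xt, xc, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
    # constant genes have zero rank variance -> undefined z; no separation
    pooled = np.concatenate([xt, xc], axis=1)
    constant = np.ptp(pooled, axis=1) == 0
    p[constant | np.isnan(p)] = 1.0
    return np.minimum(p, 1.0)


def compute_degs(
    m: NormalizedMatrix,
    meta: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 0.25,
    min_cells_per_group: int = 3,
    pseudo: float = 1e-9,
) -> pd.DataFrame:
    """Stratified DE table over all (organ, cell_type) strata.

    ``meta`` must be indexed by cell id (aligned with ``m.cell_ids``)
    and carry ``organ``, ``group`` and ``cell_type``.  Strata missing a
    group, or with fewer than ``min_cells_per_group`` cells in either
    group, are skipped.  Returns one row per (organ, cell_type, gene),
    sorted, with a ``significant`` flag.
    """
    if m.transform_tag != TRANSFORM_LOG1P:
        raise ValidationError("compute_degs expects log1p_cp10k-normalized input")
    meta = meta.loc[m.cell_ids]
    groups = set(meta["group"])
    if not {"normal", "estrogen"} <= groups:
        raise ValidationError(f"both group labels required, found {sorted(groups)}")
    col_index = {c: i for i, c in enumerate(m.cell_ids)}
    rows = []
    strata = sorted(set(zip(meta["organ"], meta["cell_type"])))
    for organ, cell_type in strata:
        in_stratum = (meta["organ"] == organ) & (meta["cell_type"] == cell_type)
        treated_ids = meta.index[in_stratum & (meta["group"] == "estrogen")]
        control_ids = meta.index[in_stratum & (meta["group"] == "normal")]
        if len(treated_ids) < min_cells_per_group or len(control_ids) < min_cells_per_group:
            continue
        xt = m.values[:, [col_index[c] for c in treated_ids]]
        xc = m.values[:, [col_index[c] for c in control_ids]]
        p = _stratum_pvalues(xt, xc)
        fdr = bh_adjust(p)
        et, ec = np.expm1(xt).mean(axis=1), np.expm1(xc).mean(axis=1)
        lfc = np.log2((et + pseudo) / (ec + pseudo))
        for g, gene in enumerate(m.gene_ids):
            rows.append(
                {
                    "organ": organ,
                    "cell_type": cell_type,
                    "gene": gene,
                    "log2fc": float(lfc[g]),
                    "p": float(p[g]),
                    "fdr": float(fdr[g]),
                    "n_treated": int(len(treated_ids)),
                    "n_control": int(len(control_ids)),
                    "direction": "up" if lfc[g] >= 0 else "down",
                    "significant": bool(fdr[g] < fdr_max and abs(lfc[g]) > lfc_min),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "organ", "cell_type", "gene", "log2fc", "p", "fdr",
            "n_treated", "n_control", "direction", "significant",
        ],
    )
    if len(df):
        df = df.sort_values(["organ", "cell_type", "gene"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def deg_count_summary(degs: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum counts of significant up/down genes (bar-plot analogue)."""
    if not len(degs):
        return pd.DataFrame(columns=["organ", "cell_type", "n_up", "n_down", "n_deg"])
    sig = degs[degs["significant"]]
    out = []
    for (organ, ct), grp in degs.groupby(["organ", "cell_type"], sort=True):
        s = sig[(sig["organ"] == organ) & (sig["cell_type"] == ct)]
        n_up = int((s["direction"] == "up").sum())
        n_down = int((s["direction"] == "down").sum())
        out.append(
            {"organ": organ, "cell_type": ct, "n_up": n_up, "n_down": n_down,
             "n_deg": n_up + n_down}
        )
    return pd.DataFrame(out)
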