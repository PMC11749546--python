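"""Per-sample NMF expression programs with consensus rank selection.

The factorization minimizes the Frobenius reconstruction error
``||X - WH||_F`` by multiplicative updates (Lee & Seung), with a small
epsilon guard in the denominators.  Rank ``k`` is chosen by the
consensus-clustering criterion: repeated factorizations from different
random starts each assign every cell to its argmax-usage program; the
cell x cell co-assignment frequencies form a consensus matrix, and the
cophenetic correlation between the induced distances (1 - consensus)
and their average-linkage dendrogram measures how stable the k-way
decomposition is.  The most stable k in the candidate range wins, ties
going to the smaller rank.

Each factor ("program" / "metagene") is summarized by its gene-loading
vector; genes are ranked by loading (ties broken by gene id) and the
top-50 set is kept for cross-sample program comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io_core import ValidationError

_EPS = 1e-10


@dataclass
class Factorization:
    """One NMF fit: X (genes x cells) ~ W (genes x k) @ H (k x cells)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: np.ndarray
    seed: int


@dataclass
class Program:
    """One NMF factor: genes ranked by loading, descending."""

    program_id: str
    genes: list[str]          # all genes, ranked by loading desc, ties by id
    loadings: np.ndarray      # aligned with ``genes``
    sample_id: str = ""

    def top_genes(self, n: int) -> list[str]:
        return self.genes[:n]

    @property
    def loading_vector(self) -> pd.Series:
        """Full loading vector indexed by gene id (unranked lookup)."""
        return pd.Series(self.loadings, index=self.genes)


@dataclass
class ProgramSet:
    """All programs of one sample at the selected rank."""

    sample_id: str
    factorization: Factorization
    cophenetic: dict[int, float]
    programs: list[Program] = field(default_factory=list)


def _init_wh(
    shape: tuple[int, int], k: int, rng: np.random.Generator, mean_x: float
) -> tuple[np.ndarray, np.ndarray]:
    # uniform(0,1) scaled so that W @ H starts near the data magnitude
    scale = np.sqrt(max(mean_x, _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(shape[0], k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, shape[1])) * scale
    return W, H


def _mu_factorize(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    track_trace: bool = True,
    stop_on_stable_assignment: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update loop; returns (W, H, objective trace).

    ``stop_on_stable_assignment`` additionally stops once the per-cell
    argmax-usage labels have been unchanged over two consecutive
    10-iteration checks — sufficient for consensus construction, where
    only the labels matter.
    """
    W, H = _init_wh(X.shape, k, rng, float(X.mean()))
    trace = []
    prev_obj = None
    prev_labels = None
    stable_checks = 0
    for it in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(X - W @ H))
        if track_trace:
            trace.append(obj)
        if prev_obj is not None and prev_obj > 0:
            if (prev_obj - obj) / prev_obj < tol:
                break
        prev_obj = obj
        if stop_on_stable_assignment and (it + 1) % 10 == 0:
            labels = H.argmax(axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stable_checks += 1
                if stable_checks >= 2:
                    break
            else:
                stable_checks = 0
            prev_labels = labels
    return W, H, np.asarray(trace)


def _normalize_scale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve NMF scale indeterminacy: unit-L2 columns of W, H rescaled."""
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms, H * norms[:, None]


def nmf_factorize(
    X: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Factorization:
    """Factorize a non-negative matrix at rank ``k``, deterministically in seed."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("X contains non-finite entries")
    if X.min() < 0:
        raise ValidationError("X contains negative entries")
    if k < 1 or k >= min(X.shape):
        raise ValidationError(f"k={k} out of range for shape {X.shape}")
    rng = np.random.default_rng(seed)
    W, H, trace = _mu_factorize(X, k, rng, max_iter, tol)
    W, H = _normalize_scale(W, H)
    return Factorization(W=W, H=H, k=k, objective_trace=trace, seed=seed)


def _subseeds(seed: int, n: int, salt: int = 0) -> list[int]:
    ss = np.random.SeedSequence([int(seed), int(salt)])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def consensus_cophenetic(
    X: np.ndarray,
    k: int,
    n_restarts: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> float:
    """Stability of the rank-k decomposition via the cophenetic coefficient.

    Runs ``n_restarts`` factorizations from distinct seeded starts, builds
    the cell x cell consensus (co-assignment frequency of argmax-usage
    labels), and returns the cophenetic correlation between 1 - consensus
    and the ultrametric distances of its average-linkage dendrogram.
    """
    X = np.asarray(X, dtype=float)
    if n_restarts < 10:
        raise ValidationError(f"n_restarts must be >= 10, got {n_restarts}")
    n_cells = X.shape[1]
    consensus = np.zeros((n_cells, n_cells))
    for sub in _subseeds(seed, n_restarts, salt=k):
        rng = np.random.default_rng(sub)
        _, H, _ = _mu_factorize(
            X, k, rng, max_iter, tol, track_trace=False, stop_on_stable_assignment=True
        )
        labels = H.argmax(axis=0)
        consensus += labels[:, None] == labels[None, :]
    consensus /= n_restarts
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.size == 0 or np.ptp(condensed) < 1e-12:
        warnings.warn(
            f"degenerate consensus at k={k}: all cell pairs co-assigned identically",
            stacklevel=2,
        )
        return 1.0
    Z = sch.average(condensed)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef, _ = sch.cophenet(Z, condensed)
    if not np.isfinite(coef):
        warnings.warn(f"undefined cophenetic coefficient at k={k}", stacklevel=2)
        return 1.0
    return float(coef)


def cophenetic_profile(
    X: np.ndarray,
    k_range: list[int],
    n_restarts: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> dict[int, float]:
    """Cophenetic coefficient for every candidate rank."""
    if not k_range:
        raise ValidationError("k_range is empty")
    return {
        k: consensus_cophenetic(X, k, n_restarts, seed, max_iter=max_iter, tol=tol)
        for k in sorted(k_range)
    }


def choose_rank(profile: dict[int, float]) -> int:
    """Rank with the maximal cophenetic coefficient; ties -> smallest k."""
    best_k, best_c = None, -np.inf
    for k in sorted(profile):
        if profile[k] > best_c:
            best_k, best_c = k, profile[k]
    return int(best_k)


def select_rank(
    X: np.ndarray,
    k_range: list[int],
    n_restarts: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> int:
    """Pick the most consensus-stable rank from ``k_range``."""
    if len(k_range) == 1:
        return int(k_range[0])
    return choose_rank(
        cophenetic_profile(X, k_range, n_restarts, seed, max_iter=max_iter, tol=tol)
    )


def extract_programs(
    f: Factorization,
    gene_ids: list[str],
    sample_id: str = "",
    n_top: int = 50,
    cophenetic: dict[int, float] | None = None,
) -> ProgramSet:
    """Turn each factor of a fit into a ranked gene program.

    Genes are ordered by loading descending with lexicographic gene-id
    tie-breaks; ``n_top`` only documents the comparison set size, the
    full ranking is retained.
    """
    if f.W.shape[0] != len(gene_ids):
        raise ValidationError("gene id list does not match W rows")
    programs = []
    gene_arr = np.asarray(gene_ids)
    for p in range(f.k):
        loadings = f.W[:, p]
        order = np.lexsort((gene_arr, -loadings))
        programs.append(
            Program(
                program_id=f"{sample_id + '_' if sample_id else ''}P{p + 1}",
                genes=[gene_ids[i] for i in order],
                loadings=loadings[order].copy(),
                sample_id=sample_id,
            )
        )
    return ProgramSet(
        sample_id=sample_id,
        factorization=f,
        cophenetic=dict(cophenetic or {}),
        programs=programs,
    )
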