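"""Meta-program (MP) distillation across samples.

Programs from all samples are compared on the union gene space: each
program contributes its full loading vector, zero-filled for genes its
sample did not retain.  Pairwise distance is 1 - Pearson correlation of
these vectors; average-linkage hierarchical clustering cut at a fixed
distance partitions the programs into MPs (singletons allowed).

Each MP's gene score aggregates its members' loadings: pool every
member's top-``pool_n`` genes; a gene's score is the sum of its
loadings over the members whose top list contains it, divided by the
number of members in the MP (so a gene shared by all members keeps its
average loading, while a member-exclusive gene is down-weighted).  The
``marker_n`` highest-scoring genes are the MP's markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io_core import ValidationError
from .nmf import Program, ProgramSet


@dataclass
class ProgramDistance:
    """Pairwise 1 - Pearson distances between programs."""

    labels: list[tuple[str, str]]  # (sample_id, program_id)
    matrix: np.ndarray
    programs: list[Program] = field(default_factory=list)


@dataclass
class MetaProgram:
    mp_id: str
    members: list[Program]
    gene_scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    markers: list[str] = field(default_factory=list)

    @property
    def member_samples(self) -> set[str]:
        return {p.sample_id for p in self.members}


def _flatten_programs(programs) -> list[Program]:
    flat: list[Program] = []
    for item in programs:
        if isinstance(item, ProgramSet):
            flat.extend(item.programs)
        else:
            flat.append(item)
    return flat


def program_distance_matrix(programs) -> ProgramDistance:
    """1 - Pearson correlation of full loading vectors on the gene union.

    Accepts ``ProgramSet``s and/or bare ``Program``s.  A program with
    zero variance on the union space cannot be correlated; its distances
    are set to the maximum (2) with a warning.
    """
    flat = _flatten_programs(programs)
    if len(flat) < 2:
        raise ValidationError("need at least 2 programs for a distance matrix")
    union = sorted(set().union(*(p.genes for p in flat)))
    V = np.zeros((len(flat), len(union)))
    index = {g: j for j, g in enumerate(union)}
    for i, p in enumerate(flat):
        for g, w in zip(p.genes, p.loadings):
            V[i, index[g]] = w
    sd = V.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} program(s) have zero loading variance; "
            "distances set to 2",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V)
    D = 1.0 - corr
    D[degenerate, :] = 2.0
    D[:, degenerate] = 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    labels = [(p.sample_id, p.program_id) for p in flat]
    return ProgramDistance(labels=labels, matrix=D, programs=flat)


def cluster_programs(d: ProgramDistance, cut_distance: float) -> list[MetaProgram]:
    """Average-linkage clustering cut at ``cut_distance``; members only.

    MPs are ordered by (number of members desc, first member label) and
    named MP1, MP2, ...  Membership is a partition: every program lands
    in exactly one MP.
    """
    n = len(d.programs)
    if n == 1:
        return [MetaProgram(mp_id="MP1", members=list(d.programs))]
    condensed = squareform(d.matrix, checks=False)
    Z = sch.average(condensed)
    flat = sch.fcluster(Z, t=cut_distance, criterion="distance")
    clusters: dict[int, list[Program]] = {}
    for lab, prog in zip(flat, d.programs):
        clusters.setdefault(int(lab), []).append(prog)
    ordered = sorted(
        clusters.values(),
        key=lambda ms: (-len(ms), ms[0].sample_id, ms[0].program_id),
    )
    return [
        MetaProgram(mp_id=f"MP{i + 1}", members=members)
        for i, members in enumerate(ordered)
    ]


def score_metaprogram(
    members: list[Program],
    pool_n: int = 100,
    marker_n: int = 30,
    mp_id: str = "MP1",
) -> MetaProgram:
    """Aggregate member loadings into MP gene scores and top markers.

    Pool each member's top-``pool_n`` genes.  For a gene found in the
    top lists of t members, score = (sum of its loadings over those t
    members) / m where m = number of members; a gene in exactly one list
    keeps its single loading divided by m.  Genes are ranked by score
    descending (ties by gene id); the first ``marker_n`` are markers.
    """
    if not members:
        raise ValidationError("meta-program needs at least one member")
    m = len(members)
    scores: dict[str, float] = {}
    for prog in members:
        top = prog.genes[:pool_n]
        for g, w in zip(top, prog.loadings[:pool_n]):
            scores[g] = scores.get(g, 0.0) + float(w)
    series = pd.Series({g: s / m for g, s in scores.items()}, dtype=float)
    ranked = series.sort_index().sort_values(ascending=False, kind="mergesort")
    markers = ranked.index[: min(marker_n, len(ranked))].tolist()
    return MetaProgram(mp_id=mp_id, members=list(members), gene_scores=ranked, markers=markers)


def build_metaprograms(
    programs,
    cut_distance: float = 0.8,
    pool_n: int = 100,
    marker_n: int = 30,
) -> list[MetaProgram]:
    """Distance -> clustering -> scoring in one call."""
    d = program_distance_matrix(programs)
    mps = cluster_programs(d, cut_distance)
    return [
        score_metaprogram(mp.members, pool_n=pool_n, marker_n=marker_n, mp_id=mp.mp_id)
        for mp in mps
    ]


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def mp_recovery_report(
    mps: list[MetaProgram], truth_programs: dict[str, set]
) -> pd.DataFrame:
    """Match each planted gene set to its best MP by top-marker Jaccard.

    Only meaningful on synthetic data where the planted program -> gene
    set map is known.  Reports, per planted program, the best-matching
    MP, the Jaccard overlap of the MP markers with the planted set, and
    how many distinct samples contribute members to that MP.
    """
    rows = []
    for name in sorted(truth_programs):
        genes = set(truth_programs[name])
        best_mp, best_j = None, -1.0
        for mp in mps:
            j = jaccard(mp.markers, genes)
            if j > best_j:
                best_mp, best_j = mp, j
        rows.append(
            {
                "true_program": name,
                "best_mp": best_mp.mp_id if best_mp else "",
                "jaccard_top_markers": best_j,
                "n_member_samples": len(best_mp.member_samples) if best_mp else 0,
                "n_members": len(best_mp.members) if best_mp else 0,
            }
        )
    return pd.DataFrame(rows)
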