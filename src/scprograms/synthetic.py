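"""Synthetic multi-sample scRNA-seq data with planted ground truth.

The generator emulates the structure the pipeline is built to recover:

* a bank of shared gene programs (disjoint, or overlapping up to a
  configured Jaccard), each a non-negative loading vector over a gene
  universe;
* per-sample count matrices whose cells mix shared programs, optional
  sample-private programs and one dense low-magnitude background
  program through Dirichlet usage weights, with counts drawn Poisson
  (or negative-binomial when a dispersion is given) around
  loading-weighted expected expression at a target library size;
* mitochondrial pseudo-genes whose per-cell UMI fraction follows a Beta
  distribution with a controllable tail above the QC cutoff;
* group-specific differential expression planted by binomial thinning /
  Poisson boosting of chosen genes in the estrogen group;
* a toy GWAS catalog with an exact number of sub-threshold
  associations, and an identity homolog map.

Every product comes with a ground-truth record sufficient to score
recovery without re-reading generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import (
    CountMatrix,
    ValidationError,
    write_count_matrix,
    write_table,
)

DEFAULT_ORGANS = ("uterus", "lung", "breast", "liver", "colon")


@dataclass
class ProgramBank:
    """Shared "true" programs: loading matrix over a fixed gene universe."""

    gene_ids: list[str]
    loadings: np.ndarray           # genes x n_meta, zero outside member sets
    gene_sets: list[set] = field(default_factory=list)

    @property
    def n_meta(self) -> int:
        return self.loadings.shape[1]


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    usage: pd.DataFrame | None = None             # cells x programs
    program_genes: dict[str, set] = field(default_factory=dict)
    de_truth: pd.DataFrame | None = None          # gene, cell_type, true_log2fc
    gwas_truth: pd.DataFrame | None = None        # trait, n_below_threshold


def generate_program_bank(
    n_genes: int,
    n_meta: int,
    genes_per_program: int,
    seed: int,
    max_overlap: float = 0.0,
    gene_ids: list[str] | None = None,
) -> ProgramBank:
    """Draw ``n_meta`` programs of ``genes_per_program`` member genes each.

    With ``max_overlap = 0`` the member sets are pairwise disjoint (and
    must fit in the universe); otherwise sets are drawn independently
    and redrawn until all pairwise Jaccard indices are below the bound.
    Member loadings are uniform(1, 2); non-members are exactly 0.
    """
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length does not match n_genes")
    rng = np.random.default_rng(seed)
    loadings = np.zeros((n_genes, n_meta))
    gene_sets: list[set] = []
    if n_meta == 0:
        return ProgramBank(gene_ids, loadings, gene_sets)
    if genes_per_program <= 0:
        raise ValidationError("genes_per_program must be positive")
    if max_overlap == 0.0:
        if n_meta * genes_per_program > n_genes:
            raise ValidationError(
                f"{n_meta} disjoint programs of {genes_per_program} genes "
                f"do not fit in {n_genes} genes"
            )
        perm = rng.permutation(n_genes)
        member_idx = [
            perm[p * genes_per_program : (p + 1) * genes_per_program]
            for p in range(n_meta)
        ]
    else:
        member_idx = []
        for _ in range(n_meta):
            for _attempt in range(1000):
                cand = rng.choice(n_genes, size=genes_per_program, replace=False)
                cand_set = set(cand.tolist())
                ok = all(
                    len(cand_set & prev) / len(cand_set | prev) <= max_overlap
                    for prev in (set(m.tolist()) for m in member_idx)
                )
                if ok:
                    member_idx.append(cand)
                    break
            else:
                raise ValidationError("could not satisfy max_overlap constraint")
    for p, idx in enumerate(member_idx):
        loadings[idx, p] = rng.uniform(1.0, 2.0, size=len(idx))
        gene_sets.append({gene_ids[i] for i in idx})
    return ProgramBank(gene_ids, loadings, gene_sets)


def simulate_sample(
    bank: ProgramBank,
    n_cells: int,
    k_private: int = 1,
    depth_mean: float = 2000.0,
    noise: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
    organ: str = "uterus",
    group: str = "estrogen",
    cell_type: str = "epithelial",
    genes_per_private: int | None = None,
    dirichlet_alpha: float = 0.1,
    background_weight: float = 0.2,
    n_mito: int = 10,
    mito_beta: tuple[float, float] = (4.0, 36.0),
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, GroundTruth]:
    """One sample's counts from planted shared + private + background programs.

    Per-cell usage over the structure programs is Dirichlet(alpha) —
    small alpha concentrates each cell on one dominant program — mixed
    with a fixed ``background_weight`` on a dense uniform background so
    no cell has zero expected depth.  Expected expression is the
    loading-weighted mixture scaled to ``depth_mean`` UMIs; counts are
    Poisson (``noise = 0``) or gamma-Poisson with dispersion ``noise``.
    Mitochondrial pseudo-genes are appended with per-cell UMI fraction
    drawn Beta(``mito_beta``).
    """
    if n_cells < 50:
        raise ValidationError("n_cells must be >= 50")
    if depth_mean <= 0:
        raise ValidationError("depth_mean must be positive")
    if noise < 0:
        raise ValidationError("noise (dispersion) must be >= 0")
    rng = np.random.default_rng(seed)
    n_genes = len(bank.gene_ids)
    gpp = genes_per_private or (
        len(next(iter(bank.gene_sets))) if bank.gene_sets else max(n_genes // 10, 10)
    )

    program_names = [f"shared_{p + 1}" for p in range(bank.n_meta)]
    columns = [bank.loadings[:, p] for p in range(bank.n_meta)]
    program_genes = {
        f"shared_{p + 1}": set(bank.gene_sets[p]) for p in range(bank.n_meta)
    }
    shared_members = set().union(*bank.gene_sets) if bank.gene_sets else set()
    free = [i for i, g in enumerate(bank.gene_ids) if g not in shared_members]
    for j in range(k_private):
        pool = free if len(free) >= gpp else list(range(n_genes))
        idx = rng.choice(len(pool), size=gpp, replace=False)
        members = [pool[i] for i in idx]
        if pool is free:
            free = [i for i in free if i not in set(members)]
        vec = np.zeros(n_genes)
        vec[members] = rng.uniform(1.0, 2.0, size=gpp)
        name = f"{sample_id}_private_{j + 1}"
        program_names.append(name)
        columns.append(vec)
        program_genes[name] = {bank.gene_ids[i] for i in members}
    # dense low-magnitude background keeps every cell at positive depth
    program_names.append("background")
    columns.append(np.full(n_genes, 1.0))

    L = np.column_stack(columns)
    L = L / L.sum(axis=0, keepdims=True)  # each program sums to 1 UMI share

    n_struct = len(program_names) - 1
    if n_struct > 0:
        u_struct = rng.dirichlet([dirichlet_alpha] * n_struct, size=n_cells)
        usage = np.column_stack(
            [u_struct * (1.0 - background_weight),
             np.full((n_cells, 1), background_weight)]
        )
    else:
        usage = np.ones((n_cells, 1))
    expected = (L @ usage.T) * depth_mean  # genes x cells
    if noise == 0:
        body = rng.poisson(expected)
    else:
        lam = rng.gamma(shape=1.0 / noise, scale=expected * noise)
        body = rng.poisson(lam)

    # mitochondrial pseudo-genes
    mito_ids = [f"{mito_prefix}{j + 1}" for j in range(n_mito)]
    if n_mito > 0:
        frac = rng.beta(mito_beta[0], mito_beta[1], size=n_cells)
        frac = np.clip(frac, 0.0, 0.95)
        mito_total = rng.poisson(frac / (1.0 - frac) * depth_mean)
        mito = np.vstack(
            [rng.multinomial(t, np.full(n_mito, 1.0 / n_mito)) for t in mito_total]
        ).T
        counts = np.vstack([body, mito])
    else:
        counts = body
    gene_ids = list(bank.gene_ids) + mito_ids
    cell_ids = [f"{sample_id}_C{i + 1:04d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "organ": organ,
            "group": group,
            "cell_type": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts.astype(np.int64)),
        cell_meta=meta,
    )
    truth = GroundTruth(
        usage=pd.DataFrame(usage, index=cell_ids, columns=program_names),
        program_genes=program_genes,
    )
    return cm, truth


def plant_differential_expression(
    matrices: list[CountMatrix],
    de_spec: list[tuple[str, str, float]],
    seed: int = 0,
) -> tuple[list[CountMatrix], GroundTruth]:
    """Rescale chosen genes in estrogen-group cells by 2**log2fc.

    Up-regulation (log2fc > 0) adds Poisson((2^lfc - 1) * count) extra
    UMIs; down-regulation thins counts binomially with keep probability
    2^lfc.  Both leave the expected count at 2^lfc times the original.
    All other genes are untouched.
    """
    rng = np.random.default_rng(seed)
    all_genes = set().union(*(set(m.gene_ids) for m in matrices))
    all_cts = set().union(*(set(m.cell_meta["cell_type"]) for m in matrices))
    for gene, cell_type, lfc in de_spec:
        if gene not in all_genes:
            raise ValidationError(f"unknown gene in de_spec: {gene}")
        if cell_type not in all_cts:
            raise ValidationError(f"unknown cell_type in de_spec: {cell_type}")
        if lfc == 0:
            raise ValidationError("true_log2fc must be non-zero")
    out = []
    for m in matrices:
        counts = m.counts.toarray()
        gene_index = {g: i for i, g in enumerate(m.gene_ids)}
        for gene, cell_type, lfc in de_spec:
            if gene not in gene_index:
                continue
            gi = gene_index[gene]
            target = (
                (m.cell_meta["group"] == "estrogen")
                & (m.cell_meta["cell_type"] == cell_type)
            ).to_numpy()
            if not target.any():
                continue
            row = counts[gi, target]
            factor = 2.0 ** lfc
            if factor >= 1.0:
                counts[gi, target] = row + rng.poisson((factor - 1.0) * row)
            else:
                counts[gi, target] = rng.binomial(row, factor)
        out.append(
            CountMatrix(
                gene_ids=list(m.gene_ids),
                cell_ids=list(m.cell_ids),
                counts=sp.csr_matrix(counts),
                cell_meta=m.cell_meta.copy(),
            )
        )
    truth = GroundTruth(
        de_truth=pd.DataFrame(
            de_spec, columns=["gene", "cell_type", "true_log2fc"]
        )
    )
    return out, truth


def generate_gwas_catalog(
    gene_universe: list[str],
    traits: list[str],
    n_assoc: int,
    frac_below: float,
    seed: int = 0,
    p_threshold: float = 1e-5,
    force_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Toy association table with an exact sub-threshold row count.

    Exactly ``round(frac_below * n_assoc)`` rows get
    ``p < p_threshold``.  ``force_genes`` (optional) claims the first
    sub-threshold rows of the first trait for the given genes, so a
    known overlap with a DE gene list can be planted.
    """
    if not 0.0 <= frac_below <= 1.0:
        raise ValidationError("frac_below must lie in [0, 1]")
    if not traits:
        raise ValidationError("need at least one trait")
    rng = np.random.default_rng(seed)
    n_below = int(round(frac_below * n_assoc))
    force_genes = list(force_genes or [])
    if len(force_genes) > n_below:
        raise ValidationError("more forced genes than sub-threshold rows")
    rows = []
    for i in range(n_assoc):
        below = i < n_below
        if below:
            p = 10.0 ** rng.uniform(-12.0, np.log10(p_threshold) - 0.05)
            trait = traits[0] if i < len(force_genes) else traits[i % len(traits)]
            gene = (
                force_genes[i]
                if i < len(force_genes)
                else str(rng.choice(gene_universe))
            )
        else:
            p = rng.uniform(p_threshold * 1.2, 0.9)
            trait = traits[i % len(traits)]
            gene = str(rng.choice(gene_universe))
        rows.append(
            {
                "trait": trait,
                "snp_id": f"rs{100000 + i}",
                "mapped_gene": gene,
                "p_value": p,
            }
        )
    catalog = pd.DataFrame(rows)
    order = rng.permutation(len(catalog))
    catalog = catalog.iloc[order].reset_index(drop=True)
    truth_counts = (
        catalog[catalog["p_value"] < p_threshold]
        .groupby("trait")
        .size()
        .reindex(traits, fill_value=0)
        .rename("n_below_threshold")
        .reset_index()
    )
    return catalog, GroundTruth(gwas_truth=truth_counts)


def identity_homolog_map(gene_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame({"source_gene": gene_ids, "human_gene": gene_ids})


def simulate_group_pair(
    n_genes: int,
    n_cells_per_group: int,
    seed: int,
    de_spec: list[tuple[str, str, float]] | None = None,
    depth_mean: float = 2000.0,
    noise: float = 0.0,
    cell_type: str = "epithelial",
    organ: str = "uterus",
) -> CountMatrix:
    """Matched estrogen/normal sample pair with no program structure.

    Cells express only the dense background program, so without a
    ``de_spec`` the two groups are exchangeable — a clean null for
    differential-expression calibration.  Planted effects (if any) are
    applied to the estrogen cells.  Mitochondrial pseudo-genes are
    omitted; the pair is returned as one combined matrix.
    """
    bank = generate_program_bank(n_genes, 0, 1, seed=seed)
    matrices = []
    for offset, (sid, group) in enumerate((("T", "estrogen"), ("N", "normal"))):
        cm, _ = simulate_sample(
            bank,
            n_cells=n_cells_per_group,
            k_private=0,
            depth_mean=depth_mean,
            noise=noise,
            seed=seed + offset,
            sample_id=sid,
            organ=organ,
            group=group,
            cell_type=cell_type,
            n_mito=0,
        )
        matrices.append(cm)
    if de_spec:
        matrices, _ = plant_differential_expression(matrices, list(de_spec), seed=seed)
    return CountMatrix(
        gene_ids=list(matrices[0].gene_ids),
        cell_ids=matrices[0].cell_ids + matrices[1].cell_ids,
        counts=sp.hstack([m.counts for m in matrices]).tocsr(),
        cell_meta=pd.concat([m.cell_meta for m in matrices]),
    )


def simulate_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_samples: int = 5,
    n_genes: int = 500,
    n_meta: int = 3,
    genes_per_program: int = 50,
    n_cells: int = 300,
    k_private: int = 1,
    depth_mean: float = 2000.0,
    noise: float = 0.0,
    organ: str = "uterus",
    cell_types: tuple[str, ...] = ("epithelial",),
    de_spec: list[tuple[str, str, float]] | None = None,
    traits: tuple[str, ...] = ("trait_A", "trait_B"),
    n_assoc: int = 40,
    frac_below: float = 0.5,
    n_gwas_overlap: int = 5,
) -> dict:
    """Write a complete synthetic study to ``outdir``; return a manifest.

    Samples alternate estrogen/normal groups (estrogen first) within a
    single organ, all sharing the program bank; DE genes (default: 10
    up-regulated members of the gene universe outside the shared
    programs, log2FC = 1) are planted into estrogen cells, and the first
    ``n_gwas_overlap`` of them are forced into the catalog's
    sub-threshold rows so the DEG x GWAS join has known size.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bank = generate_program_bank(n_genes, n_meta, genes_per_program, seed=seed)

    shared = set().union(*bank.gene_sets) if bank.gene_sets else set()
    free_genes = [g for g in bank.gene_ids if g not in shared]
    if de_spec is None:
        de_genes = list(rng.choice(free_genes, size=min(10, len(free_genes)),
                                   replace=False))
        de_spec = [(g, cell_types[0], 1.0) for g in de_genes]

    sample_seeds = [int(s) % (2**31) for s in
                    np.random.SeedSequence([seed, 7]).generate_state(n_samples)]
    matrices, truths = [], []
    for i in range(n_samples):
        group = "estrogen" if i % 2 == 0 else "normal"
        cm, truth = simulate_sample(
            bank,
            n_cells=n_cells,
            k_private=k_private,
            depth_mean=depth_mean,
            noise=noise,
            seed=sample_seeds[i],
            sample_id=f"S{i + 1}",
            organ=organ,
            group=group,
            cell_type=cell_types[i % len(cell_types)],
        )
        matrices.append(cm)
        truths.append(truth)
    matrices, de_truth = plant_differential_expression(matrices, de_spec, seed=seed)

    catalog, gwas_truth = generate_gwas_catalog(
        gene_universe=bank.gene_ids,
        traits=list(traits),
        n_assoc=n_assoc,
        frac_below=frac_below,
        seed=seed,
        force_genes=[g for g, _, _ in de_spec][:n_gwas_overlap],
    )

    manifest: dict = {"samples": {}, "seed": seed}
    metas = []
    for cm in matrices:
        sid = cm.cell_meta["sample_id"].iloc[0]
        paths = write_count_matrix(cm, outdir / sid)
        manifest["samples"][sid] = paths
        metas.append(cm.cell_meta.reset_index(names="cell_id"))
    meta_all = pd.concat(metas, ignore_index=True)
    manifest["meta"] = str(write_table(meta_all, outdir / "cell_meta.tsv"))
    manifest["gwas"] = str(write_table(catalog, outdir / "gwas_catalog.tsv"))
    homologs = identity_homolog_map(list(matrices[0].gene_ids))
    manifest["homologs"] = str(write_table(homologs, outdir / "homologs.tsv"))

    # ground-truth files
    truth_dir = outdir / "truth"
    program_rows = []
    for name, genes in truths[0].program_genes.items():
        if name.startswith("shared_"):
            for g in sorted(genes):
                program_rows.append({"program": name, "gene": g})
    for t in truths:
        for name, genes in t.program_genes.items():
            if not name.startswith("shared_"):
                for g in sorted(genes):
                    program_rows.append({"program": name, "gene": g})
    manifest["truth_programs"] = str(
        write_table(pd.DataFrame(program_rows), truth_dir / "program_genes.tsv")
    )
    manifest["truth_de"] = str(
        write_table(de_truth.de_truth, truth_dir / "de_truth.tsv")
    )
    manifest["truth_gwas"] = str(
        write_table(gwas_truth.gwas_truth, truth_dir / "gwas_truth.tsv")
    )
    for t, cm in zip(truths, matrices):
        sid = cm.cell_meta["sample_id"].iloc[0]
        write_table(
            t.usage.reset_index(names="cell_id"), truth_dir / f"usage_{sid}.tsv"
        )
    manifest["truth_dir"] = str(truth_dir)
    return manifest
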