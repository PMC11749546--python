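"""End-to-end orchestration: qc -> programs -> metaprograms -> deg -> gwas.

Each stage writes its outputs as TSV under the run directory and adds
its input/output counts to a machine-readable run log.  Any stage
failure aborts the run with the stage name attached.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deg import compute_degs, deg_count_summary
from .gwas import intersect_deg_gwas, load_and_filter_catalog, map_homologs
from .io_core import (
    CountMatrix,
    PipelineConfig,
    PipelineError,
    read_count_matrix,
    write_count_matrix,
    write_run_log,
    write_table,
)
from .metaprograms import build_metaprograms
from .nmf import choose_rank, cophenetic_profile, extract_programs, nmf_factorize
from .qc import (
    filter_cells,
    filter_low_variance_genes,
    normalize_log1p_cp10k,
    relative_expression_nonneg,
)


def load_dataset(dataset_dir: str | Path) -> tuple[list[CountMatrix], dict]:
    """Read every per-sample MTX triplet under ``dataset_dir``.

    Expects the layout written by :func:`scprograms.synthetic.simulate_dataset`:
    one subdirectory per sample plus a shared ``cell_meta.tsv``.
    """
    dataset_dir = Path(dataset_dir)
    meta_path = dataset_dir / "cell_meta.tsv"
    matrices = []
    for sub in sorted(p for p in dataset_dir.iterdir() if p.is_dir()):
        mtx = sub / "matrix.mtx"
        if not mtx.exists():
            continue
        matrices.append(
            read_count_matrix(mtx, sub / "features.tsv", sub / "barcodes.tsv", meta_path)
        )
    if not matrices:
        raise FileNotFoundError(f"no sample matrices under {dataset_dir}")
    paths = {
        "meta": str(meta_path),
        "gwas": str(dataset_dir / "gwas_catalog.tsv"),
        "homologs": str(dataset_dir / "homologs.tsv"),
    }
    return matrices, paths


def stage_qc(matrices: list[CountMatrix], config: PipelineConfig, outdir: Path):
    filtered, reports = [], []
    for cm in matrices:
        sid = cm.cell_meta["sample_id"].iloc[0]
        f, report = filter_cells(
            cm,
            min_genes=config.min_genes,
            max_genes=config.max_genes,
            max_mito=config.max_mito_frac,
            mito_prefix=config.mito_prefix,
        )
        report["sample_id"] = sid
        filtered.append(f)
        reports.append(report)
        write_count_matrix(f, outdir / "qc" / sid)
    report_df = pd.DataFrame(reports)[
        ["sample_id", "n_input", "removed_low_genes", "removed_high_genes",
         "removed_high_mito", "n_retained"]
    ]
    write_table(report_df, outdir / "qc" / "qc_report.tsv", sort_by=["sample_id"])
    return filtered, report_df


def _sample_seed(base_seed: int, sample_id: str) -> int:
    digest = sum(ord(c) * (i + 1) for i, c in enumerate(sample_id))
    return int(np.random.SeedSequence([base_seed, digest]).generate_state(1)[0]) % (2**31)


def stage_programs(
    filtered: list[CountMatrix], config: PipelineConfig, outdir: Path, seed: int
):
    program_sets = []
    prog_rows, coph_rows = [], []
    for cm in filtered:
        sid = cm.cell_meta["sample_id"].iloc[0]
        nm = normalize_log1p_cp10k(cm)
        nm = filter_low_variance_genes(nm, sd_min=config.sd_min)
        rel = relative_expression_nonneg(nm)
        X = rel.values
        sub_seed = _sample_seed(seed, sid)
        profile = cophenetic_profile(
            X, config.k_range, config.n_restarts, sub_seed
        )
        k = choose_rank(profile)
        fit = nmf_factorize(X, k, sub_seed, max_iter=config.max_iter, tol=config.tol)
        ps = extract_programs(
            fit, rel.gene_ids, sample_id=sid, n_top=config.top_n_corr,
            cophenetic=profile,
        )
        program_sets.append(ps)
        for kk in sorted(profile):
            coph_rows.append({"sample_id": sid, "k": kk, "cophenetic": profile[kk]})
        for prog in ps.programs:
            for rank, (g, w) in enumerate(zip(prog.genes, prog.loadings), start=1):
                if rank > config.top_n_corr:
                    break
                prog_rows.append(
                    {"sample_id": sid, "program_id": prog.program_id,
                     "rank": rank, "gene": g, "loading": w}
                )
    write_table(pd.DataFrame(coph_rows), outdir / "programs" / "cophenetic.tsv")
    write_table(pd.DataFrame(prog_rows), outdir / "programs" / "programs.tsv")
    return program_sets


def stage_metaprograms(program_sets, config: PipelineConfig, outdir: Path):
    mps = build_metaprograms(
        program_sets,
        cut_distance=config.cut_distance,
        pool_n=config.pool_n,
        marker_n=config.marker_n,
    )
    member_rows, score_rows, marker_rows = [], [], []
    for mp in mps:
        for prog in mp.members:
            member_rows.append(
                {"mp_id": mp.mp_id, "sample_id": prog.sample_id,
                 "program_id": prog.program_id}
            )
        for rank, (g, s) in enumerate(mp.gene_scores.items(), start=1):
            score_rows.append({"mp_id": mp.mp_id, "gene": g, "score": s, "rank": rank})
        for rank, g in enumerate(mp.markers, start=1):
            marker_rows.append({"mp_id": mp.mp_id, "rank": rank, "gene": g})
    write_table(pd.DataFrame(member_rows), outdir / "metaprograms" / "membership.tsv")
    write_table(pd.DataFrame(score_rows), outdir / "metaprograms" / "gene_scores.tsv")
    write_table(pd.DataFrame(marker_rows), outdir / "metaprograms" / "markers.tsv")
    return mps


def stage_deg(filtered: list[CountMatrix], config: PipelineConfig, outdir: Path):
    genes = filtered[0].gene_ids
    for cm in filtered[1:]:
        if cm.gene_ids != genes:
            raise ValueError("samples disagree on the gene universe")
    import scipy.sparse as sp

    combined = CountMatrix(
        gene_ids=list(genes),
        cell_ids=[c for cm in filtered for c in cm.cell_ids],
        counts=sp.hstack([cm.counts for cm in filtered]).tocsr(),
        cell_meta=pd.concat([cm.cell_meta for cm in filtered]),
    )
    nm = normalize_log1p_cp10k(combined)
    degs = compute_degs(
        nm,
        combined.cell_meta,
        fdr_max=config.fdr_max,
        lfc_min=config.lfc_min,
        min_cells_per_group=config.min_cells_per_group,
        pseudo=config.pseudo,
    )
    write_table(degs, outdir / "deg" / "degs.tsv")
    write_table(deg_count_summary(degs), outdir / "deg" / "deg_counts.tsv")
    return degs


def stage_gwas(
    degs: pd.DataFrame, paths: dict, config: PipelineConfig, outdir: Path
):
    catalog = load_and_filter_catalog(paths["gwas"], p_max=config.p_max)
    mapping = map_homologs(sorted(set(degs["gene"])), paths["homologs"])
    tables = {}
    for trait in sorted(set(catalog["trait"])):
        table = intersect_deg_gwas(
            degs, catalog, mapping, trait, p_agg=config.gwas_p_agg
        )
        safe = trait.replace("/", "_").replace(" ", "_")
        write_table(table, outdir / "gwas" / f"risk_genes_{safe}.tsv")
        tables[trait] = table
    return tables


def run_pipeline(
    config: PipelineConfig,
    dataset_dir: str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run all stages on a dataset directory; return a summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    report: dict = {"version": __version__, "seed": seed, "config": config.to_dict(),
                    "stages": {}}

    def _run(stage_name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise PipelineError(stage_name, exc) from exc

    matrices, paths = _run("load", load_dataset, dataset_dir)
    report["stages"]["load"] = {"n_samples": len(matrices)}

    filtered, qc_report = _run("qc", stage_qc, matrices, config, outdir)
    report["stages"]["qc"] = {
        "n_cells_in": int(qc_report["n_input"].sum()),
        "n_cells_out": int(qc_report["n_retained"].sum()),
    }

    program_sets = _run("programs", stage_programs, filtered, config, outdir, seed)
    report["stages"]["programs"] = {
        "n_program_sets": len(program_sets),
        "ranks": {ps.sample_id: ps.factorization.k for ps in program_sets},
    }

    mps = _run("metaprograms", stage_metaprograms, program_sets, config, outdir)
    report["stages"]["metaprograms"] = {
        "n_mps": len(mps),
        "n_multi_sample_mps": sum(len(mp.member_samples) > 1 for mp in mps),
    }

    degs = _run("deg", stage_deg, filtered, config, outdir)
    report["stages"]["deg"] = {
        "n_rows": int(len(degs)),
        "n_significant": int(degs["significant"].sum()) if len(degs) else 0,
    }

    gwas_tables = _run("gwas", stage_gwas, degs, paths, config, outdir)
    report["stages"]["gwas"] = {
        trait: int(len(table)) for trait, table in gwas_tables.items()
    }

    write_run_log(outdir / "run_log.json", report)
    return report
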