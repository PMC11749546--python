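import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scprograms import (
    FormatError,
    ValidationError,
    intersect_deg_gwas,
    load_and_filter_catalog,
    load_catalog,
    map_homologs,
)


def write_catalog(tmp_path, rows, name="catalog.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def catalog_row(trait="t1", snp="rs1", gene="A", p=1e-6):
    return {"trait": trait, "snp_id": snp, "mapped_gene": gene, "p_value": p}


def make_degs(genes, organ="uterus", cell_type="epithelial"):
    return pd.DataFrame(
        {
            "organ": organ,
            "cell_type": cell_type,
            "gene": genes,
            "log2fc": np.linspace(-1, 1, len(genes)),
            "p": 0.01,
            "fdr": 0.02,
            "n_treated": 10,
            "n_control": 10,
            "direction": "up",
            "significant": True,
        }
    )


class TestCatalogFilter:
    def test_strict_threshold_and_counts(self, tmp_path):
        rows = [catalog_row(snp=f"rs{i}", p=1e-7) for i in range(4)]
        rows += [catalog_row(snp=f"rs{i + 4}", p=0.01) for i in range(6)]
        out = load_and_filter_catalog(write_catalog(tmp_path, rows))
        assert len(out) == 4

    def test_boundary_p_exactly_1e5_excluded(self, tmp_path):
        rows = [catalog_row(snp="rs1", p=1e-5), catalog_row(snp="rs2", p=0.99e-5)]
        out = load_and_filter_catalog(write_catalog(tmp_path, rows))
        assert out["snp_id"].tolist() == ["rs2"]

    def test_empty_catalog_ok(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("trait\tsnp_id\tmapped_gene\tp_value\n")
        assert len(load_and_filter_catalog(path)) == 0

    def test_duplicate_trait_snp_rejected(self, tmp_path):
        rows = [catalog_row(), catalog_row()]
        with pytest.raises(ValidationError, match="duplicate"):
            load_catalog(write_catalog(tmp_path, rows))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"trait": ["t"], "snp_id": ["rs1"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(FormatError):
            load_catalog(path)

    def test_unparsable_p_dropped_with_warning(self, tmp_path):
        rows = [catalog_row(), catalog_row(snp="rs2", p="not-a-number")]
        with pytest.warns(UserWarning, match="unparsable"):
            out = load_catalog(write_catalog(tmp_path, rows))
        assert len(out) == 1

    def test_nhgri_style_headers_accepted(self, tmp_path):
        path = tmp_path / "ebi.tsv"
        pd.DataFrame(
            {
                "DISEASE/TRAIT": ["t1"],
                "SNPS": ["rs1"],
                "MAPPED_GENE": ["A"],
                "P-VALUE": [1e-8],
            }
        ).to_csv(path, sep="\t", index=False)
        assert len(load_and_filter_catalog(path)) == 1


class TestHomologMap:
    def test_identity_table(self, tmp_path):
        table = pd.DataFrame({"source_gene": ["A", "B"], "human_gene": ["A", "B"]})
        assert map_homologs(["A", "B"], table) == {"A": "A", "B": "B"}

    def test_absent_gene_dropped_with_warning(self):
        table = pd.DataFrame({"source_gene": ["A"], "human_gene": ["hA"]})
        with pytest.warns(UserWarning, match="dropped"):
            mapping = map_homologs(["A", "B"], table)
        assert mapping == {"A": "hA"}

    def test_many_to_one_allowed(self):
        table = pd.DataFrame(
            {"source_gene": ["mA", "mB"], "human_gene": ["hA", "hA"]}
        )
        assert map_homologs(["mA", "mB"], table) == {"mA": "hA", "mB": "hA"}

    def test_conflicting_source_rows_rejected(self):
        table = pd.DataFrame(
            {"source_gene": ["mA", "mA"], "human_gene": ["hA", "hB"]}
        )
        with pytest.raises(ValidationError, match="mA"):
            map_homologs(["mA"], table)


class TestIntersect:
    def _catalog(self, rows):
        df = pd.DataFrame(rows)
        return df[df["p_value"] < 1e-5].reset_index(drop=True)

    def test_disjoint_gene_sets_give_empty_table(self):
        catalog = self._catalog([catalog_row(gene="X")])
        out = intersect_deg_gwas(
            make_degs(["A", "B"]), catalog, {"A": "A", "B": "B"}, "t1"
        )
        assert len(out) == 0

    def test_planted_overlap_recovered_exactly(self):
        genes = [f"G{i}" for i in range(8)]
        overlap = genes[:5]
        catalog = self._catalog(
            [catalog_row(snp=f"rs{i}", gene=g, p=1e-8) for i, g in enumerate(overlap)]
            + [catalog_row(snp="rs90", gene="UNRELATED", p=1e-9)]
        )
        out = intersect_deg_gwas(
            make_degs(genes), catalog, {g: g for g in genes}, "t1"
        )
        assert sorted(out["gene_human"]) == sorted(overlap)

    def test_min_p_aggregation(self):
        catalog = self._catalog(
            [catalog_row(snp="rs1", p=1e-6), catalog_row(snp="rs2", p=1e-8)]
        )
        out = intersect_deg_gwas(make_degs(["A"]), catalog, {"A": "A"}, "t1")
        assert out["neg_log10_p"].iloc[0] == pytest.approx(8.0)

    def test_absent_trait_warns_and_returns_empty(self):
        catalog = self._catalog([catalog_row()])
        with pytest.warns(UserWarning, match="absent"):
            out = intersect_deg_gwas(make_degs(["A"]), catalog, {"A": "A"}, "zzz")
        assert len(out) == 0

    def test_join_is_lossless_on_deg_side(self):
        degs = make_degs(["A", "B", "C"])
        catalog = self._catalog(
            [catalog_row(snp="rs1", gene="A"), catalog_row(snp="rs2", gene="C")]
        )
        out = intersect_deg_gwas(degs, catalog, {g: g for g in "ABC"}, "t1")
        merged = out.merge(
            degs, left_on=["organ", "cell_type", "gene_monkey"],
            right_on=["organ", "cell_type", "gene"],
        )
        assert len(merged) == len(out)
        np.testing.assert_allclose(merged["log2fc_x"], merged["log2fc_y"])
        np.testing.assert_allclose(merged["fdr_x"], merged["fdr_y"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pvals=st.lists(
            st.floats(1e-12, 1.0, allow_nan=False), min_size=1, max_size=30
        ),
        seed=st.integers(0, 1000),
    )
    def test_filter_then_join_commutes_with_join_then_filter(self, pvals, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i % 6}" for i in range(len(pvals))]
        catalog = pd.DataFrame(
            [
                catalog_row(snp=f"rs{i}", gene=g, p=p)
                for i, (g, p) in enumerate(zip(genes, pvals))
            ]
        )
        degs = make_degs(sorted(set(genes)))
        mapping = {g: g for g in set(genes)}
        filtered = catalog[catalog["p_value"] < 1e-5].reset_index(drop=True)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = intersect_deg_gwas(degs, filtered, mapping, "t1", p_agg="min")
            b = intersect_deg_gwas(degs, catalog, mapping, "t1", p_agg="min")
        b = b[b["neg_log10_p"] > -np.log10(1e-5)].reset_index(drop=True)
        assert len(a) == len(b)
        if len(a):
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
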