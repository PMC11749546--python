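import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scprograms import (
    ValidationError,
    cluster_programs,
    mp_recovery_report,
    program_distance_matrix,
    score_metaprogram,
)
from scprograms.nmf import Program


def make_program(loadings: dict, program_id="P1", sample_id="S1"):
    """Program from a gene -> loading dict (ranked as extract_programs would)."""
    items = sorted(loadings.items(), key=lambda kv: (-kv[1], kv[0]))
    return Program(
        program_id=program_id,
        genes=[g for g, _ in items],
        loadings=np.array([w for _, w in items], dtype=float),
        sample_id=sample_id,
    )


class TestProgramDistance:
    def test_identical_programs_have_zero_distance(self):
        p = {"A": 1.0, "B": 0.5, "C": 0.2}
        d = program_distance_matrix(
            [make_program(p, "P1"), make_program(p, "P2")]
        )
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_loadings_have_zero_distance(self):
        p1 = make_program({"A": 1.0, "B": 0.5, "C": 0.2}, "P1")
        p2 = make_program({"A": 3.0, "B": 1.5, "C": 0.6}, "P2")
        d = program_distance_matrix([p1, p2])
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_programs_hand_computed_pearson(self):
        # unit loadings on disjoint triples over a 6-gene union:
        # vectors (1,1,1,0,0,0) vs (0,0,0,1,1,1) have r = -1, distance 2
        p1 = make_program({"A": 1.0, "B": 1.0, "C": 1.0}, "P1")
        p2 = make_program({"D": 1.0, "E": 1.0, "F": 1.0}, "P2")
        d = program_distance_matrix([p1, p2])
        assert d.matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_program_gets_max_distance(self):
        p1 = make_program({"A": 1.0, "B": 0.5}, "P1")
        p2 = make_program({"A": 0.7, "B": 0.7}, "P2")  # constant on union
        with pytest.warns(UserWarning, match="zero loading variance"):
            d = program_distance_matrix([p1, p2])
        assert d.matrix[0, 1] == 2.0

    def test_matrix_invariants(self):
        progs = [
            make_program({"A": 1.0, "B": 0.2}, "P1"),
            make_program({"B": 1.0, "C": 0.4}, "P2"),
            make_program({"C": 1.0, "A": 0.1}, "P3"),
        ]
        d = program_distance_matrix(progs)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0)
        assert d.matrix.min() >= 0 and d.matrix.max() <= 2


class TestClustering:
    def _programs(self):
        base = {"A": 1.0, "B": 0.8, "C": 0.1}
        far = {"X": 1.0, "Y": 0.9, "Z": 0.8}
        return [
            make_program(base, "P1", "S1"),
            make_program(base, "P2", "S2"),
            make_program(base, "P3", "S3"),
            make_program(far, "P4", "S4"),
        ]

    def test_three_close_one_far(self):
        d = program_distance_matrix(self._programs())
        mps = cluster_programs(d, cut_distance=0.8)
        sizes = sorted(len(mp.members) for mp in mps)
        assert sizes == [1, 3]

    def test_cut_zero_gives_singletons_for_distinct_programs(self):
        progs = [
            make_program({"A": 1.0, "B": 0.3}, "P1"),
            make_program({"B": 1.0, "C": 0.3}, "P2"),
            make_program({"C": 1.0, "A": 0.3}, "P3"),
        ]
        mps = cluster_programs(program_distance_matrix(progs), cut_distance=0.0)
        assert len(mps) == 3

    def test_cut_at_max_distance_gives_one_mp(self):
        mps = cluster_programs(program_distance_matrix(self._programs()), 2.0)
        assert len(mps) == 1
        assert len(mps[0].members) == 4

    def test_membership_invariant_to_input_order(self, rng):
        progs = self._programs()
        d1 = program_distance_matrix(progs)
        order = rng.permutation(len(progs))
        d2 = program_distance_matrix([progs[i] for i in order])
        as_sets = lambda mps: {
            frozenset((p.sample_id, p.program_id) for p in mp.members) for mp in mps
        }
        assert as_sets(cluster_programs(d1, 0.8)) == as_sets(cluster_programs(d2, 0.8))


def score_oracle(members, pool_n, marker_n):
    """Brute-force enumeration of the pooled top-gene lists."""
    m = len(members)
    pooled = []
    for prog in members:
        pooled.extend(list(zip(prog.genes, prog.loadings))[:pool_n])
    genes = sorted({g for g, _ in pooled})
    scores = {g: sum(w for gg, w in pooled if gg == g) / m for g in genes}
    ranked = sorted(scores, key=lambda g: (-scores[g], g))
    return scores, ranked[:marker_n]


class TestMetaSignatureScore:
    def test_hand_computed_two_member_example(self):
        m1 = make_program({"A": 0.5, "B": 0.6}, "P1", "S1")
        m2 = make_program({"A": 0.3}, "P2", "S2")
        mp = score_metaprogram([m1, m2], pool_n=100, marker_n=30)
        assert mp.gene_scores["A"] == pytest.approx(0.4)
        assert mp.gene_scores["B"] == pytest.approx(0.3)
        assert mp.markers[0] == "A"

    def test_single_member_identity(self):
        m1 = make_program({"A": 0.9, "B": 0.5, "C": 0.1}, "P1")
        mp = score_metaprogram([m1], pool_n=2, marker_n=30)
        assert dict(mp.gene_scores) == {"A": 0.9, "B": 0.5}

    def test_scaling_linearity(self):
        members = [
            make_program({"A": 0.5, "B": 0.6}, "P1"),
            make_program({"A": 0.3, "C": 0.2}, "P2"),
        ]
        scaled = [
            make_program({"A": 1.5, "B": 1.8}, "P1"),
            make_program({"A": 0.9, "C": 0.6}, "P2"),
        ]
        mp1 = score_metaprogram(members)
        mp2 = score_metaprogram(scaled)
        assert mp1.markers == mp2.markers
        np.testing.assert_allclose(mp2.gene_scores.values, 3 * mp1.gene_scores.values)

    def test_empty_membership_rejected(self):
        with pytest.raises(ValidationError):
            score_metaprogram([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.lists(
                st.tuples(
                    st.sampled_from("ABCDEFGHIJ"),
                    st.floats(0.01, 10.0, allow_nan=False),
                ),
                min_size=1,
                max_size=10,
                unique_by=lambda t: t[0],
            ),
            min_size=1,
            max_size=5,
        ),
        pool_n=st.integers(1, 10),
    )
    def test_matches_brute_force_oracle(self, data, pool_n):
        members = [
            make_program(dict(item), f"P{i}", f"S{i}") for i, item in enumerate(data)
        ]
        mp = score_metaprogram(members, pool_n=pool_n, marker_n=5)
        scores, markers = score_oracle(members, pool_n, 5)
        assert set(mp.gene_scores.index) == set(scores)
        for g, s in scores.items():
            assert mp.gene_scores[g] == pytest.approx(s, abs=1e-12)
        assert mp.markers == markers


class TestRecoveryReport:
    def test_perfect_and_disjoint_matches(self):
        m1 = make_program({"A": 1.0, "B": 0.9}, "P1", "S1")
        mp = score_metaprogram([m1], marker_n=2)
        truth = {"planted_1": {"A", "B"}, "planted_2": {"X", "Y"}}
        report = mp_recovery_report([mp], truth).set_index("true_program")
        assert report.loc["planted_1", "jaccard_top_markers"] == pytest.approx(1.0)
        assert report.loc["planted_2", "jaccard_top_markers"] == pytest.approx(0.0)
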