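import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioentity2vec.attributes import (
    AttributeError_,
    Fingerprint,
    MeshDescriptor,
    build_semantic_dag,
    kmer_index,
    kmer_vector,
    load_fingerprints,
    make_sequence,
    parent_tree_number,
    read_fasta,
    read_mesh_descriptors,
    reduce_protein_alphabet,
    semantic_similarity,
    semantic_value,
    similarity_matrix,
    write_fasta,
    write_fingerprints,
    write_mesh_descriptors,
)

# ---------------------------------------------------------------------------
# independent brute-force scorer for the semantic similarity oracle
# ---------------------------------------------------------------------------


def _oracle_positions(entity):
    """All hierarchy positions of the entity's ancestor closure."""
    positions = set()

    def up(code):
        if code in positions:
            return
        positions.add(code)
        if "." in code:
            up(code.rsplit(".", 1)[0])

    for t in entity.tree_numbers:
        up(t)
    return positions


def _oracle_contributions(entity, delta=0.5):
    """Recursive max-rule contributions, no depth shortcut."""
    positions = _oracle_positions(entity)
    own = set(entity.tree_numbers)
    memo = {}

    def value(code):
        if code in memo:
            return memo[code]
        if code in own:
            memo[code] = 1.0
            return 1.0
        kids = [c for c in positions if "." in c and c.rsplit(".", 1)[0] == code]
        memo[code] = delta * max(value(c) for c in kids)
        return memo[code]

    return {c: value(c) for c in positions}


def oracle_similarity(a, b, delta=0.5):
    va, vb = _oracle_contributions(a, delta), _oracle_contributions(b, delta)
    shared = set(va) & set(vb)
    if not shared:
        return 0.0
    return sum(va[c] + vb[c] for c in shared) / (sum(va.values()) + sum(vb.values()))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


class TestSequences:
    def test_dna_t_mapped_to_u(self):
        assert make_sequence("x", "rna", "acgt").residues == "ACGU"

    def test_invalid_residue_names_position(self):
        with pytest.raises(AttributeError_, match="position 2"):
            make_sequence("x", "protein", "AXA")

    @pytest.mark.parametrize(
        "residues,expected",
        [("RKH", "333"), ("DE", "44"), ("AVLIMFWP", "11111111"), ("GSTCNQY", "2222222")],
    )
    def test_polarity_groups(self, residues, expected):
        red = reduce_protein_alphabet(make_sequence("p", "protein", residues))
        assert red.residues == expected

    def test_reduction_total_and_length_preserving(self):
        all20 = "ACDEFGHIKLMNPQRSTVWY"
        red = reduce_protein_alphabet(make_sequence("p", "protein", all20))
        assert len(red.residues) == 20
        assert set(red.residues) <= set("1234")

    def test_fasta_round_trip(self, tmp_path):
        seqs = [
            make_sequence("rna1", "rna", "ACGU" * 30),
            make_sequence("prot1", "protein", "MKV" * 40),
        ]
        write_fasta(seqs, tmp_path / "s.fa")
        back = read_fasta(tmp_path / "s.fa", {"rna1": "rna", "prot1": "protein"})
        assert {s.node_id: s.residues for s in seqs} == {
            k: v.residues for k, v in back.items()
        }


class TestKmer:
    def test_single_window(self):
        v = kmer_vector(make_sequence("x", "rna", "AAA"))
        assert v[kmer_index("ACGU").index("AAA")] == 1.0
        assert v.sum() == 1.0

    def test_two_identical_windows(self):
        v = kmer_vector(make_sequence("x", "rna", "AAAA"))
        assert v[kmer_index("ACGU").index("AAA")] == 1.0

    def test_acgu_two_windows(self):
        v = kmer_vector(make_sequence("x", "rna", "ACGU"))
        idx = kmer_index("ACGU")
        assert v[idx.index("ACG")] == 0.5
        assert v[idx.index("CGU")] == 0.5
        assert v.sum() == 1.0

    def test_too_short_errors(self):
        with pytest.raises(AttributeError_, match="shorter"):
            kmer_vector(make_sequence("x", "rna", "AC"))

    def test_unreduced_protein_rejected(self):
        with pytest.raises(AttributeError_, match="reduce"):
            kmer_vector(make_sequence("x", "protein", "MKVLL"))

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=3, max_size=300))
    def test_sum_to_one_property(self, s):
        v = kmer_vector(make_sequence("x", "rna", s))
        assert v.shape == (64,)
        assert abs(v.sum() - 1.0) < 1e-9
        assert (v >= 0).all()

    def test_counts_match_naive_window_count(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGU"), size=200))
        v = kmer_vector(make_sequence("x", "rna", s))
        idx = kmer_index("ACGU")
        naive = np.array(
            [sum(s[i : i + 3] == w for i in range(len(s) - 2)) for w in idx], float
        )
        np.testing.assert_allclose(v, naive / (len(s) - 2), atol=1e-12)


# ---------------------------------------------------------------------------
# MeSH semantics
# ---------------------------------------------------------------------------

CHAIN = [
    MeshDescriptor("A", ("C01",)),
    MeshDescriptor("B", ("C01.100",)),
    MeshDescriptor("C", ("C01.100.200",)),
]


class TestMesh:
    @pytest.mark.parametrize(
        "code,parent",
        [("B03.353.500", "B03.353"), ("B03.510.100", "B03.510"), ("C04", None)],
    )
    def test_parent_tree_number(self, code, parent):
        assert parent_tree_number(code) == parent

    def test_malformed_code_errors(self):
        with pytest.raises(AttributeError_):
            parent_tree_number("B3.35")

    def test_isolated_root_dag(self):
        d = build_semantic_dag(CHAIN[0], CHAIN[:1])
        assert d.contributions == {"C01": 1.0}
        assert semantic_value(d) == 1.0

    def test_chain_contributions_halve_per_level(self):
        d = build_semantic_dag(CHAIN[2], CHAIN)
        assert d.contributions == {"C01.100.200": 1.0, "C01.100": 0.5, "C01": 0.25}
        assert semantic_value(d) == 1.75

    def test_chain_of_two(self):
        d = build_semantic_dag(CHAIN[1], CHAIN)
        assert semantic_value(d) == 1.5

    def test_diamond_takes_max_over_paths(self):
        # two tree numbers put the entity at depth 1 and depth 2 below C01
        e = MeshDescriptor("X", ("C01.100", "C01.200.300"))
        d = build_semantic_dag(e, [e])
        assert d.contributions["C01"] == 0.5  # max(0.5*1, 0.5*0.5)

    def test_entity_absent_from_universe_errors(self):
        with pytest.raises(AttributeError_, match="absent"):
            build_semantic_dag(MeshDescriptor("Z", ("C09",)), CHAIN)

    def test_self_similarity_and_symmetry(self):
        da = build_semantic_dag(CHAIN[2], CHAIN)
        db = build_semantic_dag(CHAIN[1], CHAIN)
        assert semantic_similarity(da, da) == 1.0
        assert semantic_similarity(da, db) == semantic_similarity(db, da)

    def test_disjoint_dags_give_zero(self):
        a = MeshDescriptor("a", ("C01",))
        b = MeshDescriptor("b", ("B05",))
        assert semantic_similarity(
            build_semantic_dag(a, [a, b]), build_semantic_dag(b, [a, b])
        ) == 0.0

    def test_worked_chain_example(self):
        # DAG(C) = {C:1, B:.5, A:.25}, DAG(B) = {B:1, A:.5};
        # shared {A,B} -> (0.25+0.5 + 0.5+1) / (1.75+1.5) = 2.25/3.25
        da = build_semantic_dag(CHAIN[2], CHAIN)
        db = build_semantic_dag(CHAIN[1], CHAIN)
        assert semantic_similarity(da, db) == pytest.approx(2.25 / 3.25, abs=1e-12)
        ids, m = similarity_matrix(CHAIN)
        assert m[ids.index("B"), ids.index("C")] == pytest.approx(2.25 / 3.25, abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self, small_bundle):
        ids, m = similarity_matrix(small_bundle.mesh["disease"])
        np.testing.assert_allclose(m, m.T, atol=0)
        np.testing.assert_allclose(np.diag(m), 1.0, atol=0)
        assert ((m >= 0) & (m <= 1)).all()

    def test_descriptor_round_trip(self, tmp_path, small_bundle):
        descs = small_bundle.mesh["microbe"]
        write_mesh_descriptors(descs, tmp_path / "m.tsv")
        back = read_mesh_descriptors(tmp_path / "m.tsv")
        assert sorted(back, key=lambda d: d.entity_id) == sorted(
            descs, key=lambda d: d.entity_id
        )


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


class TestFingerprints:
    def test_load_two_rows(self, tmp_path):
        (tmp_path / "fp.tsv").write_text("a\t01010101\nb\t11110000\n")
        fps = load_fingerprints(tmp_path / "fp.tsv")
        assert len(fps) == 2 and all(len(f.bits) == 8 for f in fps)

    def test_ragged_lengths_error(self, tmp_path):
        (tmp_path / "fp.tsv").write_text("a\t01010101\nb\t0101010101010101\n")
        with pytest.raises(AttributeError_, match="length"):
            load_fingerprints(tmp_path / "fp.tsv")

    def test_non_binary_error(self, tmp_path):
        (tmp_path / "fp.tsv").write_text("a\t0102\n")
        with pytest.raises(AttributeError_, match="non-binary"):
            load_fingerprints(tmp_path / "fp.tsv")

    def test_round_trip(self, tmp_path):
        fps = [Fingerprint("a", (0, 1, 1, 0)), Fingerprint("b", (1, 0, 0, 1))]
        write_fingerprints(fps, tmp_path / "fp.tsv")
        assert load_fingerprints(tmp_path / "fp.tsv") == fps
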