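import math

import numpy as np
import pytest

from chemomine.phyloclass import (
    ClassAssignment,
    DistanceMatrix,
    build_nj,
    classify_by_tree,
    dnds_nei_gojobori,
    place_one_by_one,
    protein_distance,
)
from chemomine.seqcore import ProtSequence
from chemomine.synthetic import AA20, _mutate_protein

from chemomine.benchmarks import make_class_references, random_additive_tree_matrix


class TestProteinDistance:
    def test_identical_pair_is_zero(self):
        msa = [ProtSequence(id="a", residues="MKLVW" * 20),
               ProtSequence(id="b", residues="MKLVW" * 20)]
        dm = protein_distance(msa)
        assert dm.matrix[0, 1] == 0.0

    def test_closed_form_poisson(self):
        a = "A" * 300
        b = "A" * 270 + "C" * 30  # p = 0.1 over 300 shared columns
        dm = protein_distance([ProtSequence(id="a", residues=a),
                               ProtSequence(id="b", residues=b)])
        assert math.isclose(dm.matrix[0, 1], -math.log(0.9), rel_tol=1e-12)

    def test_no_shared_columns_is_error(self):
        msa = [ProtSequence(id="a", residues="MKLVW" * 10 + "-" * 50),
               ProtSequence(id="b", residues="-" * 50 + "MKLVW" * 10)]
        with pytest.raises(ValueError, match="a.*b|shares"):
            protein_distance(msa)

    def test_matrix_contract_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=("a", "b"), matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_roundtrip(self):
        # tree ((A:1,B:2):1.5,C:0.5,D:3): hand-computed path lengths
        ids = ("A", "B", "C", "D")
        m = np.array([
            [0.0, 3.0, 3.0, 5.5],
            [3.0, 0.0, 4.0, 6.5],
            [3.0, 4.0, 0.0, 3.5],
            [5.5, 6.5, 3.5, 0.0],
        ])
        tree = build_nj(DistanceMatrix(ids=ids, matrix=m))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert math.isclose(pdm.patristic_distance(taxa[a], taxa[b]),
                                        m[i, j], abs_tol=1e-12)

    def test_identical_taxa_become_sisters(self):
        ids = ("a", "b", "c", "d")
        m = np.array([
            [0.0, 0.0, 2.0, 2.0],
            [0.0, 0.0, 2.0, 2.0],
            [2.0, 2.0, 0.0, 1.0],
            [2.0, 2.0, 1.0, 0.0],
        ])
        tree = build_nj(DistanceMatrix(ids=ids, matrix=m))
        leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
        assert leaves["a"].parent_node is leaves["b"].parent_node

    def test_three_taxa_closed_form(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 2.5], [2.0, 2.5, 0.0]])
        tree = build_nj(DistanceMatrix(ids=("x", "y", "z"), matrix=m))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert math.isclose(lengths["x"], 0.25)   # (1 + 2 - 2.5)/2
        assert math.isclose(lengths["y"], 0.75)
        assert math.isclose(lengths["z"], 1.75)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_additive_matrices_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        m = random_additive_tree_matrix(rng, n)
        ids = tuple(f"t{i}" for i in range(n))
        tree = build_nj(DistanceMatrix(ids=ids, matrix=m))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                assert math.isclose(
                    pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]]), m[i, j],
                    abs_tol=1e-9,
                )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=("a", "b", "c"),
                           matrix=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))


class TestClassification:
    def test_query_identical_to_class1_reference(self):
        rng = np.random.default_rng(30)
        refs, labels, anc = make_class_references(rng)
        q = ProtSequence(id="q", residues=refs[0].residues)  # a classI ref copy
        a = place_one_by_one([q], refs, labels)[0]
        assert a.assigned_class == "classI"

    def test_simulated_queries_mostly_correct(self):
        rng = np.random.default_rng(31)
        refs, labels, anc = make_class_references(rng)
        correct = 0
        n = 40
        for i in range(n):
            cls = "classI" if i % 2 == 0 else "classII"
            q = ProtSequence(
                id=f"q{i}",
                residues=_mutate_protein(rng, anc[cls], float(rng.uniform(0.05, 0.2))),
            )
            a = place_one_by_one([q], refs, labels)[0]
            correct += a is not None and a.assigned_class == cls
        assert correct >= 0.95 * n

    def test_equidistant_tie_goes_to_class2_with_nearest_method(self):
        # star-ish constructed matrix: query exactly between the two classes
        ids = ("I_a", "I_b", "II_a", "II_b", "q")
        m = np.array([
            [0.0, 0.2, 1.0, 1.0, 0.6],
            [0.2, 0.0, 1.0, 1.0, 0.6],
            [1.0, 1.0, 0.0, 0.2, 0.6],
            [1.0, 1.0, 0.2, 0.0, 0.6],
            [0.6, 0.6, 0.6, 0.6, 0.0],
        ])
        tree = build_nj(DistanceMatrix(ids=ids, matrix=m))
        labels = {"I_a": "classI", "I_b": "classI",
                  "II_a": "classII", "II_b": "classII"}
        a = classify_by_tree(tree, labels, "q")
        assert a.assigned_class == "classII"
        assert a.method == "nearest"

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(32)
        refs, labels, anc = make_class_references(rng)
        q = ProtSequence(id="q", residues=_mutate_protein(rng, anc["classI"], 0.1))
        first = place_one_by_one([q], refs, labels)[0]
        second = place_one_by_one([q], list(reversed(refs)), labels)[0]
        assert first.assigned_class == second.assigned_class == "classI"

    def test_missing_reference_class_is_error(self):
        rng = np.random.default_rng(33)
        refs, labels, anc = make_class_references(rng)
        only1 = {k: v for k, v in labels.items() if v == "classI"}
        q = ProtSequence(id="q", residues=_mutate_protein(rng, anc["classI"], 0.1))
        msa = refs + [ProtSequence(id="q", residues=q.residues)]
        from chemomine.phyloclass import protein_distance

        tree = build_nj(protein_distance(msa))
        with pytest.raises(ValueError):
            classify_by_tree(tree, only1, "q")


class TestOneByOnePlacement:
    def test_fragments_of_class2_gene_both_class2_any_order(self):
        rng = np.random.default_rng(34)
        refs, labels, anc = make_class_references(rng)
        gene = _mutate_protein(rng, anc["classII"], 0.12)
        half = len(gene) // 2
        frags = [ProtSequence(id="f1", residues=gene[:half]),
                 ProtSequence(id="f2", residues=gene[half:])]
        fwd = place_one_by_one(frags, refs, labels)
        rev = place_one_by_one(list(reversed(frags)), refs, labels)[::-1]
        assert all(a.assigned_class == "classII" for a in fwd)
        assert [a.assigned_class for a in fwd] == [a.assigned_class for a in rev]

    def test_cterminal_fragment_of_class1_reference(self):
        rng = np.random.default_rng(35)
        refs, labels, anc = make_class_references(rng)
        frag = ProtSequence(id="f", residues=refs[0].residues[-90:])
        a = place_one_by_one([frag], refs, labels)[0]
        assert a.assigned_class == "classI"

    def test_too_short_fragment_unassigned(self):
        rng = np.random.default_rng(36)
        refs, labels, anc = make_class_references(rng)
        stub = ProtSequence(id="stub", residues=refs[0].residues[:12])
        assert place_one_by_one([stub], refs, labels) == [None]

    def test_empty_query_list(self):
        rng = np.random.default_rng(37)
        refs, labels, _ = make_class_references(rng)
        assert place_one_by_one([], refs, labels) == []


class TestDnDs:
    def test_identical_sequences_undefined_omega(self):
        r = dnds_nei_gojobori("ATGAAACCG" * 20, "ATGAAACCG" * 20)
        assert r.dn == 0.0 and r.ds == 0.0 and r.omega is None

    def test_synonymous_only_pair(self):
        a = "GCT" * 90 + "GCC" * 10
        b = "GCT" * 100
        r = dnds_nei_gojobori(a, b)
        assert r.dn == 0.0 and r.ds > 0.0 and r.omega == 0.0

    def test_nine_codon_hand_oracle(self):
        """Pathway counts worked out by hand (and double-checked against an
        independent enumeration): S=5.5, N=21.5, Sd=3, Nd=2."""
        a = "TTTGCTATGACCGAAAAACCGTATGGG"
        b = "TTTGCTATGACAGATAGGCCGTACGGG"
        r = dnds_nei_gojobori(a, b)
        assert math.isclose(r.syn_sites, 5.5, abs_tol=1e-9)
        assert math.isclose(r.nonsyn_sites, 21.5, abs_tol=1e-9)
        assert math.isclose(r.syn_diffs, 3.0, abs_tol=1e-9)
        assert math.isclose(r.nonsyn_diffs, 2.0, abs_tol=1e-9)
        assert math.isclose(r.ds, 0.974462, abs_tol=1e-6)
        assert math.isclose(r.dn, 0.099318, abs_tol=1e-6)
        assert math.isclose(r.omega, 0.101921, abs_tol=1e-6)

    @pytest.mark.parametrize(
        "a,b",
        [("ATGAA", "ATGAA"), ("ATGAAATTT", "ATGAAA"), ("ATGTGAAAA", "ATGTGCAAA")],
        ids=["not-codon-multiple", "unequal-length", "internal-stop"],
    )
    def test_invalid_input_rejected(self, a, b):
        with pytest.raises(ValueError):
            dnds_nei_gojobori(a, b)

    def test_purifying_selection_gives_omega_below_one(self):
        from chemomine.benchmarks import dnds_selection_simulation

        res = dnds_selection_simulation(seed=50, n_replicates=25)
        assert res["omega_lt1_pct"] >= 95.0

    def test_neutral_evolution_omega_near_one(self):
        from chemomine.benchmarks import dnds_neutral_simulation

        res = dnds_neutral_simulation(seed=51, n_codons=500)
        assert 0.8 <= res["mean_omega"] <= 1.25
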