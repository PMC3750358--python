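"""K2P distances, neighbour joining, bootstrap, divergence summaries."""
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as st

import bulkbarcode as bb
from bulkbarcode.validation import DistanceMatrix, SaturationError, species_monophyly


def seq_pair(P: float, Q: float, n: int = 100):
    """Aligned pair with exactly P*n transition and Q*n transversion differences."""
    nP, nQ = round(P * n), round(Q * n)
    a = "A" * n
    b = "G" * nP + "C" * nQ + "A" * (n - nP - nQ)  # A->G transition, A->C transversion
    return a, b


class TestK2P:
    def test_identical_is_zero(self):
        assert bb.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    @pytest.mark.parametrize(
        "P,Q",
        [(0.1, 0.05), (0.02, 0.0), (0.0, 0.04), (0.2, 0.1)],
    )
    def test_closed_form(self, P, Q):
        a, b = seq_pair(P, Q)
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert bb.k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_spec_worked_value(self):
        a, b = seq_pair(0.1, 0.05)
        assert bb.k2p_distance(a, b) == pytest.approx(0.1702, abs=1e-4)

    def test_transition_only_limit(self):
        for P in (0.01, 0.05, 0.1):
            a, b = seq_pair(P, 0.0)
            assert bb.k2p_distance(a, b) == pytest.approx(-0.5 * math.log(1 - 2 * P), rel=1e-12)

    def test_ambiguous_sites_pairwise_deleted(self):
        # N site excluded from numerator and denominator: P=1/4 over 4 sites
        assert bb.k2p_distance("ACGTN", "GCGTA") == bb.k2p_distance("ACGT", "GCGT")

    def test_saturation_flagged(self):
        a = "A" * 10
        b = "C" * 10  # Q = 1: 1-2Q < 0
        with pytest.raises(SaturationError):
            bb.k2p_distance(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bb.k2p_distance("ACGT", "ACG")

    @given(st.integers(0, 999))
    def test_symmetric_and_revcomp_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(
            c if rng.random() > 0.1 else rng.choice([x for x in "ACGT" if x != c])
            for c in a
        )
        d = bb.k2p_distance(a, b)
        assert bb.k2p_distance(b, a) == d
        assert bb.k2p_distance(bb.revcomp(a), bb.revcomp(b)) == pytest.approx(d, rel=1e-12)


class TestPairwiseMatrix:
    def test_identical_sequences_zero_matrix(self):
        m = bb.pairwise_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.all(m.d == 0)

    def test_two_sequences_single_value(self):
        a, b = seq_pair(0.1, 0.05)
        m = bb.pairwise_matrix({"x": a, "y": b})
        assert m.d[0, 1] == bb.k2p_distance(a, b)

    def test_matches_per_pair_recomputation(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), 343)) for i in range(10)
        }
        m = bb.pairwise_matrix(seqs)
        labels = list(seqs)
        for i in range(10):
            for j in range(i + 1, 10):
                try:
                    expected = bb.k2p_distance(seqs[labels[i]], seqs[labels[j]])
                    assert m.d[i, j] == expected
                except SaturationError:
                    assert (labels[i], labels[j]) in m.excluded

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            bb.pairwise_matrix({"only": "ACGT"})


def random_additive_matrix(n_taxa, seed):
    """Path-length matrix of a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, taxon_namespace=taxa,
        rng=__import__("random").Random(seed),
    )
    for edge in tree.preorder_edge_iter():
        edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(n_taxa):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def tree_path_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = bb.neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 1), (8, 2), (12, 3)])
    def test_additive_matrix_recovered_exactly(self, n_taxa, seed):
        m = random_additive_matrix(n_taxa, seed)
        tree = bb.neighbor_joining(m, clamp_negative=False)
        labels, d = tree_path_distances(tree)
        order = [labels.index(lab) for lab in sorted(m.labels)]
        orig = m.d[np.ix_(np.argsort(m.labels), np.argsort(m.labels))]
        assert np.allclose(d, orig, atol=1e-9)

    def test_agrees_with_independent_nj_on_additive_input(self):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        m = random_additive_matrix(7, seed=42)
        ours = bb.neighbor_joining(m, clamp_negative=False)
        theirs_newick = skbio_nj(SkbioDM(m.d, ids=m.labels)).__str__()
        theirs = dendropy.Tree.get(
            data=theirs_newick, schema="newick", taxon_namespace=ours.taxon_namespace
        )
        theirs.encode_bipartitions()
        ours.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(ours, theirs)
        assert rf == 0

    def test_zero_distance_pair_are_siblings(self):
        base = "ACGTACGTAC" * 20
        a = base[:100] + "TTTTTTTT" + base[108:]  # shared derived sites -> internal edge
        seqs = {
            "a1": a,
            "a2": a,
            "b": "GGGGG" + base[5:],
            "c": base[:50] + "AAAAA" + base[55:],
        }
        tree = bb.neighbor_joining(bb.pairwise_matrix(seqs))
        a1 = tree.find_node_with_taxon_label("a1")
        siblings = [c.taxon.label for c in a1.parent_node.child_nodes() if c.taxon]
        assert set(siblings) == {"a1", "a2"}

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], d)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            bb.neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestBootstrap:
    def test_b1_supports_are_zero_or_hundred(self, coi_seqs):
        sub = {k: coi_seqs[k] for k in list(coi_seqs)[:9]}
        tree = bb.bootstrap_support(sub, B=1, seed=5)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None and n.taxon is None
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_identical_supports(self, coi_seqs):
        sub = {k: coi_seqs[k] for k in list(coi_seqs)[:9]}
        t1 = bb.bootstrap_support(sub, B=20, seed=7)
        t2 = bb.bootstrap_support(sub, B=20, seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_well_separated_clusters_get_high_support(self):
        db = bb.simulate_reference_db(n_species=2, n_per_species=5, seed=13)
        seqs = {r.specimen_id: r.sequence for r in db.by_gene("COI")}
        species_of = {r.specimen_id: r.species for r in db.by_gene("COI")}
        tree = bb.bootstrap_support(seqs, B=100, seed=3)
        mono = species_monophyly(tree, species_of)
        assert all(s is not None and s >= 95.0 for s in mono.values())

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bb.bootstrap_support({"a": "A", "b": "C", "c": "G"}, B=10, seed=0)


class TestDivergenceSummary:
    def test_monomorphic_species_intra_zero(self):
        db = bb.ReferenceDB(
            [
                bb.SpeciesRecord("a1", "A a", "COI", "ACGTACGTAC"),
                bb.SpeciesRecord("a2", "A a", "COI", "ACGTACGTAC"),
                bb.SpeciesRecord("b1", "B b", "COI", "ACGTACGTCC"),
                bb.SpeciesRecord("b2", "B b", "COI", "ACGTACGTCC"),
            ]
        )
        out = bb.divergence_summary(db)
        assert out["COI"]["intra"] == (0.0, 0.0)

    def test_single_species_inter_absent(self):
        db = bb.ReferenceDB(
            [
                bb.SpeciesRecord("a1", "A a", "COI", "ACGTACGTAC"),
                bb.SpeciesRecord("a2", "A a", "COI", "ACGTACGAAC"),
            ]
        )
        out = bb.divergence_summary(db)
        assert out["COI"]["inter"] is None
        assert out["COI"]["intra"] is not None

    def test_programmed_divergence_bracketed(self):
        db = bb.simulate_reference_db(
            n_species=10, n_per_species=4, intra_divergence=0.02, inter_divergence=0.12, seed=17
        )
        out = bb.divergence_summary(db)
        for gene in ("COI", "CytB"):
            lo, hi = out[gene]["intra"]
            assert lo <= 2.0 <= hi
            lo, hi = out[gene]["inter"]
            assert lo <= 12.0 <= hi


class TestBarcodeGapProperty:
    def test_species_form_single_clades_when_gap_is_wide(self):
        # programmed inter/intra ratio 6x: every species should be a clade
        db = bb.simulate_reference_db(
            n_species=6, n_per_species=4, intra_divergence=0.02, inter_divergence=0.12, seed=23
        )
        seqs = {r.specimen_id: r.sequence for r in db.by_gene("CytB")}
        species_of = {r.specimen_id: r.species for r in db.by_gene("CytB")}
        tree = bb.neighbor_joining(bb.pairwise_matrix(seqs))
        mono = species_monophyly(tree, species_of)
        assert all(s is not None for s in mono.values())
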