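"""Tests for translation, identity, distances, NJ and bootstrap."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from conftest import tree_path_distances
from rnrkit.errors import DomainError
from rnrkit.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    correct_distance,
    neighbor_joining,
    pairwise_identity,
    protein_distance,
    scan_ken_box,
    translate_cds,
)


def make_alignment(seqs: dict) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()])


class TestTranslate:
    def test_two_codons_then_stop(self):
        assert translate_cds("ATGAAATAA") == "MK"

    def test_length_bookkeeping_793(self):
        cds = "ATG" * 793 + "TAA"
        assert len(translate_cds(cds)) == 793

    def test_internal_stop_rejected_in_strict_mode(self):
        with pytest.raises(DomainError, match="internal stop"):
            translate_cds("ATGTAAAAATAA")
        assert translate_cds("ATGTAAAAATAA", strict=False) == "M"

    def test_bad_length_and_characters_rejected(self):
        with pytest.raises(DomainError):
            translate_cds("ATGA")
        with pytest.raises(DomainError):
            translate_cds("ATGXXX")


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKWVTFISLL", "MKWVTFISLL") == 100.0

    def test_single_substitution_in_ten(self):
        assert pairwise_identity("MKWVTFISLL", "MKWVTFISLV") == pytest.approx(90.0)

    def test_symmetric(self):
        a, b = "MKWVTFISLLFLFSSAYS", "MKWVTFLSLLFLFSSGYS"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DomainError):
            pairwise_identity("", "MK")


class TestDistances:
    def test_identical_rows_are_zero_under_every_model(self):
        aln = make_alignment({"a": "MKWVTFISLL", "b": "MKWVTFISLL"})
        for model in ("p", "poisson", "kimura"):
            assert protein_distance(aln, model).matrix[0, 1] == 0.0

    def test_poisson_closed_form(self):
        assert correct_distance(0.1, "poisson") == pytest.approx(0.10536, abs=1e-5)

    def test_kimura_closed_form(self):
        assert correct_distance(0.1, "kimura") == pytest.approx(0.10758, abs=1e-5)

    def test_corrections_agree_with_p_in_the_small_p_limit(self):
        p = 1e-4
        assert correct_distance(p, "poisson") == pytest.approx(p, abs=1e-6)
        assert correct_distance(p, "kimura") == pytest.approx(p, abs=1e-6)

    def test_pairwise_gap_deletion(self):
        # gap columns drop out pairwise: 1 mismatch in 8 comparable columns
        aln = make_alignment({"a": "MKWVTF-SLL", "b": "MKWVTY-SL-"})
        assert protein_distance(aln, "p").matrix[0, 1] == pytest.approx(1 / 8)

    def test_saturated_pair_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = correct_distance(0.999, "kimura")
        assert math.isfinite(d)

    def test_all_gap_pair_rejected(self):
        aln = make_alignment({"a": "--", "b": "--"})
        with pytest.raises(DomainError):
            protein_distance(aln, "p")

    def test_taxon_permutation_equivariance(self):
        seqs = {"a": "MKWVTFISLL", "b": "MKWVTYISLL", "c": "MKAVTYISLV"}
        fwd = protein_distance(make_alignment(seqs))
        rev = protein_distance(make_alignment(dict(reversed(seqs.items()))))
        for x, y in itertools.combinations(seqs, 2):
            assert fwd[x, y] == rev[x, y]


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths (oracle input)."""
    from Bio.Phylo.BaseTree import Clade, Tree

    nodes = [Clade(name=f"t{i}", branch_length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Clade(branch_length=float(rng.uniform(0.05, 1.0)))
        parent.clades = [nodes[i], nodes[j]]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = Clade()
    root.clades = nodes
    return Tree(root=root, rooted=False)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(d)
        lengths = {c.name: c.branch_length for c in tree.root.clades}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_matrix_exact(self):
        # ((A:1,B:2):1,(C:3,D:4)) as a distance matrix
        mat = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                        [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), mat))
        labels, recovered = tree_path_distances(tree)
        assert labels == list("ABCD")
        assert np.allclose(recovered, mat, atol=1e-12)
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_four_taxon_topology_matches_brute_force_least_squares(self):
        """Enumerate all three quartet topologies, fit branch lengths by
        least squares, and check NJ picks the best-fitting one."""
        rng = np.random.default_rng(5)
        tree = random_additive_tree(4, rng)
        labels, mat = tree_path_distances(tree)
        nj = neighbor_joining(DistanceMatrix(labels, mat))
        # brute force: topology AB|CD encoded by the pair grouped together
        pair_index = {tuple(sorted(p)): None for p in
                      [("t0", "t1"), ("t0", "t2"), ("t0", "t3")]}
        best = None
        for a, b in pair_index:
            c, d = [x for x in labels if x not in (a, b)]
            # design matrix for the 5 branch lengths of topology ab|cd
            idx = {name: i for i, name in enumerate([a, b, c, d])}
            rows, rhs = [], []
            for x, y in itertools.combinations(labels, 2):
                row = np.zeros(5)
                row[idx[x]] = 1
                row[idx[y]] = 1
                same_side = {x, y} in ({a, b}, {c, d})
                if not same_side:
                    row[4] = 1
                rows.append(row)
                rhs.append(mat[labels.index(x), labels.index(y)])
            sol, resid, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs),
                                             rcond=None)
            sse = float(np.sum((np.array(rows) @ sol - rhs) ** 2))
            if best is None or sse < best[0]:
                best = (sse, frozenset({a, b}))
        nj_parts = bipartitions(nj)
        anchor_side = next(iter(nj_parts))
        complement = frozenset(labels) - anchor_side
        assert best[1] in (anchor_side, complement)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrices_reproduced_exactly(self, n_taxa):
        """NJ on additive input returns a tree whose path lengths equal
        the input distances (direct-construction oracle)."""
        rng = np.random.default_rng(n_taxa)
        tree = random_additive_tree(n_taxa, rng)
        labels, mat = tree_path_distances(tree)
        nj = neighbor_joining(DistanceMatrix(labels, mat))
        _, recovered = tree_path_distances(nj)
        assert np.allclose(recovered, mat, atol=1e-9)

    def test_topology_invariant_to_taxon_order(self):
        rng = np.random.default_rng(17)
        tree = random_additive_tree(6, rng)
        labels, mat = tree_path_distances(tree)
        perm = rng.permutation(len(labels))
        shuffled = DistanceMatrix([labels[i] for i in perm],
                                  mat[np.ix_(perm, perm)])
        assert (bipartitions(neighbor_joining(shuffled))
                == bipartitions(neighbor_joining(DistanceMatrix(labels, mat))))

    def test_matches_dendropy_on_random_matrix(self):
        """Independent NJ oracle: dendropy on the same distances."""
        import io

        import dendropy

        rng = np.random.default_rng(23)
        n = 6
        labels = [f"t{i}" for i in range(n)]
        noise = rng.uniform(0.1, 1.0, (n, n))
        mat = (noise + noise.T) / 2
        np.fill_diagonal(mat, 0.0)
        ours = bipartitions(neighbor_joining(DistanceMatrix(labels, mat)))
        csv = "x," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(mat[i, j]) for j in range(n))
            for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        full = frozenset(labels)
        anchor = min(full)
        theirs = set()
        for edge in dtree.preorder_edge_iter():
            if edge.bipartition is None:
                continue
            side = frozenset(t.taxon.label for t in edge.head_node.leaf_iter())
            if anchor in side:
                side = full - side
            if 1 < len(side) < n - 1:
                theirs.add(side)
        assert ours == theirs

    def test_degenerate_equal_distances_still_builds_a_tree(self):
        n = 5
        mat = np.ones((n, n)) - np.eye(n)
        labels = [f"t{i}" for i in range(n)]
        tree_a = neighbor_joining(DistanceMatrix(labels, mat))
        tree_b = neighbor_joining(DistanceMatrix(labels, mat))
        assert len(tree_a.get_terminals()) == n
        assert bipartitions(tree_a) == bipartitions(tree_b)  # deterministic ties

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(DomainError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0]], float)))


class TestBootstrap:
    def _family(self, rng, n_per_clade=3, length=120, divergence=60):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base1 = "".join(rng.choice(list(aa), length))
        base2 = list(base1)
        for i in rng.choice(length, divergence, replace=False):
            base2[i] = aa[rng.integers(20)]
        seqs = {}
        for c, base in (("x", base1), ("y", "".join(base2))):
            for i in range(n_per_clade):
                s = list(base)
                for j in rng.choice(length, 4, replace=False):
                    s[j] = aa[rng.integers(20)]
                seqs[f"{c}{i}"] = "".join(s)
        return make_alignment(seqs)

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(0)
        tree = bootstrap_support(self._family(rng), n_reps=1, seed=1)
        supports = [c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None]
        assert supports and all(s in (0, 1) for s in supports)

    def test_same_seed_identical_supports(self):
        rng = np.random.default_rng(1)
        aln = self._family(rng)
        t1 = bootstrap_support(aln, n_reps=50, seed=7)
        t2 = bootstrap_support(aln, n_reps=50, seed=7)
        s1 = [c.confidence for c in t1.get_nonterminals()]
        s2 = [c.confidence for c in t2.get_nonterminals()]
        assert s1 == s2

    def test_star_family_has_weak_internal_support(self):
        """A family evolved on a star tree carries no internal signal, so
        no split should approach full support."""
        from rnrkit.synth import PhyloScenario, ScenarioConfig, simulate_protein_family

        star = "(" + ",".join(f"t{i}:0.3" for i in range(6)) + ");"
        fam = simulate_protein_family(ScenarioConfig(seed=2, phylo=PhyloScenario(
            guide_tree_newick=star, sequence_length=300)))
        tree = bootstrap_support(fam["alignment"], n_reps=100, seed=3)
        supports = [c.confidence for c in tree.get_nonterminals()
                    if c.confidence is not None]
        assert supports and all(s < 75 for s in supports)

    def test_short_alignment_warns(self):
        aln = make_alignment({"a": "MKWVT", "b": "MKWVT", "c": "MKAVT"})
        with pytest.warns(UserWarning, match="shorter"):
            bootstrap_support(aln, n_reps=2, seed=0)


class TestKenBox:
    def test_minimal_motif_span(self):
        assert scan_ken_box("AAKENAA") == [(3, 5)]

    def test_absent_motif(self):
        assert scan_ken_box("MKWVTFISLL") == []

    def test_multiple_and_overlapping_hits(self):
        assert scan_ken_box("KENKEN") == [(1, 3), (4, 6)]
        assert scan_ken_box("KENEN") == [(1, 3)]

    def test_extended_consensus(self):
        assert scan_ken_box("AAKENAAAQAA", extended=True) == []
        assert scan_ken_box("AAKENAAADAA", extended=True) == [(3, 9)]

    def test_span_inside_n_terminal_window(self):
        # a KEN box planted where the carp p53R2ii motif sits (24-36)
        seq = "M" + "A" * 24 + "KEN" + "A" * 40
        (start, end), = scan_ken_box(seq)
        assert 24 <= start and end <= 36
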