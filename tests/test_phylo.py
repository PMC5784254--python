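"""Alignment, trimming, WAG distances, NJ, bootstrap and clade reports."""

import itertools

import numpy as np
import pytest

from gpcrmine import phylo
from gpcrmine.phylo import (
    GAP_EXTEND,
    GAP_OPEN,
    MultipleAlignment,
    TreeNode,
    bipartitions,
    blosum62,
    bootstrap_support,
    distance_matrix,
    evaluate_type_clades,
    neighbor_joining,
    pairwise_align,
    parse_newick,
    progressive_align,
    robinson_foulds,
    trim_gap_columns,
    wag_distance,
)
from gpcrmine.profiles import AA
from gpcrmine.synthetic import FamilySimSpec, simulate_family
from gpcrmine.wag import default_model


def brute_force_affine_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive enumeration of all global alignments (tiny inputs only)."""
    best = -np.inf

    def score_gap(length):
        return -(gap_open + (length - 1) * gap_extend) if length else 0.0

    def recurse(i, j, acc, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            s = matrix[AA.index(a[i]), AA.index(b[j])]
            recurse(i + 1, j + 1, acc + s, "m")
        if i < len(a):
            cost = -gap_extend if last == "x" else -gap_open
            recurse(i + 1, j, acc + cost, "x")
        if j < len(b):
            cost = -gap_extend if last == "y" else -gap_open
            recurse(i, j + 1, acc + cost, "y")

    recurse(0, 0, 0.0, "")
    return best


class TestPairwiseAlign:
    def test_identical_sequences_align_without_gaps(self):
        a = "ACDEFGHIKL"
        out_a, out_b, score = pairwise_align(a, a)
        assert out_a == out_b == a
        expected = sum(blosum62()[AA.index(c), AA.index(c)] for c in a)
        assert score == pytest.approx(expected)

    def test_textbook_pair_matches_independent_dp(self):
        # cross-checked against Biopython's affine-gap global aligner
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        expected = aligner.score("HEAGAWGHEE", "PAWHEAE")
        _, _, score = pairwise_align("HEAGAWGHEE", "PAWHEAE",
                                     gap_open=10.0, gap_extend=1.0)
        assert score == pytest.approx(expected)

    def test_alignment_against_empty_is_a_single_gap_run(self):
        a = "ACDEF"
        out_a, out_b, score = pairwise_align(a, "")
        assert out_a == a and out_b == "-----"
        assert score == pytest.approx(-(GAP_OPEN + GAP_EXTEND * (len(a) - 1)))

    @pytest.mark.parametrize("a,b", [
        ("ACD", "AD"), ("WWWW", "WW"), ("KR", "KKRR"), ("ACDEF", "FEDCA"),
    ])
    def test_dp_score_equals_exhaustive_enumeration(self, a, b):
        matrix = blosum62()
        _, _, score = pairwise_align(a, b)
        oracle = brute_force_affine_score(a, b, matrix, GAP_OPEN, GAP_EXTEND)
        assert score == pytest.approx(oracle)

    def test_aligned_rows_ungap_to_inputs(self):
        a, b = "MKKVLITGGAGY", "MKVLITGAGY"
        out_a, out_b, _ = pairwise_align(a, b)
        assert out_a.replace("-", "") == a
        assert out_b.replace("-", "") == b
        assert len(out_a) == len(out_b)


class TestProgressiveAlign:
    def test_identical_sequences_produce_gap_free_alignment(self):
        seqs = [(f"s{i}", "MKVLITGGAGY") for i in range(4)]
        msa = progressive_align(seqs)
        assert all(row == "MKVLITGGAGY" for row in msa.rows)

    def test_zero_divergence_family_is_fully_conserved(self):
        tree = "((a:0,b:0):0,(c:0,d:0):0);"
        records, _, _ = simulate_family(
            FamilySimSpec(tree=tree, root_sequence_length=60, seed=1))
        msa = progressive_align([(r.id, r.seq) for r in records])
        for j in range(msa.n_cols):
            assert len(set(msa.column(j))) == 1

    def test_low_divergence_homologous_pairs_mostly_aligned(self):
        tree = "((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);"
        spec = FamilySimSpec(tree=tree, root_sequence_length=150,
                             indel_rate=0.02, seed=4)
        records, _, homology = simulate_family(spec)
        msa = progressive_align([(r.id, r.seq) for r in records])
        correct = total = 0
        for (i, a), (j, b) in itertools.combinations(enumerate(msa.ids), 2):
            sites_a, sites_b = homology[a], homology[b]
            truth_pairs = set(sites_a) & set(sites_b)
            # recover aligned residue pairs from the alignment columns
            pos_a = pos_b = 0
            for col in range(msa.n_cols):
                ca, cb = msa.rows[i][col], msa.rows[j][col]
                if ca != "-" and cb != "-":
                    if sites_a[pos_a] == sites_b[pos_b]:
                        correct += 1
                if ca != "-":
                    pos_a += 1
                if cb != "-":
                    pos_b += 1
            total += len(truth_pairs)
        assert correct / total >= 0.95

    def test_row_order_preserved(self):
        seqs = [("z", "ACDEF"), ("a", "ACDEF"), ("m", "ACDDF")]
        msa = progressive_align(seqs)
        assert msa.ids == ["z", "a", "m"]


class TestTrim:
    def test_gap_free_alignment_unchanged(self):
        msa = MultipleAlignment(ids=list("abcd"), rows=["ACD"] * 4)
        trimmed, kept = trim_gap_columns(msa)
        assert trimmed.rows == msa.rows
        assert kept == [0, 1, 2]

    def test_half_gapped_column_removed_quarter_gapped_retained(self):
        rows = ["A-CA", "A-CA", "AGC-", "AGCA"]  # col2: 2/4 gaps; col4: 1/4
        msa = MultipleAlignment(ids=list("abcd"), rows=rows)
        trimmed, kept = trim_gap_columns(msa, 0.25)
        assert kept == [0, 2, 3]  # strictly-more-than rule keeps 0.25
        assert trimmed.rows[0] == "ACA"

    def test_fully_gapped_input_returns_empty_alignment(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["--", "--"])
        trimmed, kept = trim_gap_columns(msa)
        assert trimmed.n_cols == 0 and kept == []

    def test_retained_columns_exactly_satisfy_rule_by_recount(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("AC-"), size=50, p=[.4, .3, .3]))
                for _ in range(8)]
        msa = MultipleAlignment(ids=[str(i) for i in range(8)], rows=rows)
        trimmed, kept = trim_gap_columns(msa, 0.25)
        for j in range(50):
            frac = sum(r[j] == "-" for r in rows) / 8
            assert (j in kept) == (frac <= 0.25)


class TestWagDistance:
    def test_identical_rows_have_zero_distance(self):
        assert wag_distance("ACDEFGHIKL", "ACDEFGHIKL") == 0.0

    def test_distance_monotone_in_simulated_divergence(self):
        model = default_model()
        rng = np.random.default_rng(6)
        root = rng.choice(20, size=800, p=model.pi)
        estimates = []
        for t in (0.05, 0.2, 0.6, 1.2):
            p = model.transition_matrix(t)
            cum = p.cumsum(axis=1)
            child = (rng.random(800)[:, None] > cum[root]).sum(axis=1)
            a = "".join(AA[i] for i in root)
            b = "".join(AA[i] for i in child)
            estimates.append(wag_distance(a, b))
        assert estimates == sorted(estimates)

    def test_disjoint_gap_patterns_are_undefined(self):
        assert np.isnan(wag_distance("A--", "--A"))

    def test_aligned_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wag_distance("ACD", "AC")


def additive_matrix_from_tree(newick):
    """Path-length distances between all leaf pairs (the additivity oracle)."""
    tree = parse_newick(newick)
    leaves = tree.leaf_names()

    def paths(node, acc, out):
        if node.is_leaf:
            out[node.name] = acc
        for child in node.children:
            paths(child, acc + [(child, child.length)], out)

    out = {}
    paths(tree, [], out)
    n = len(leaves)
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i >= j:
                continue
            ea = {id(e): l for e, l in out[a]}
            eb = {id(e): l for e, l in out[b]}
            shared = set(ea) & set(eb)
            d = sum(l for k, l in ea.items() if k not in shared)
            d += sum(l for k, l in eb.items() if k not in shared)
            D[i, j] = D[j, i] = d
    return D, leaves, tree


class TestNeighborJoining:
    NEWICK5 = "((a:0.2,b:0.3):0.15,(c:0.25,d:0.1):0.05,e:0.4);"

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        D, ids, true_tree = additive_matrix_from_tree(self.NEWICK5)
        tree = neighbor_joining(D, ids)
        assert robinson_foulds(tree, true_tree) == 0
        # branch lengths: recompute path distances from the NJ tree
        D2, ids2, _ = additive_matrix_from_tree(tree.to_newick(False))
        order = [ids2.index(x) for x in ids]
        assert np.allclose(D2[np.ix_(order, order)], D, atol=1e-9)

    def test_three_taxa_solve_the_three_point_formulas(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (5 + 9 - 10))
        assert lengths["b"] == pytest.approx(0.5 * (5 + 10 - 9))
        assert lengths["c"] == pytest.approx(0.5 * (9 + 10 - 5))

    def test_matches_independent_nj_implementation(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj

        D, ids, _ = additive_matrix_from_tree(
            "((a:0.4,b:0.15):0.2,((c:0.3,d:0.21):0.1,e:0.5):0.08,f:0.3);")
        ours = neighbor_joining(D, ids)
        theirs = nj(DistanceMatrix(D, ids))
        our_splits = set(bipartitions(ours))
        their_splits = set()
        all_leaves = frozenset(ids)
        ref = min(ids)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(ids) - 2:
                their_splits.add(side)
        assert our_splits == their_splits

    def test_negative_branch_lengths_clamped(self):
        # a matrix violating the triangle structure yields negative NJ
        # estimates that must be clamped to zero
        D = np.array([
            [0.0, 0.1, 0.5, 0.55],
            [0.1, 0.0, 0.45, 0.5],
            [0.5, 0.45, 0.0, 0.05],
            [0.55, 0.5, 0.05, 0.0],
        ])
        tree = neighbor_joining(D, list("abcd"))
        for node in tree.walk():
            assert node.length >= 0

    def test_undefined_distances_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, list("abc"))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])


@pytest.fixture(scope="module")
def clade_family():
    tree = "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);"
    records, _, _ = simulate_family(
        FamilySimSpec(tree=tree, root_sequence_length=300, seed=9))
    return MultipleAlignment(ids=[r.id for r in records],
                             rows=[r.seq for r in records])


class TestBootstrap:

    def test_single_replicate_supports_are_zero_or_hundred(self, clade_family):
        _, support = bootstrap_support(clade_family, n_replicates=1, seed=0)
        assert set(support.values()) <= {0.0, 100.0}

    def test_identical_seed_gives_identical_supports(self, clade_family):
        _, s1 = bootstrap_support(clade_family, n_replicates=20, seed=3)
        _, s2 = bootstrap_support(clade_family, n_replicates=20, seed=3)
        assert s1 == s2

    def test_deep_split_between_clades_strongly_supported(self, clade_family):
        tree, support = bootstrap_support(clade_family, n_replicates=100,
                                          seed=1)
        split = frozenset({"c", "d"})
        assert split in support
        assert support[split] >= 90.0


class TestTypeClades:
    def test_single_leaf_type_is_trivially_monophyletic(self):
        tree = parse_newick("((a:1,b:1):1,c:1,d:1);")
        report = evaluate_type_clades(
            tree, {"a": "I", "b": "I", "c": "II", "d": "III"})
        assert report["II"]["monophyletic"]
        assert report["III"]["monophyletic"]

    def test_interleaved_labels_on_star_tree_not_monophyletic(self):
        tree = parse_newick("(a:1,b:1,c:1,d:1);")
        report = evaluate_type_clades(
            tree, {"a": "I", "b": "II", "c": "I", "d": "II"})
        assert not report["I"]["monophyletic"]
        assert not report["II"]["monophyletic"]

    def test_unlabeled_leaf_rejected(self):
        tree = parse_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError):
            evaluate_type_clades(tree, {"a": "I", "b": "I"})


class TestNewick:
    def test_roundtrip_preserves_topology_and_lengths(self):
        text = "((a:0.100000,b:0.200000):0.050000,c:0.300000);"
        tree = parse_newick(text)
        assert sorted(tree.leaf_names()) == ["a", "b", "c"]
        again = parse_newick(tree.to_newick(with_support=False))
        assert robinson_foulds(tree, again) == 0
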