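"""Alignment, distances, NJ, JTT maximum likelihood, bootstrap, clades."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.linalg import expm

from sepmine.io_formats import SeqRecord
from sepmine.jtt import JttModel
from sepmine.msa_phylo import (
    MSA,
    DistanceMatrix,
    MLEngine,
    _AA,
    _MLTree,
    assign_to_reference_clades,
    bootstrap_support,
    build_msa,
    ml_optimize,
    nj_tree,
    partition_clades,
    protein_distance,
)
from sepmine.synthetic_data.families import evolve_sequence, random_protein
from sepmine.tree import parse_newick

MODEL = JttModel(order=_AA[:20])


def _global_score(rows):
    """Score an alignment under BLOSUM62 with affine gaps (open 11, ext 1)."""
    mat = substitution_matrices.load("BLOSUM62")
    score, state = 0.0, None
    for x, y in zip(*rows):
        if x == "-" or y == "-":
            s = "x" if y == "-" else "y"
            score += -11 if state != s else -1
            state = s
        else:
            score += mat[x, y]
            state = None
    return score


class TestBuildMsa:
    def test_two_sequences_equal_optimal_global(self):
        """Pairwise case reduces to the optimal global alignment."""
        rng = np.random.default_rng(0)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        for _ in range(5):
            a = random_protein(60, rng)
            b = evolve_sequence(a, 0.4, rng)
            if rng.random() < 0.5:
                b = b[: len(b) - int(rng.integers(1, 6))]
            msa = build_msa([SeqRecord("a", a), SeqRecord("b", b)])
            assert _global_score(msa.rows) == aligner.score(a, b)

    def test_identical_sequences_gap_free(self):
        rng = np.random.default_rng(1)
        seq = random_protein(80, rng)
        msa = build_msa([SeqRecord(f"s{i}", seq) for i in range(4)])
        assert all("-" not in row for row in msa.rows)

    def test_rows_reproduce_inputs_and_length_bound(self):
        rng = np.random.default_rng(2)
        root = random_protein(100, rng)
        seqs = [
            SeqRecord(f"s{i}", evolve_sequence(root, 0.3, rng)) for i in range(5)
        ]
        msa = build_msa(seqs)
        by_id = {s.id: s.residues for s in seqs}
        for sid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == by_id[sid]
        assert msa.n_cols >= max(len(s.residues) for s in seqs)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_msa([SeqRecord("a", "MKV")])


class TestProteinDistance:
    def test_identical_rows_zero(self):
        msa = MSA(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert protein_distance(msa).matrix[0, 1] == 0.0

    def test_closed_form_p019(self):
        msa = MSA(ids=["a", "b"], rows=["A" * 81 + "C" * 19, "A" * 81 + "D" * 19])
        d = protein_distance(msa).matrix[0, 1]
        assert round(d, 4) == 0.2120

    def test_saturation_capped(self):
        msa = MSA(ids=["a", "b"], rows=["A" * 100, "C" * 100])
        assert protein_distance(msa).matrix[0, 1] == 5.0

    def test_no_shared_columns_capped_with_warning(self):
        msa = MSA(ids=["a", "b"], rows=["AA--", "--CC"])
        with pytest.warns(UserWarning, match="no shared columns"):
            d = protein_distance(msa).matrix[0, 1]
        assert d == 5.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ids=["x", "y", "z"],
            matrix=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"x": 0.1, "y": 0.2, "z": 0.4})

    def test_additive_distances_recovered_exactly(self):
        """Path-length distances from a known tree give back its topology."""
        true = parse_newick(
            "((a:0.1,b:0.2):0.15,(c:0.3,(d:0.12,e:0.08):0.1):0.05,f:0.4);"
        )
        ml = _MLTree.from_tree(true)
        lab2id = {v: k for k, v in ml.leaf_label.items()}

        def path(u, v):
            dist = {lab2id[u]: 0.0}
            stack = [lab2id[u]]
            while stack:
                x = stack.pop()
                for nb, ln in ml.adj[x].items():
                    if nb not in dist:
                        dist[nb] = dist[x] + ln
                        stack.append(nb)
            return dist[lab2id[v]]

        ids = sorted(lab2id)
        D = np.array([[path(i, j) if i != j else 0.0 for j in ids] for i in ids])
        recovered = nj_tree(DistanceMatrix(ids=ids, matrix=D))
        assert recovered.splits() == true.splits()

    def test_agrees_with_skbio(self):
        """Independent NJ implementation builds the same topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        root = random_protein(200, rng)
        seqs = [
            SeqRecord(f"t{i}", evolve_sequence(root, 0.4, rng)) for i in range(6)
        ]
        dm = protein_distance(build_msa(seqs))
        ours = nj_tree(dm)
        sk = skbio.tree.nj(
            skbio.DistanceMatrix(dm.matrix, ids=dm.ids)
        )
        taxa = frozenset(dm.ids)
        sk_splits = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(taxa) - 2:
                sk_splits.add(frozenset((side, taxa - side)))
        assert sk_splits == ours.splits()

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestMaximumLikelihood:
    def test_two_taxon_single_column_matrix_exponential(self):
        """logL = ln(pi_a P_ab(t)) with P from the JTT rate matrix."""
        msa = MSA(ids=["a", "b"], rows=["A", "C"])
        ml = _MLTree.from_tree(parse_newick("(a:0.2,b:0.3);"))
        engine = MLEngine(ml, msa, MODEL)
        ia, ic = _AA.index("A"), _AA.index("C")
        oracle = np.log(MODEL.pi[ia] * expm(MODEL.q * 0.5)[ia, ic])
        assert engine.loglik() == pytest.approx(oracle, abs=1e-9)

    def test_three_taxon_pruning_equals_state_summation(self):
        msa = MSA(ids=["x", "y", "z"], rows=["AC", "CD", "AD"])
        ml = _MLTree.from_tree(parse_newick("(x:0.1,y:0.2,z:0.4);"))
        engine = MLEngine(ml, msa, MODEL)
        total = 0.0
        for site in range(2):
            states = [_AA.index(msa.rows[k][site]) for k in range(3)]
            s = sum(
                MODEL.pi[a]
                * expm(MODEL.q * 0.1)[a, states[0]]
                * expm(MODEL.q * 0.2)[a, states[1]]
                * expm(MODEL.q * 0.4)[a, states[2]]
                for a in range(20)
            )
            total += np.log(s)
        assert engine.loglik() == pytest.approx(total, abs=1e-9)

    def test_likelihood_invariant_to_evaluation_edge(self):
        """Time reversibility: the same likelihood from any edge."""
        rng = np.random.default_rng(4)
        root = random_protein(60, rng)
        seqs = [
            SeqRecord(f"t{i}", evolve_sequence(root, 0.3, rng)) for i in range(5)
        ]
        msa = build_msa(seqs)
        ml = _MLTree.from_tree(nj_tree(protein_distance(msa)))
        engine = MLEngine(ml, msa, MODEL)
        values = [engine.edge_loglik(u, v) for u, v in ml.edges()]
        assert np.allclose(values, values[0], atol=1e-8)

    def test_gaps_are_missing_data(self):
        """A column of all-gaps contributes zero information."""
        msa_a = MSA(ids=["a", "b"], rows=["AC", "AD"])
        msa_b = MSA(ids=["a", "b"], rows=["AC-", "AD-"])
        tree = parse_newick("(a:0.2,b:0.3);")
        la = MLEngine(_MLTree.from_tree(tree), msa_a, MODEL).loglik()
        lb = MLEngine(_MLTree.from_tree(tree), msa_b, MODEL).loglik()
        assert la == pytest.approx(lb, abs=1e-9)

    def test_optimization_never_decreases_loglik(self):
        rng = np.random.default_rng(5)
        root = random_protein(80, rng)
        seqs = [
            SeqRecord(f"t{i}", evolve_sequence(root, 0.4, rng)) for i in range(5)
        ]
        msa = build_msa(seqs)
        ml = _MLTree.from_tree(nj_tree(protein_distance(msa)))
        engine = MLEngine(ml, msa, MODEL)
        trace = [engine.loglik()]
        for u, v in ml.edges():
            trace.append(engine.optimize_edge(u, v))
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_four_taxon_nni_matches_exhaustive_search(self):
        """NNI from any start finds the best of the 3 unrooted topologies."""
        rng = np.random.default_rng(6)
        root = random_protein(100, rng)
        sA = evolve_sequence(root, 0.5, rng)
        sB = evolve_sequence(root, 0.5, rng)
        seqs = [
            SeqRecord("w", evolve_sequence(sA, 0.1, rng)),
            SeqRecord("x", evolve_sequence(sA, 0.1, rng)),
            SeqRecord("y", evolve_sequence(sB, 0.1, rng)),
            SeqRecord("z", evolve_sequence(sB, 0.1, rng)),
        ]
        msa = build_msa(seqs)
        tops = [
            "((w:0.1,x:0.1):0.1,y:0.1,z:0.1);",
            "((w:0.1,y:0.1):0.1,x:0.1,z:0.1);",
            "((w:0.1,z:0.1):0.1,x:0.1,y:0.1);",
        ]
        results = [ml_optimize(parse_newick(t), msa, MODEL) for t in tops]
        best_tree, best_ll = max(results, key=lambda r: r[1])
        for start in tops:
            tree, ll = ml_optimize(parse_newick(start), msa, MODEL)
            assert tree.splits() == best_tree.splits()
            assert ll == pytest.approx(best_ll, abs=1e-3)

    def test_empty_alignment_rejected(self):
        msa = MSA(ids=["a", "b"], rows=["", ""])
        with pytest.raises(ValueError):
            ml_optimize(parse_newick("(a:0.1,b:0.1);"), msa, MODEL)


def _planted_two_clade_msa(rng, n_per=4, length=120):
    root = random_protein(length, rng)
    s1 = evolve_sequence(root, 0.75, rng)
    s2 = evolve_sequence(root, 0.75, rng)
    seqs = [
        SeqRecord(f"p{i}", evolve_sequence(s1, 0.05, rng)) for i in range(n_per)
    ] + [
        SeqRecord(f"q{i}", evolve_sequence(s2, 0.05, rng)) for i in range(n_per)
    ]
    return build_msa(seqs)


def _support_of(tree, side_names):
    all_leaves = frozenset(tree.leaf_names())
    target = frozenset((frozenset(side_names), all_leaves - frozenset(side_names)))
    for node in tree.root.traverse_postorder():
        if node.is_leaf or node.parent is None or node.support is None:
            continue
        side = frozenset(
            l.name for l in node.traverse_postorder() if l.is_leaf
        )
        if frozenset((side, all_leaves - side)) == target:
            return node.support
    return None


class TestBootstrap:
    def test_strong_signal_full_support(self):
        rng = np.random.default_rng(7)
        msa = _planted_two_clade_msa(rng)
        tree = bootstrap_support(msa, n=25, seed=11, model=MODEL)
        assert _support_of(tree, [f"p{i}" for i in range(4)]) == 100

    def test_same_seed_identical(self):
        rng = np.random.default_rng(8)
        msa = _planted_two_clade_msa(rng)
        t1 = bootstrap_support(msa, n=10, seed=3, model=MODEL)
        t2 = bootstrap_support(msa, n=10, seed=3, model=MODEL)
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(9)
        msa = _planted_two_clade_msa(rng, n_per=3, length=80)
        tree = bootstrap_support(msa, n=1, seed=5, model=MODEL)
        sups = [
            n.support
            for n in tree.root.traverse_postorder()
            if n.support is not None
        ]
        assert sups and set(sups) <= {0, 100}

    def test_zero_replicates_rejected(self):
        rng = np.random.default_rng(10)
        msa = _planted_two_clade_msa(rng, n_per=3, length=80)
        with pytest.raises(ValueError):
            bootstrap_support(msa, n=0, seed=1)


class TestCladePartition:
    def test_all_identical_single_clade(self):
        rng = np.random.default_rng(11)
        seq = random_protein(100, rng)
        part = partition_clades([SeqRecord(f"s{i}", seq) for i in range(4)])
        assert part.n_clades == 1 and part.orphans == []

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        root = random_protein(200, rng)
        seqs = [
            SeqRecord(f"s{i}", evolve_sequence(root, 0.25, rng))
            for i in range(6)
        ]
        counts = []
        for thr in (40.0, 60.0, 80.0, 95.0):
            part = partition_clades(seqs, similarity_threshold=thr,
                                    min_clade_size=1)
            counts.append(part.n_clades)
        assert counts == sorted(counts)

    def test_partition_covers_all_ids(self, pylrs_preset):
        records, _truth, _model = pylrs_preset
        part = partition_clades(records)
        covered = {m for c in part.clades for m in c} | set(part.orphans)
        assert covered == {r.id for r in records}
        assert sum(len(c) for c in part.clades) + len(part.orphans) == len(records)


class TestReferenceAssignment:
    def test_identical_query_gets_reference_clade(self):
        rng = np.random.default_rng(13)
        ref = SeqRecord("r1", random_protein(100, rng))
        out = assign_to_reference_clades(
            [SeqRecord("q", ref.residues)], [(ref, "cladeA")]
        )
        assert out == {"q": "cladeA"}

    def test_zero_threshold_never_novel(self):
        rng = np.random.default_rng(14)
        ref = SeqRecord("r1", random_protein(100, rng))
        far = SeqRecord("q", random_protein(100, rng))
        out = assign_to_reference_clades([far], [(ref, "cladeA")],
                                         similarity_threshold=0.0)
        assert out["q"] == "cladeA"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            assign_to_reference_clades([SeqRecord("q", "MKV")], [])
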