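"""Local alignment, percent similarity and the iterative search."""

import functools
import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from sepmine.homolog_search import (
    DEFAULT_SCHEME,
    HomologSet,
    PairwiseAlignment,
    ScoringScheme,
    group_by_similarity,
    iterative_search,
    local_align,
    pairwise_similarity,
    percent_similarity,
)
from sepmine.io_formats import SeqRecord
from sepmine.synthetic_data.families import evolve_sequence, random_protein

B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(a: str, b: str, open_: int = 11, ext: int = 1) -> float:
    """Independent oracle: maximum over all local alignments with affine
    gaps (first gap column costs ``open_``, each further column ``ext``),
    via memoized recursion over (position, position, gap state)."""

    @functools.lru_cache(maxsize=None)
    def best_from(i: int, j: int, state: str) -> float:
        # best score of any alignment continuation starting at (i, j);
        # ending immediately (score 0) is always allowed
        out = 0.0
        if i < len(a) and j < len(b):
            out = max(out, B62[a[i], b[j]] + best_from(i + 1, j + 1, "M"))
        if i < len(a):
            cost = ext if state == "X" else open_
            out = max(out, -cost + best_from(i + 1, j, "X"))
        if j < len(b):
            cost = ext if state == "Y" else open_
            out = max(out, -cost + best_from(i, j + 1, "Y"))
        return out

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, best_from(i, j, "M"))
    return best


class TestLocalAlign:
    def test_self_alignment(self):
        rec = SeqRecord("a", "MKVL")
        aln = local_align(rec, rec)
        expected = sum(B62[c, c] for c in "MKVL")
        assert aln.score == expected
        assert percent_similarity(aln) == 100.0
        assert aln.query_coverage == 1.0

    def test_no_positive_pair_gives_empty(self):
        aln = local_align(SeqRecord("a", "MK"), SeqRecord("b", "WW"))
        assert aln.is_empty and aln.score == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            local_align(SeqRecord("a", "MK"), SeqRecord("b", "M-"))

    def test_brute_force_exhaustive_dimers(self):
        """All pairs of 1-2-mers over a 4-letter sub-alphabet."""
        alphabet = "ACDE"
        seqs = [
            "".join(t)
            for n in (1, 2)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for sa, sb in itertools.product(seqs, repeat=2):
            got = local_align(SeqRecord("a", sa), SeqRecord("b", sb)).score
            assert got == brute_force_local_score(sa, sb), (sa, sb)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_random_short_pairs(self, seed):
        """Seeded random pairs up to length 6 over a restricted alphabet."""
        rng = np.random.default_rng(seed)
        alphabet = "ACDEKW"
        for _ in range(60):
            la, lb = rng.integers(3, 7, size=2)
            sa = "".join(alphabet[i] for i in rng.integers(0, 6, size=la))
            sb = "".join(alphabet[i] for i in rng.integers(0, 6, size=lb))
            got = local_align(SeqRecord("a", sa), SeqRecord("b", sb)).score
            assert got == brute_force_local_score(sa, sb), (sa, sb)

    def test_score_symmetric(self):
        rng = np.random.default_rng(3)
        a = SeqRecord("a", random_protein(80, rng))
        b = SeqRecord("b", evolve_sequence(a.residues, 0.8, rng))
        assert local_align(a, b).score == local_align(b, a).score


class TestPercentSimilarity:
    def test_identical_tenmers(self):
        aln = local_align(SeqRecord("a", "MKVLWAALLV"), SeqRecord("b", "MKVLWAALLV"))
        assert percent_similarity(aln) == 100.0

    def test_direct_arithmetic_with_gaps(self):
        """10 columns: 4 positive pairs, 2 gap columns, 4 non-positive -> 40."""
        aln = PairwiseAlignment(
            query_id="q", subject_id="s",
            #               MKVL positive; WWWW vs GGGG non-positive
            aligned_query="MKVLWWWWAC",
            aligned_subject="MKVLGGGG--",
            score=10.0,
            query_start=1, query_end=10, subject_start=1, subject_end=8,
            query_length=10, subject_length=8,
        )
        assert percent_similarity(aln) == 40.0

    def test_empty_alignment_rejected(self):
        aln = local_align(SeqRecord("a", "MK"), SeqRecord("b", "WW"))
        with pytest.raises(ValueError):
            percent_similarity(aln)

    def test_similarity_decreases_with_distance(self):
        rng = np.random.default_rng(4)
        root = random_protein(300, rng)
        means = []
        for d in (0.1, 0.5, 1.0):
            sims = [
                pairwise_similarity(
                    SeqRecord("a", root),
                    SeqRecord("b", evolve_sequence(root, d, rng)),
                )
                for _ in range(5)
            ]
            means.append(np.mean(sims))
        assert means[0] > means[1] > means[2]


def _make_chain(rng):
    """A -> B -> C where sim(A,B) and sim(B,C) clear the 40% retention
    threshold but sim(A,C) does not; verified with the alignment oracle."""
    for _ in range(200):
        a = random_protein(250, rng)
        b = evolve_sequence(a, 0.55, rng)
        c = evolve_sequence(b, 0.55, rng)
        ra, rb, rc = SeqRecord("A", a), SeqRecord("B", b), SeqRecord("C", c)
        sim_ab = pairwise_similarity(ra, rb)
        sim_bc = pairwise_similarity(rb, rc)
        sim_ac = pairwise_similarity(ra, rc)
        if sim_ab >= 45 and sim_bc >= 45 and sim_ac < 38:
            return ra, rb, rc
    raise AssertionError("could not construct the similarity chain")


class TestIterativeSearch:
    def test_seed_in_database_retained_round_one(self):
        rng = np.random.default_rng(5)
        seed = SeqRecord("s", random_protein(100, rng))
        result = iterative_search([seed], [seed])
        (rec,) = result.records
        assert rec.similarity == 100.0 and rec.round_found == 1

    def test_chain_requires_second_round(self):
        """C is invisible to the seed A but reachable through B's group
        representative in round 2."""
        rng = np.random.default_rng(6)
        ra, rb, rc = _make_chain(rng)
        result = iterative_search([ra], [rb, rc], threshold=40.0)
        rounds = {r.seq_id: r.round_found for r in result.records}
        assert rounds == {"B": 1, "C": 2}

    def test_threshold_monotone(self):
        rng = np.random.default_rng(6)
        ra, rb, rc = _make_chain(rng)
        db = [rb, rc]
        low = iterative_search([ra], db, threshold=40.0).ids()
        high = iterative_search([ra], db, threshold=60.0).ids()
        assert high <= low

    def test_threshold_100_empty_for_non_identical(self):
        rng = np.random.default_rng(7)
        seed = SeqRecord("s", random_protein(100, rng))
        db = [SeqRecord("d", evolve_sequence(seed.residues, 0.2, rng))]
        assert iterative_search([seed], db, threshold=100.0).ids() == set()

    def test_empty_database(self):
        rng = np.random.default_rng(8)
        seed = SeqRecord("s", random_protein(100, rng))
        assert iterative_search([seed], []).records == []

    def test_recall_on_default_preset(self, default_metagenome):
        """Seeded with one clade-I SepRS, the search recovers >=95% of all
        planted SepRS genes, across clades and the truncated orphan."""
        mg = default_metagenome
        seprs = {
            g.protein_id
            for g in mg.truth.genes.values() if g.family == "SepRS"
        }
        seed_pid = sorted(
            g.protein_id
            for g in mg.truth.genes.values()
            if g.family == "SepRS" and g.clade == "cladeI"
        )[0]
        prot = {p.id: p for p in mg.proteins}
        result = iterative_search([prot[seed_pid]], mg.proteins)
        found = result.ids()
        assert len(found & seprs) / len(seprs) >= 0.95
        # the coverage gate keeps unrelated families out
        assert found <= seprs


class TestGrouping:
    def test_identical_set_single_group(self):
        rng = np.random.default_rng(9)
        seq = random_protein(80, rng)
        records = [SeqRecord(f"r{i}", seq) for i in range(4)]
        groups = group_by_similarity(records)
        assert len(groups) == 1
        members, rep = groups[0]
        assert len(members) == 4 and rep in members

    def test_singleton(self):
        rng = np.random.default_rng(10)
        rec = SeqRecord("only", random_protein(60, rng))
        assert group_by_similarity([rec]) == [(["only"], "only")]

    def test_two_planted_clades_recovered(self):
        rng = np.random.default_rng(11)
        root = random_protein(250, rng)
        s1 = evolve_sequence(root, 0.8, rng)
        s2 = evolve_sequence(root, 0.8, rng)
        records, truth = [], {}
        for k, s in enumerate((s1, s2)):
            for i in range(3):
                rec = SeqRecord(f"c{k}_{i}", evolve_sequence(s, 0.08, rng))
                records.append(rec)
                truth[rec.id] = k
        groups = group_by_similarity(records, link_threshold=60.0)
        assert len(groups) == 2
        for members, _rep in groups:
            assert len({truth[m] for m in members}) == 1
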