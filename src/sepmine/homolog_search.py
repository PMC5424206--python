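"""Local protein alignment and iterative similarity-threshold homolog search.

The search strategy mirrors how distant aminoacyl-tRNA-synthetase homologs
are mined from metagenomic protein databases: a single seed query retrieves
everything above a percent-similarity threshold, the retained hits are
grouped by sequence similarity, and one representative per group is
re-queried, so that successive rounds walk outward through sequence space
until no new family member is found.

"Percent similarity" here is the BLAST-style positives fraction: the share
of local-alignment columns whose residue pair scores positively under the
substitution matrix, with gap columns counted in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ALPHABET, SeqRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` is charged for the first gapped column and ``gap_extend``
    for each further column of the same gap (BLAST charges open + k*extend;
    the two conventions differ only by a constant per gap).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local alignment of query vs subject with similarity statistics.

    ``aligned_query``/``aligned_subject`` are equal-length strings over the
    amino-acid alphabet plus ``-``; coordinates are 1-based inclusive into
    the original (unaligned) sequences.  An empty alignment (no positively
    scoring local hit) has score 0 and empty aligned strings.
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    query_length: int
    subject_length: int

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")
        for qa, sa in zip(self.aligned_query, self.aligned_subject):
            if qa == "-" and sa == "-":
                raise ValueError("gap-vs-gap column in alignment")

    @property
    def is_empty(self) -> bool:
        return not self.aligned_query

    @property
    def query_coverage(self) -> float:
        if self.is_empty:
            return 0.0
        return (self.query_end - self.query_start + 1) / self.query_length


def _check_protein(seq: SeqRecord) -> None:
    if not seq.residues:
        raise ValueError(f"empty sequence {seq.id!r}")
    bad = set(seq.residues) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"{seq.id!r}: residues outside amino alphabet: {sorted(bad)}")


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -float(scheme.gap_open)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    return aligner


def local_align(
    a: SeqRecord, b: SeqRecord, scheme: ScoringScheme = DEFAULT_SCHEME
) -> PairwiseAlignment:
    """Optimal Smith–Waterman local alignment of ``a`` (query) vs ``b``.

    Exact quadratic dynamic programming with affine gaps (no heuristic
    seeding); among co-optimal alignments the aligner's first, deterministic
    traceback is reported.  Returns the empty alignment when no local pair
    of segments scores positively.
    """
    _check_protein(a)
    _check_protein(b)
    aligner = _make_aligner(scheme)
    score = aligner.score(a.residues, b.residues)
    if score <= 0:
        return PairwiseAlignment(
            query_id=a.id, subject_id=b.id, aligned_query="", aligned_subject="",
            score=0.0, query_start=0, query_end=0, subject_start=0, subject_end=0,
            query_length=len(a.residues), subject_length=len(b.residues),
        )
    aln = next(iter(aligner.align(a.residues, b.residues)))
    qa, sa = str(aln[0]), str(aln[1])
    # Bio.Align local alignment strings cover the aligned region only as of
    # indices; derive 1-based coordinates from the aligned blocks.
    q_blocks, s_blocks = aln.aligned
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    return PairwiseAlignment(
        query_id=a.id, subject_id=b.id,
        aligned_query=qa, aligned_subject=sa, score=float(score),
        query_start=q_start, query_end=q_end,
        subject_start=s_start, subject_end=s_end,
        query_length=len(a.residues), subject_length=len(b.residues),
    )


def percent_similarity(
    aln: PairwiseAlignment, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Positives fraction over all alignment columns, as a 0–100 percentage.

    A column counts as similar iff both residues are non-gap and their
    substitution score is strictly positive; gap columns stay in the
    denominator, so long insertions depress similarity.
    """
    if aln.is_empty:
        raise ValueError("empty alignment has no percent similarity")
    matrix = scheme.matrix
    positive = 0
    for qa, sa in zip(aln.aligned_query, aln.aligned_subject):
        if qa != "-" and sa != "-" and matrix[qa, sa] > 0:
            positive += 1
    return 100.0 * positive / len(aln.aligned_query)


@dataclass(frozen=True)
class HomologRecord:
    seq_id: str
    similarity: float  # best similarity to any accepted query
    round_found: int
    group: int
    is_representative: bool


@dataclass
class HomologSet:
    """Retained homologs with their groups and medoid representatives."""

    records: list[HomologRecord] = field(default_factory=list)

    def ids(self) -> set[str]:
        return {r.seq_id for r in self.records}

    def to_rows(self) -> list[dict]:
        return [
            {
                "seq_id": r.seq_id,
                "similarity": round(r.similarity, 2),
                "round": r.round_found,
                "group": r.group,
                "representative": int(r.is_representative),
            }
            for r in sorted(self.records, key=lambda r: (r.round_found, r.seq_id))
        ]


class _SimilarityCache:
    """Symmetric cache of (similarity, query_coverage) for sequence pairs."""

    def __init__(self, scheme: ScoringScheme):
        self.scheme = scheme
        self._cache: dict[tuple[str, str], tuple[float, float]] = {}

    def query(self, a: SeqRecord, b: SeqRecord) -> tuple[float, float]:
        key = (a.id, b.id)
        if key not in self._cache:
            aln = local_align(a, b, self.scheme)
            if aln.is_empty:
                sim, cov = 0.0, 0.0
            else:
                sim, cov = percent_similarity(aln, self.scheme), aln.query_coverage
            self._cache[key] = (sim, cov)
        return self._cache[key]

    def similarity(self, a: SeqRecord, b: SeqRecord) -> float:
        # similarity is symmetric in practice; use either orientation if cached
        if (b.id, a.id) in self._cache:
            return self._cache[(b.id, a.id)][0]
        return self.query(a, b)[0]


def group_by_similarity(
    records: list[SeqRecord],
    link_threshold: float = 60.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cache: _SimilarityCache | None = None,
) -> list[tuple[list[str], str]]:
    """Single-linkage groups at ``link_threshold`` percent similarity.

    Returns ``(member_ids, representative_id)`` per group, members sorted
    lexicographically, groups sorted by their smallest member.  The
    representative is the medoid (maximum mean similarity to its own group;
    ties broken by lexicographic id).
    """
    if not records:
        return []
    cache = cache or _SimilarityCache(scheme)
    by_id = {r.id: r for r in records}
    parent = {r.id: r.id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = sorted(by_id)
    sims: dict[tuple[str, str], float] = {}
    for i, xi in enumerate(ids):
        for xj in ids[i + 1 :]:
            sim = cache.similarity(by_id[xi], by_id[xj])
            sims[(xi, xj)] = sim
            if sim >= link_threshold:
                parent[find(xi)] = find(xj)

    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)

    out: list[tuple[list[str], str]] = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        if len(members) == 1:
            out.append((members, members[0]))
            continue
        best_id, best_mean = None, -1.0
        for m in members:
            mean = sum(
                sims[(min(m, o), max(m, o))] for o in members if o != m
            ) / (len(members) - 1)
            if mean > best_mean or (mean == best_mean and (best_id is None or m < best_id)):
                best_id, best_mean = m, mean
        out.append((members, best_id))
    return out


def iterative_search(
    seed_queries: list[SeqRecord],
    database: list[SeqRecord],
    threshold: float = 40.0,
    coverage_min: float = 0.6,
    max_rounds: int = 10,
    link_threshold: float = 60.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> HomologSet:
    """Iterative query-expansion homolog search.

    Round 1 retains database entries with percent similarity >= ``threshold``
    and query coverage >= ``coverage_min`` against any seed.  The retained
    set is grouped by sequence similarity; one medoid representative per
    group joins
    the query pool, and search continues until a round adds nothing or
    ``max_rounds`` is reached.  Every retained entry is stamped with the
    round in which it was first found and its best similarity to any
    accepted query.
    """
    if not seed_queries:
        raise ValueError("at least one seed query is required")
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")

    cache = _SimilarityCache(scheme)
    by_id = {r.id: r for r in database}
    retained: dict[str, tuple[float, int]] = {}  # id -> (best sim, round)
    queries = list(seed_queries)
    queried_ids: set[str] = set()

    for round_no in range(1, max_rounds + 1):
        new_queries = [q for q in queries if q.id not in queried_ids]
        if not new_queries:
            break
        queried_ids.update(q.id for q in new_queries)
        found_new = False
        for entry in database:
            for q in new_queries:
                if entry.id == q.id:
                    sim, cov = 100.0, 1.0
                else:
                    sim, cov = cache.query(q, entry)
                if sim >= threshold and cov >= coverage_min:
                    prev = retained.get(entry.id)
                    if prev is None:
                        retained[entry.id] = (sim, round_no)
                        found_new = True
                    elif sim > prev[0]:
                        retained[entry.id] = (sim, prev[1])
        if not found_new:
            break
        groups = group_by_similarity(
            [by_id[i] for i in sorted(retained)], link_threshold, scheme, cache
        )
        queries = [by_id[rep] for _members, rep in groups]

    if not retained:
        return HomologSet([])

    groups = group_by_similarity(
        [by_id[i] for i in sorted(retained)], link_threshold, scheme, cache
    )
    records = []
    for gid, (members, rep) in enumerate(groups, start=1):
        for m in members:
            sim, rnd = retained[m]
            records.append(
                HomologRecord(
                    seq_id=m, similarity=sim, round_found=rnd,
                    group=gid, is_representative=(m == rep),
                )
            )
    return HomologSet(records)


def pairwise_similarity(
    a: SeqRecord, b: SeqRecord, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Percent similarity of the optimal local alignment (0 if no hit)."""
    aln = local_align(a, b, scheme)
    return 0.0 if aln.is_empty else percent_similarity(aln, scheme)
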