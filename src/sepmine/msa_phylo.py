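"""Multiple alignment, maximum-likelihood phylogeny and clade partitioning.

The engine mirrors a standard protein phylogenetics workflow: progressive
multiple alignment (k-mer distances, UPGMA guide tree, profile-profile
global alignment with affine gaps), corrected pairwise distances, a
neighbor-joining starting tree, maximum-likelihood optimization under the
JTT model with uniform rates (Felsenstein pruning; gaps treated as missing
data), nearest-neighbor-interchange topology search, and nonparametric
bootstrap supports (default 100 replicates).

Clade delineation is made operational rather than visual: sequences are
partitioned by single-linkage clustering of pairwise local-alignment
percent similarity, clusters at least ``min_clade_size`` strong are major
clades and everything else is an orphan.  The ML tree with supports is
produced alongside for inspection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize_scalar

from .homolog_search import (
    DEFAULT_SCHEME,
    ScoringScheme,
    _SimilarityCache,
    group_by_similarity,
)
from .io_formats import SeqRecord
from .jtt import JttModel
from .tree import Node, Tree

GAP = "-"


# ---------------------------------------------------------------------------
# MSA


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def resample_columns(self, rng: np.random.Generator) -> "MSA":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        return MSA(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


_AA = "ACDEFGHIKLMNPQRSTVWYX"
_AA_IDX = {a: i for i, a in enumerate(_AA)}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    def counts(s):
        out: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            out[w] = out.get(w, 0) + 1
        return out

    ca, cb = counts(a), counts(b)
    shared = sum(min(ca.get(w, 0), cb.get(w, 0)) for w in ca)
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom if denom > 0 else 1.0


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequency vectors, (L, 20); gaps carry no mass."""
    n, L = len(rows), len(rows[0])
    counts = np.zeros((L, 20))
    for r in rows:
        for j, ch in enumerate(r):
            if ch != GAP:
                counts[j, min(_AA_IDX.get(ch, 20), 19)] += 1
    return counts / n


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Global affine (Gotoh) alignment of two profiles; returns gapped rows."""
    matrix = np.array(
        [[scheme.score(a, b) for b in _AA[:20]] for a in _AA[:20]]
    )
    fa = _profile(rows_a)
    fb = _profile(rows_b)
    S = fa @ matrix @ fb.T  # (LA, LB) expected column scores
    la, lb = S.shape
    open_, ext = float(scheme.gap_open), float(scheme.gap_extend)
    NEG = -1e30

    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, lb + 1):
        Y[0, j] = -open_ - (j - 1) * ext

    js = np.arange(lb + 1)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        X[i] = np.maximum(M[i - 1] - open_, X[i - 1] - ext)
        # Y[i, j] = max_{k<j} M[i, k] - open - (j-1-k)*ext, via running max
        c = M[i] + ext * js
        run = np.maximum.accumulate(c)
        Y[i, 1:] = run[:-1] - open_ - ext * (js[1:] - 1)

    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[int] = []  # 0 match, 1 gap-in-B, 2 gap-in-A
    tol = 1e-9
    while i > 0 or j > 0:
        ops.append(state)
        if state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            state = 0 if abs(X[i, j] - (M[i - 1, j] - open_)) < tol else 1
            i -= 1
        else:
            state = 0 if abs(Y[i, j] - (M[i, j - 1] - open_)) < tol else 2
            j -= 1
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, o in zip(rows_a, out_a):
                o.append(r[ia])
            for r, o in zip(rows_b, out_b):
                o.append(r[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for r, o in zip(rows_a, out_a):
                o.append(r[ia])
            for o in out_b:
                o.append(GAP)
            ia += 1
        else:
            for o in out_a:
                o.append(GAP)
            for r, o in zip(rows_b, out_b):
                o.append(r[ib])
            ib += 1
    return ["".join(o) for o in out_a], ["".join(o) for o in out_b]


def build_msa(seqs: list[SeqRecord], scheme: ScoringScheme = DEFAULT_SCHEME) -> MSA:
    """Progressive multiple alignment along a UPGMA guide tree.

    Deterministic; for two sequences the result is the optimal global
    pairwise alignment under the scheme.
    """
    if len(seqs) < 2:
        raise ValueError("at least two sequences are required")
    n = len(seqs)
    if n == 2:
        ra, rb = _align_profiles([seqs[0].residues], [seqs[1].residues], scheme)
        return MSA(ids=[s.id for s in seqs], rows=[ra[0], rb[0]])

    condensed = [
        _kmer_distance(seqs[i].residues, seqs[j].residues)
        for i, j in itertools.combinations(range(n), 2)
    ]
    merges = linkage(np.array(condensed), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i].id], [seqs[i].residues]) for i in range(n)
    }
    nxt = n
    for a, b, _dist, _cnt in merges:
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b, scheme)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (ids, rows), = clusters.values()
    order = {s.id: k for k, s in enumerate(seqs)}
    paired = sorted(zip(ids, rows), key=lambda x: order[x[0]])
    return MSA(ids=[p[0] for p in paired], rows=[p[1] for p in paired])


# ---------------------------------------------------------------------------
# Distances and neighbor joining


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if np.isnan(m).any():
            raise ValueError("NaN distances are not allowed")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")


DISTANCE_CAP = 5.0


def protein_distance(msa: MSA) -> DistanceMatrix:
    """Corrected pairwise distances under the 20-state uniform model.

    For each pair, p is the mismatch fraction over columns where both rows
    are non-gap; the distance is -(19/20) ln(1 - (20/19) p), capped at
    5.0 when saturated (log argument <= 0) or when no columns are shared.
    """
    import warnings as _warnings

    n = len(msa.ids)
    if n < 2:
        raise ValueError("need at least two rows")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = msa.rows[i], msa.rows[j]
            shared = mismatch = 0
            for a, b in zip(ri, rj):
                if a != GAP and b != GAP:
                    shared += 1
                    if a != b:
                        mismatch += 1
            if shared == 0:
                _warnings.warn(
                    f"no shared columns between {msa.ids[i]} and {msa.ids[j]}; "
                    f"distance capped"
                )
                d = DISTANCE_CAP
            else:
                p = mismatch / shared
                arg = 1.0 - (20.0 / 19.0) * p
                d = DISTANCE_CAP if arg <= 0 else min(
                    DISTANCE_CAP, -(19.0 / 20.0) * float(np.log(arg))
                )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=list(msa.ids), matrix=out)


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Neighbor joining; negative branch lengths are clamped to zero.

    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[Node] = [Node(name=i_d) for i_d in dist.ids]
    D = dist.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length = max(0.0, float(li))
        cj.length = max(0.0, float(lj))
        parent.add(ci)
        parent.add(cj)
        new_index = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_index, k] = D[k, new_index] = 0.5 * (
                D[i, k] + D[j, k] - dij
            )
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    root = Node()
    di = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    dj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, di), (j, dj), (k, dk)):
        nodes[idx].length = max(0.0, float(ln))
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Maximum likelihood under JTT


class _MLTree:
    """Adjacency representation for likelihood computation and NNI."""

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.leaf_label[nid] = label
        return nid

    def connect(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def disconnect(self, a: int, b: int) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    def set_length(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for a in sorted(self.adj):
            for b in sorted(self.adj[a]):
                if a < b:
                    out.append((a, b))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (a, b)
            for a, b in self.edges()
            if a not in self.leaf_label and b not in self.leaf_label
        ]

    @classmethod
    def from_tree(cls, tree: Tree) -> "_MLTree":
        ml = cls()

        def _walk(node: Node) -> int:
            nid = ml.new_node(node.name if node.is_leaf else None)
            for child in node.children:
                cid = _walk(child)
                ml.connect(nid, cid, child.length if child.length else 1e-6)
            return nid

        root = _walk(tree.root)
        # suppress a degree-2 root (rooted binary input): splice it out
        if len(ml.adj[root]) == 2:
            (a, la), (b, lb) = list(ml.adj[root].items())
            ml.disconnect(root, a)
            ml.disconnect(root, b)
            del ml.adj[root]
            ml.connect(a, b, la + lb)
        return ml

    def to_tree(self) -> Tree:
        # root at the lowest-numbered internal node (or a leaf's neighbor)
        internals = [n for n in sorted(self.adj) if n not in self.leaf_label]
        root_id = internals[0] if internals else sorted(self.adj)[0]

        def _build(nid: int, parent: int | None) -> Node:
            node = Node(name=self.leaf_label.get(nid))
            if parent is not None:
                node.length = self.adj[nid][parent]
            for nb in sorted(self.adj[nid]):
                if nb != parent:
                    node.add(_build(nb, nid))
            return node

        return Tree(_build(root_id, None))


class MLEngine:
    """Felsenstein pruning with per-site scaling on an adjacency tree."""

    def __init__(self, ml_tree: _MLTree, msa: MSA, model: JttModel | None = None):
        self.tree = ml_tree
        self.model = model or JttModel(order=_AA[:20])
        self.msa = msa
        self.n_sites = msa.n_cols
        self._leaf_partial: dict[int, np.ndarray] = {}
        row_by_id = dict(zip(msa.ids, msa.rows))
        for nid, label in ml_tree.leaf_label.items():
            if label not in row_by_id:
                raise ValueError(f"leaf {label!r} missing from the alignment")
            row = row_by_id[label]
            part = np.zeros((self.n_sites, 20))
            for s, ch in enumerate(row):
                if ch == GAP or ch == "X":
                    part[s, :] = 1.0  # missing data
                else:
                    part[s, _AA_IDX[ch]] = 1.0
            self._leaf_partial[nid] = part
        self._memo: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def invalidate(self) -> None:
        self._memo.clear()

    def _msg(self, src: int, dst: int) -> tuple[np.ndarray, np.ndarray]:
        """Partial likelihoods of the subtree on ``src``'s side of (src,dst),
        evaluated at ``src``; returns (sites x 20, per-site log scale)."""
        key = (src, dst)
        if key in self._memo:
            return self._memo[key]
        if src in self.tree.leaf_label:
            out = (self._leaf_partial[src], np.zeros(self.n_sites))
            self._memo[key] = out
            return out
        vals = np.ones((self.n_sites, 20))
        scale = np.zeros(self.n_sites)
        for nb, length in sorted(self.tree.adj[src].items()):
            if nb == dst:
                continue
            child, child_scale = self._msg(nb, src)
            p = self.model.transition(length)
            vals = vals * (child @ p.T)
            scale = scale + child_scale
        mx = vals.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        vals = vals / mx[:, None]
        out = (vals, scale + np.log(mx))
        self._memo[key] = out
        return out

    def edge_loglik(self, u: int, v: int, t: float | None = None) -> float:
        mu, su = self._msg(u, v)
        mv, sv = self._msg(v, u)
        length = self.tree.adj[u][v] if t is None else t
        p = self.model.transition(length)
        site = ((mu * self.model.pi[None, :]) * (mv @ p.T)).sum(axis=1)
        site = np.clip(site, 1e-300, None)
        return float(np.sum(np.log(site) + su + sv))

    def loglik(self) -> float:
        u, v = self.tree.edges()[0]
        return self.edge_loglik(u, v)

    def optimize_edge(self, u: int, v: int) -> float:
        mu_su = self._msg(u, v)
        mv_sv = self._msg(v, u)
        mu, su = mu_su
        mv, sv = mv_sv
        pre = mu * self.model.pi[None, :]
        const = float(np.sum(su + sv))

        def neg(t: float) -> float:
            p = self.model.transition(t)
            site = (pre * (mv @ p.T)).sum(axis=1)
            return -(float(np.sum(np.log(np.clip(site, 1e-300, None)))) + const)

        res = minimize_scalar(
            neg, bounds=(1e-9, 10.0), method="bounded",
            options={"xatol": 1e-6},
        )
        self.tree.set_length(u, v, float(res.x))
        self.invalidate()
        return -float(res.fun)

    def optimize_branch_lengths(self, passes: int = 2) -> float:
        best = self.loglik()
        for _ in range(passes):
            for u, v in self.tree.edges():
                best = self.optimize_edge(u, v)
        return best

    def optimize_branch_lengths_to_convergence(
        self, tol: float = 1e-6, max_passes: int = 25
    ) -> float:
        best = self.loglik()
        for _ in range(max_passes):
            for u, v in self.tree.edges():
                new = self.optimize_edge(u, v)
            if new - best < tol:
                return new
            best = new
        return best


def _nni_neighbors(tree: _MLTree, u: int, v: int) -> list[tuple[int, int]]:
    """The two NNI swaps around internal edge (u, v): swap one u-side
    neighbor with one v-side neighbor."""
    u_nb = [x for x in sorted(tree.adj[u]) if x != v]
    v_nb = [x for x in sorted(tree.adj[v]) if x != u]
    if len(u_nb) < 2 or len(v_nb) < 2:
        return []
    b = u_nb[1]
    return [(b, v_nb[0]), (b, v_nb[1])]


def _apply_swap(tree: _MLTree, u: int, v: int, x: int, y: int) -> None:
    """Swap subtree x (attached to u) with subtree y (attached to v)."""
    lx = tree.adj[u][x]
    ly = tree.adj[v][y]
    tree.disconnect(u, x)
    tree.disconnect(v, y)
    tree.connect(u, y, ly)
    tree.connect(v, x, lx)


def ml_optimize(
    start_tree: Tree,
    msa: MSA,
    model: JttModel | None = None,
    tol: float = 1e-6,
    max_nni_rounds: int = 10,
) -> tuple[Tree, float]:
    """Maximum-likelihood tree under JTT with uniform rates.

    Branch lengths are optimized one-dimensionally (Brent, tolerance 1e-6);
    NNI moves are accepted while the log-likelihood improves by at least
    ``tol``.  Gaps and X are treated as missing data (all-ones partials),
    so every alignment column contributes.  Deterministic.
    """
    if msa.n_cols == 0:
        raise ValueError("empty alignment")
    ml = _MLTree.from_tree(start_tree)
    engine = MLEngine(ml, msa, model)
    best = engine.optimize_branch_lengths(passes=2)

    # small trees can afford re-optimizing every branch when scoring an NNI
    # candidate; larger trees score candidates on the focal branch only
    full_reopt = len(ml.leaf_label) <= 6
    for _round in range(max_nni_rounds):
        improved = False
        for u, v in ml.internal_edges():
            if v not in ml.adj.get(u, {}):
                continue
            for x, y in _nni_neighbors(ml, u, v):
                _apply_swap(ml, u, v, x, y)
                engine.invalidate()
                if full_reopt:
                    cand = engine.optimize_branch_lengths(passes=1)
                else:
                    cand = engine.optimize_edge(u, v)
                if cand > best + tol:
                    best = cand
                    improved = True
                    break  # neighbor lists around this edge are now stale
                _apply_swap(ml, u, v, y, x)  # revert
                engine.invalidate()
        if not improved:
            break
    best = engine.optimize_branch_lengths_to_convergence(tol=tol)
    tree = ml.to_tree()
    return tree, best


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    msa: MSA,
    n: int = 100,
    seed: int | None = None,
    model: JttModel | None = None,
) -> Tree:
    """ML tree with bootstrap supports from ``n`` column-resampled replicates.

    Each replicate goes through the full distance + NJ + ML pipeline; the
    support of an internal branch of the full-data ML tree is the percent of
    replicate trees containing the same bipartition.  Reproducible under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    model = model or JttModel(order=_AA[:20])
    rng = np.random.default_rng(seed)
    main_tree, _ = ml_optimize(nj_tree(protein_distance(msa)), msa, model)

    split_counts: dict[frozenset, int] = {}
    for _ in range(n):
        rep = msa.resample_columns(rng)
        rep_tree, _ = ml_optimize(nj_tree(protein_distance(rep)), rep, model)
        for split in rep_tree.splits():
            split_counts[split] = split_counts.get(split, 0) + 1

    all_leaves = frozenset(main_tree.leaf_names())

    def annotate(node: Node) -> None:
        for child in node.children:
            annotate(child)
        if node.is_leaf or node.parent is None:
            return
        side = frozenset(
            leaf.name for leaf in node.traverse_postorder() if leaf.is_leaf
        )
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            split = frozenset((side, other))
            node.support = int(round(100 * split_counts.get(split, 0) / n))

    annotate(main_tree.root)
    return main_tree


# ---------------------------------------------------------------------------
# Clade partitioning


@dataclass
class CladePartition:
    """Major clades (size >= min_clade_size) and the orphan remainder."""

    clades: list[list[str]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    def membership(self) -> dict[str, str]:
        out = {}
        for k, clade in enumerate(self.clades, start=1):
            for m in clade:
                out[m] = f"clade_{k}"
        for m in self.orphans:
            out[m] = "orphan"
        return out


def partition_clades(
    seqs: list[SeqRecord],
    similarity_threshold: float = 50.0,
    min_clade_size: int = 3,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> CladePartition:
    """Single-linkage clusters of pairwise local-alignment percent similarity.

    Clusters of at least ``min_clade_size`` members are major clades (sorted
    by size, then lexicographically); members of smaller clusters are
    orphans.  Deterministic.
    """
    groups = group_by_similarity(seqs, similarity_threshold, scheme)
    clades = sorted(
        (sorted(m) for m, _rep in groups if len(m) >= min_clade_size),
        key=lambda c: (-len(c), c[0]),
    )
    orphans = sorted(
        m for members, _rep in groups if len(members) < min_clade_size
        for m in members
    )
    return CladePartition(clades=[list(c) for c in clades], orphans=orphans)


def assign_to_reference_clades(
    queries: list[SeqRecord],
    labeled_references: list[tuple[SeqRecord, str]],
    similarity_threshold: float = 50.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, str]:
    """Assign each query the clade label of its most similar reference.

    A query whose best reference similarity is below the threshold is called
    ``novel``.  Ties are broken by higher similarity, then lexicographic
    label.
    """
    if not labeled_references:
        raise ValueError("empty reference set")
    cache = _SimilarityCache(scheme)
    out: dict[str, str] = {}
    for q in queries:
        best: tuple[float, str] | None = None
        for ref, label in labeled_references:
            if ref.id == q.id:
                continue
            sim = cache.similarity(q, ref)
            cand = (sim, label)
            if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and cand[1] < best[1]
            ):
                best = cand
        if best is None or best[0] < similarity_threshold:
            out[q.id] = "novel"
        else:
            out[q.id] = best[1]
    return out
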