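"""GC/read-depth contig binning with marker-based contaminant removal.

Contigs are clustered into genome bins by single linkage under two hard
gates: two contigs link iff their GC contents differ by at most ``gc_tol``
AND their depths differ by at most ``depth_tol_log2`` on a log2 scale
(coverage errors are multiplicative).  Hard gates keep the procedure
auditable, which suits a binning step that in practice is threshold-like and
manually curated.  Bins can then be purged of contigs whose marker-gene
taxonomy conflicts with the bin majority — the generalization of removing
individual contaminating lineages from a bin by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DepthRow, SeqRecord


@dataclass(frozen=True)
class ContigProfile:
    contig_id: str
    length: int
    gc: float
    depth: float

    def __post_init__(self):
        if not (0 <= self.gc <= 1):
            raise ValueError(f"{self.contig_id}: gc outside [0, 1]")
        if self.depth < 0:
            raise ValueError(f"{self.contig_id}: negative depth")
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: non-positive length")


@dataclass(frozen=True)
class BinSummary:
    bin_id: int
    n_contigs: int
    total_bp: int
    mean_gc: float
    mean_depth: float


@dataclass
class BinAssignment:
    """contig -> bin map plus per-bin summaries; bin ids are dense from 1."""

    contig_to_bin: dict[str, int]
    summaries: list[BinSummary]
    unbinned: list[str] = field(default_factory=list)

    def members(self, bin_id: int) -> list[str]:
        return sorted(c for c, b in self.contig_to_bin.items() if b == bin_id)

    @property
    def n_bins(self) -> int:
        return len(self.summaries)


def profile_contigs(
    contigs: list[SeqRecord], depth_table: list[DepthRow]
) -> list[ContigProfile]:
    """Per-contig (length, GC, depth) profiles.

    GC is computed over unambiguous A/C/G/T only; N is excluded from both
    numerator and denominator.  Every contig must have a depth row.
    """
    depth = {row.contig_id: row.mean_depth for row in depth_table}
    profiles = []
    for rec in contigs:
        if rec.id not in depth:
            raise KeyError(f"contig {rec.id!r} missing from the depth table")
        seq = rec.residues
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            raise ValueError(f"contig {rec.id!r} has no unambiguous bases")
        gc = (seq.count("G") + seq.count("C")) / acgt
        profiles.append(
            ContigProfile(
                contig_id=rec.id, length=len(seq), gc=gc, depth=depth[rec.id]
            )
        )
    return profiles


def bin_contigs(
    profiles: list[ContigProfile],
    gc_tol: float = 0.025,
    depth_tol_log2: float = 0.5,
    min_len: int = 2000,
) -> BinAssignment:
    """Single-linkage binning under the GC and log2-depth gates.

    Contigs shorter than ``min_len`` are reported unbinned.  A zero-depth
    contig is assigned a pseudo-depth of 0.01 (with a warning) so the log2
    comparison stays defined.  Output is deterministic and invariant to
    input order: bins are numbered by their lexicographically smallest
    member.
    """
    if not profiles:
        raise ValueError("no contig profiles supplied")
    eligible = sorted(
        (p for p in profiles if p.length >= min_len), key=lambda p: p.contig_id
    )
    unbinned = sorted(p.contig_id for p in profiles if p.length < min_len)

    depths = []
    for p in eligible:
        d = p.depth
        if d == 0:
            warnings.warn(
                f"contig {p.contig_id} has zero depth; using pseudo-depth 0.01"
            )
            d = 0.01
        depths.append(d)

    n = len(eligible)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    log2d = np.log2(np.array(depths)) if n else np.array([])
    gcs = np.array([p.gc for p in eligible])
    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(gcs[i] - gcs[j]) <= gc_tol
                and abs(log2d[i] - log2d[j]) <= depth_tol_log2
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idxs: eligible[idxs[0]].contig_id)

    contig_to_bin: dict[str, int] = {}
    summaries: list[BinSummary] = []
    for bin_id, idxs in enumerate(ordered, start=1):
        members = [eligible[i] for i in idxs]
        for m in members:
            contig_to_bin[m.contig_id] = bin_id
        total = sum(m.length for m in members)
        summaries.append(
            BinSummary(
                bin_id=bin_id,
                n_contigs=len(members),
                total_bp=total,
                mean_gc=float(np.average([m.gc for m in members],
                                         weights=[m.length for m in members])),
                mean_depth=float(np.mean([m.depth for m in members])),
            )
        )
    return BinAssignment(
        contig_to_bin=contig_to_bin, summaries=summaries, unbinned=unbinned
    )


def purge_conflicts(
    bin_members: list[str], marker_taxon_calls: dict[str, str]
) -> tuple[list[str], list[str]]:
    """Remove contigs whose marker taxon conflicts with the bin majority.

    The majority taxon is the modal label among the bin's marker-bearing
    contigs; contigs with a different label are removed, unlabeled contigs
    are kept.  On a tie nothing is removed and a warning is issued.
    Returns (kept, removed), both sorted.
    """
    labels = [
        marker_taxon_calls[c] for c in bin_members if c in marker_taxon_calls
    ]
    if not labels:
        return sorted(bin_members), []
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    modal = [lab for lab, c in counts.items() if c == top]
    if len(modal) > 1:
        warnings.warn(
            f"marker-taxon tie among {sorted(modal)}; no contigs removed"
        )
        return sorted(bin_members), []
    majority = modal[0]
    kept, removed = [], []
    for c in bin_members:
        if c in marker_taxon_calls and marker_taxon_calls[c] != majority:
            removed.append(c)
        else:
            kept.append(c)
    return sorted(kept), sorted(removed)
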