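"""Operon detection and SepRS-SepCysS pairing.

Paired SepCysS genes usually lie close to the SepRS gene —
in the same operon or on the same contig — and otherwise can be attributed
through contig binning, because an organism's SepRS and SepCysS genes
travel together even when assembly scatters them across contigs.  Pairing
therefore walks an evidence hierarchy: same operon > same contig > same
bin.  A genome may carry one *or two* SepCysS partners, so every SepCysS in
the SepRS's bin is reported as a partner while the recorded evidence level
is the strongest relation among them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_formats import FeatureRow

SEPCYSS_FAMILIES = frozenset({"SepCysS", "SepCysSN"})


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    protein_id: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


def gene_calls_from_gff(rows: list[FeatureRow]) -> list[GeneCall]:
    """Convert annotation rows (gene and tRNA features) into GeneCalls."""
    calls = []
    for row in rows:
        if row.feature_type not in ("gene", "tRNA"):
            continue
        calls.append(
            GeneCall(
                gene_id=row.attributes.get("ID", f"{row.contig_id}:{row.start}"),
                contig=row.contig_id,
                start=row.start,
                end=row.end,
                strand=row.strand,
                family=row.attributes.get("family", ""),
                protein_id=row.attributes.get("protein_id"),
            )
        )
    return calls


@dataclass(frozen=True)
class OperonCall:
    contig: str
    strand: str
    member_gene_ids: tuple[str, ...]
    span: tuple[int, int]


@dataclass(frozen=True)
class PairingRecord:
    seprs_gene: str
    partner_genes: tuple[str, ...]
    evidence: str  # operon | contig | bin | unpaired
    bin_id: int | None


@dataclass
class PairingResult:
    records: list[PairingRecord] = field(default_factory=list)
    unpaired_sepcyss: list[str] = field(default_factory=list)


def call_operons(genes: list[GeneCall], max_gap: int = 150) -> list[OperonCall]:
    """Maximal same-contig, same-strand runs with intergenic gaps <= max_gap.

    Genes are sorted by (contig, start); singletons come out as one-gene
    operons.  Overlapping same-strand genes stay in one operon (warning).
    """
    operons: list[OperonCall] = []
    by_contig: dict[str, list[GeneCall]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: (g.start, g.end))
        run: list[GeneCall] = []
        for g in ordered:
            if run and g.strand == run[-1].strand:
                gap = g.start - run[-1].end - 1
                if gap < 0:
                    warnings.warn(
                        f"overlapping genes {run[-1].gene_id}/{g.gene_id} "
                        f"kept in one operon"
                    )
                if gap <= max_gap:
                    run.append(g)
                    continue
            if run:
                operons.append(_close_run(run))
            run = [g]
        if run:
            operons.append(_close_run(run))
    return operons


def _close_run(run: list[GeneCall]) -> OperonCall:
    return OperonCall(
        contig=run[0].contig,
        strand=run[0].strand,
        member_gene_ids=tuple(g.gene_id for g in run),
        span=(min(g.start for g in run), max(g.end for g in run)),
    )


def pair_systems(
    genes: list[GeneCall],
    operons: list[OperonCall],
    contig_to_bin: dict[str, int],
) -> PairingResult:
    """Pair each SepRS with the SepCysS genes of its bin.

    Partners are every SepCysS (including SepCysS with a fused N-terminal
    SepCysE domain) in the same bin as the SepRS; when the SepRS's contig is
    unbinned only its own contig is searched.  ``evidence`` is the strongest
    relation to any partner: operon > contig > bin.  SepRS with no partner
    and SepCysS with no SepRS in their bin are reported unpaired.
    """
    operon_of: dict[str, int] = {}
    for i, op in enumerate(operons):
        for gid in op.member_gene_ids:
            operon_of[gid] = i

    seprs = [g for g in genes if g.family == "SepRS"]
    sepcyss = [g for g in genes if g.family in SEPCYSS_FAMILIES]
    result = PairingResult()
    claimed: set[str] = set()

    for s in sorted(seprs, key=lambda g: g.gene_id):
        bin_id = contig_to_bin.get(s.contig)
        if bin_id is None:
            candidates = [c for c in sepcyss if c.contig == s.contig]
        else:
            candidates = [
                c for c in sepcyss if contig_to_bin.get(c.contig) == bin_id
            ]
        if not candidates:
            result.records.append(
                PairingRecord(
                    seprs_gene=s.gene_id, partner_genes=(), evidence="unpaired",
                    bin_id=bin_id,
                )
            )
            continue
        evidence = "bin"
        for c in candidates:
            if (
                s.gene_id in operon_of
                and operon_of.get(c.gene_id) == operon_of[s.gene_id]
            ):
                evidence = "operon"
                break
            if c.contig == s.contig:
                evidence = "contig"
        claimed.update(c.gene_id for c in candidates)
        result.records.append(
            PairingRecord(
                seprs_gene=s.gene_id,
                partner_genes=tuple(sorted(c.gene_id for c in candidates)),
                evidence=evidence,
                bin_id=bin_id,
            )
        )

    seprs_bins = {contig_to_bin.get(s.contig) for s in seprs}
    for c in sorted(sepcyss, key=lambda g: g.gene_id):
        if c.gene_id in claimed:
            continue
        if contig_to_bin.get(c.contig) not in seprs_bins or not seprs:
            result.unpaired_sepcyss.append(c.gene_id)
    return result
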