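"""Per-bin Pyl/Sec trait detection and the SepRS x trait co-occurrence table.

Pyrrolysine usage is encoded in three architectures — a single fused pylS
gene, split pylSn + pylSc genes, or pylSc alone — usually clustered with the
tRNA(Pyl) gene (pylT), the biosynthesis genes pylBCD and the Pyl-dependent
methylamine methyltransferases (mtmB/mtbB/mttB).  The selenocysteine trait
is detected at the protein-homolog level through four shared selenoprotein
families (SPS, HdrA, VhuD, VhuU); SPS sometimes occurs split in two
fragments.  Trait calls are made per genome bin, the unit of attribution,
and tabulated against SepRS/SepCysS/SepCysE status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .gene_pairing import GeneCall, OperonCall
from .homolog_search import DEFAULT_SCHEME, ScoringScheme, local_align
from .io_formats import SeqRecord

PYL_ACCESSORIES = ("pylT", "pylB", "pylC", "pylD", "mtmB", "mtbB", "mttB")
SEC_FAMILIES = ("SPS", "HdrA", "VhuD", "VhuU")


@dataclass
class TraitProfile:
    bin_id: int | str
    has_seprs: bool = False
    has_sepcyss: bool = False
    sepcysE_status: str = "none"      # none | full | split_n | fused_N
    pyl_architecture: str = "none"    # none | single_pylS | split_pylSn_pylSc | pylSc_only
    pyl_accessories: frozenset = frozenset()
    pyl_clustered: bool = False
    sec_families: frozenset = frozenset()
    sps_split: bool = False
    uncertain: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.pyl_architecture == "pylSc_only" and "pylSn" in self.notes:
            raise ValueError("pylSc_only profile cannot also carry pylSn")


def detect_pyl(
    bin_genes: list[GeneCall], operons: list[OperonCall] | None = None
) -> tuple[str, frozenset, bool, list[str]]:
    """Pyl architecture, accessories and cluster flag for one bin's genes.

    Architecture: fused full-length PylS -> ``single_pylS``; separate PylSn
    and PylSc -> ``split_pylSn_pylSc``; PylSc alone -> ``pylSc_only``.  A
    contradictory bin (both fused and split forms) is reported as
    ``single_pylS`` with a warning note.  The cluster flag is set when a
    PylRS gene shares an operon with at least two accessories.
    """
    labels = {g.family for g in bin_genes}
    notes: list[str] = []
    has_pyls = "pylS" in labels
    has_n = "pylSn" in labels
    has_c = "pylSc" in labels
    if has_pyls and (has_n or has_c):
        msg = "both fused pylS and split pylSn/pylSc present"
        warnings.warn(msg)
        notes.append(msg)
    if has_pyls:
        arch = "single_pylS"
    elif has_n and has_c:
        arch = "split_pylSn_pylSc"
    elif has_c:
        arch = "pylSc_only"
    else:
        arch = "none"
    accessories = frozenset(a for a in PYL_ACCESSORIES if a in labels)

    clustered = False
    if operons:
        pylrs_ids = {
            g.gene_id for g in bin_genes if g.family in ("pylS", "pylSc")
        }
        acc_ids = {
            g.gene_id for g in bin_genes if g.family in PYL_ACCESSORIES
        }
        for op in operons:
            members = set(op.member_gene_ids)
            if members & pylrs_ids and len(members & acc_ids) >= 2:
                clustered = True
                break
    return arch, accessories, clustered, notes


def detect_sec(
    bin_genes: list[GeneCall],
    proteins: dict[str, SeqRecord] | None = None,
    sps_reference: SeqRecord | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[frozenset, bool]:
    """Selenoprotein families present in a bin, and whether SPS is split.

    ``sps_split`` is true iff at least two sub-full-length SPS fragments
    jointly cover >= 80% of the SPS reference while each covers < 60%;
    this needs the protein sequences and the SPS reference — without them
    only family presence is reported.
    """
    families = frozenset(
        f for f in SEC_FAMILIES if any(g.family == f for g in bin_genes)
    )
    sps_split = False
    sps_genes = [g for g in bin_genes if g.family == "SPS"]
    if (
        len(sps_genes) >= 2
        and proteins is not None
        and sps_reference is not None
    ):
        ref_len = len(sps_reference.residues)
        intervals = []
        for g in sps_genes:
            if g.protein_id is None or g.protein_id not in proteins:
                continue
            aln = local_align(proteins[g.protein_id], sps_reference, scheme)
            if aln.is_empty:
                continue
            cov = (aln.subject_end - aln.subject_start + 1) / ref_len
            if cov < 0.6:
                intervals.append((aln.subject_start, aln.subject_end))
        if len(intervals) >= 2:
            covered = set()
            for lo, hi in intervals:
                covered.update(range(lo, hi + 1))
            if len(covered) / ref_len >= 0.8:
                sps_split = True
    return families, sps_split


def build_trait_profile(
    bin_id: int | str,
    bin_genes: list[GeneCall],
    operons: list[OperonCall] | None = None,
    sepcysE_status: str = "none",
    proteins: dict[str, SeqRecord] | None = None,
    sps_reference: SeqRecord | None = None,
    uncertain: bool = False,
) -> TraitProfile:
    arch, accessories, clustered, notes = detect_pyl(bin_genes, operons)
    sec, sps_split = detect_sec(bin_genes, proteins, sps_reference)
    return TraitProfile(
        bin_id=bin_id,
        has_seprs=any(g.family == "SepRS" for g in bin_genes),
        has_sepcyss=any(
            g.family in ("SepCysS", "SepCysSN") for g in bin_genes
        ),
        sepcysE_status=sepcysE_status,
        pyl_architecture=arch,
        pyl_accessories=accessories,
        pyl_clustered=clustered,
        sec_families=sec,
        sps_split=sps_split,
        uncertain=uncertain,
        notes=notes,
    )


@dataclass
class CooccurrenceTable:
    """Per-bin trait rows plus summary tallies (tallies = column recounts)."""

    rows: pd.DataFrame
    summary: dict[str, int]

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def build_cooccurrence(profiles: list[TraitProfile]) -> CooccurrenceTable:
    """Tabulate trait profiles and tally the headline co-occurrences.

    Summary counts: bins with SepRS, with a Pyl system, with the Sec trait
    (any selenoprotein family), and the pairwise co-occurrences including
    full-length SepCysE with Sec.  An ``uncertain`` flag is propagated for
    bins whose attribution was marked low-confidence.
    """
    if not profiles:
        raise ValueError("no trait profiles supplied")
    records = []
    for p in profiles:
        records.append(
            {
                "bin_id": p.bin_id,
                "has_seprs": int(p.has_seprs),
                "has_sepcyss": int(p.has_sepcyss),
                "sepcysE_status": p.sepcysE_status,
                "pyl_architecture": p.pyl_architecture,
                "pyl_accessories": ",".join(sorted(p.pyl_accessories)) or ".",
                "pyl_clustered": int(p.pyl_clustered),
                "sec_families": ",".join(sorted(p.sec_families)) or ".",
                "n_sec_families": len(p.sec_families),
                "sps_split": int(p.sps_split),
                "uncertain": "?" if p.uncertain else "",
            }
        )
    df = pd.DataFrame.from_records(records)

    has_pyl = [p.pyl_architecture != "none" for p in profiles]
    has_sec = [bool(p.sec_families) for p in profiles]
    summary = {
        "n_bins": len(profiles),
        "seprs": sum(p.has_seprs for p in profiles),
        "pyl": sum(has_pyl),
        "sec": sum(has_sec),
        "seprs_and_pyl": sum(
            p.has_seprs and h for p, h in zip(profiles, has_pyl)
        ),
        "seprs_and_sec": sum(
            p.has_seprs and h for p, h in zip(profiles, has_sec)
        ),
        "sepcysE_full_and_sec": sum(
            p.sepcysE_status == "full" and h
            for p, h in zip(profiles, has_sec)
        ),
    }
    return CooccurrenceTable(rows=df, summary=summary)
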