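"""End-to-end analysis: bin, purge, pair, classify, tabulate.

Takes the standard inputs (contigs + depth table, gene annotations, protein
and tRNA sequences, per-family reference sequences) and runs the full
discovery pipeline: GC/depth binning with marker-based contaminant removal,
operon detection, SepRS-SepCysS pairing by the operon > contig > bin
evidence hierarchy, SepRS truncation and SepCysE homolog classification,
tRNA N37 typing, and per-bin Pyl/Sec trait co-occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .contig_binning import BinAssignment, bin_contigs, profile_contigs, purge_conflicts
from .feature_rules import (
    DomainModel,
    TrnaCall,
    classify_sepcysE_homolog,
    classify_trna,
    detect_seprs_truncation,
)
from .gene_pairing import (
    GeneCall,
    PairingResult,
    call_operons,
    gene_calls_from_gff,
    pair_systems,
)
from .io_formats import DepthRow, FeatureRow, SeqRecord
from .trait_cooccurrence import (
    CooccurrenceTable,
    TraitProfile,
    build_cooccurrence,
    build_trait_profile,
)

SEPRS_CATALYTIC_SPAN = (1, 390)
SEPRS_CTERM_SPAN = (391, 520)
SEPCYSE_N_DOMAIN = (1, 110)


@dataclass
class PipelineResult:
    bins: BinAssignment
    contig_to_bin: dict[str, int]          # after purging
    removed_contigs: list[str]
    uncertain_bins: set[int]
    genes: list[GeneCall]
    pairing: PairingResult
    seprs_truncation: dict[str, str]       # protein id -> full | delta_C | none
    sepcysE_status: dict[int, str]         # bin id -> status
    trna_calls: list[TrnaCall]
    profiles: list[TraitProfile]
    cooccurrence: CooccurrenceTable


def marker_taxon_calls(annotations: list[FeatureRow]) -> dict[str, str]:
    """contig -> taxon for contigs carrying annotated marker genes."""
    calls: dict[str, str] = {}
    for row in annotations:
        if row.attributes.get("family") == "marker" and "taxon" in row.attributes:
            calls[row.contig_id] = row.attributes["taxon"]
    return calls


def run_pipeline(
    contigs: list[SeqRecord],
    depth: list[DepthRow],
    annotations: list[FeatureRow],
    proteins: list[SeqRecord],
    trnas: list[SeqRecord],
    references: dict[str, SeqRecord],
    gc_tol: float = 0.025,
    depth_tol_log2: float = 0.5,
    min_len: int = 2000,
    max_gap: int = 150,
) -> PipelineResult:
    # --- binning + purge
    profiles = profile_contigs(contigs, depth)
    bins = bin_contigs(profiles, gc_tol=gc_tol, depth_tol_log2=depth_tol_log2,
                       min_len=min_len)
    markers = marker_taxon_calls(annotations)
    contig_to_bin = dict(bins.contig_to_bin)
    removed: list[str] = []
    uncertain: set[int] = set()
    for summary in bins.summaries:
        members = bins.members(summary.bin_id)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _kept, dropped = purge_conflicts(members, markers)
        if any("tie" in str(w.message) for w in caught):
            uncertain.add(summary.bin_id)
        for c in dropped:
            removed.append(c)
            del contig_to_bin[c]

    # --- genes, operons, pairing
    genes = gene_calls_from_gff(annotations)
    operons = call_operons(genes, max_gap=max_gap)
    pairing = pair_systems(genes, operons, contig_to_bin)

    prot_by_id = {p.id: p for p in proteins}

    # --- SepRS truncation
    seprs_trunc: dict[str, str] = {}
    if "SepRS" in references:
        model = DomainModel(
            reference=references["SepRS"],
            spans={"catalytic": SEPRS_CATALYTIC_SPAN, "cterm": SEPRS_CTERM_SPAN},
        )
        for g in genes:
            if g.family == "SepRS" and g.protein_id in prot_by_id:
                seprs_trunc[g.protein_id] = detect_seprs_truncation(
                    prot_by_id[g.protein_id], model
                )

    # --- SepCysE homolog classification per bin
    sepcysE_status: dict[int, str] = {}
    if "SepCysE" in references and "SepCysS" in references:
        ref_e = references["SepCysE"]
        lo, hi = SEPCYSE_N_DOMAIN
        n_dom = SeqRecord(id="SepCysE_Ndom", residues=ref_e.residues[lo - 1 : hi])
        core = references["SepCysS"]
        # genes immediately preceding a SepCysS in their operon
        precedes: set[str] = set()
        for op in operons:
            fams = [
                next((g.family for g in genes if g.gene_id == gid), "")
                for gid in op.member_gene_ids
            ]
            for k in range(len(fams) - 1):
                if fams[k + 1] in ("SepCysS", "SepCysSN"):
                    precedes.add(op.member_gene_ids[k])
        candidates = [
            g for g in genes
            if g.family in ("SepCysE", "SepCysSn", "SepCysSN")
            or (g.gene_id in precedes and g.family not in
                ("SepCysS", "SepRS", "tRNA-Cys"))
        ]
        per_bin: dict[int, list[str]] = {}
        for g in candidates:
            if g.protein_id not in prot_by_id:
                continue
            call = classify_sepcysE_homolog(
                prot_by_id[g.protein_id], n_dom, core,
                precedes_sepcyss=g.gene_id in precedes,
            )
            bin_id = contig_to_bin.get(g.contig)
            if bin_id is not None and call != "none":
                per_bin.setdefault(bin_id, []).append(call)
        for bin_id, calls in per_bin.items():
            for status in ("full", "split_n", "fused_N"):
                if status in calls:
                    sepcysE_status[bin_id] = status
                    break

    # --- tRNA typing
    trna_by_id = {t.id: t for t in trnas}
    trna_calls: list[TrnaCall] = []
    for row in annotations:
        if row.feature_type != "tRNA":
            continue
        tid = row.attributes.get("trna_id")
        if tid and tid in trna_by_id:
            call = classify_trna(trna_by_id[tid], row.attributes)
            if call is not None:
                trna_calls.append(call)

    # --- per-bin trait profiles and co-occurrence
    genes_by_bin: dict[int, list[GeneCall]] = {}
    for g in genes:
        bin_id = contig_to_bin.get(g.contig)
        if bin_id is not None:
            genes_by_bin.setdefault(bin_id, []).append(g)
    trait_profiles = [
        build_trait_profile(
            bin_id=bin_id,
            bin_genes=genes_by_bin.get(bin_id, []),
            operons=operons,
            sepcysE_status=sepcysE_status.get(bin_id, "none"),
            proteins=prot_by_id,
            sps_reference=references.get("SPS"),
            uncertain=bin_id in uncertain,
        )
        for bin_id in sorted(genes_by_bin)
    ]
    cooc = build_cooccurrence(trait_profiles) if trait_profiles else None

    return PipelineResult(
        bins=bins,
        contig_to_bin=contig_to_bin,
        removed_contigs=removed,
        uncertain_bins=uncertain,
        genes=genes,
        pairing=pairing,
        seprs_truncation=seprs_trunc,
        sepcysE_status=sepcysE_status,
        trna_calls=trna_calls,
        profiles=trait_profiles,
        cooccurrence=cooc,
    )
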