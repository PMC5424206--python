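"""Reference-anchored sequence-feature rules.

The diagnostic idiosyncrasies of bacterial-type SepRS/SepCysS systems are
defined in the coordinate system of structural reference proteins: the
hydrophobic residue at SepRS position 444 (replaced by a hydrophilic
residue, mostly Asp, in bacterial SepRS), the SepCysS loop at residues
144-147 (missing in most bacterial SepCysS), the 8-residue indel between
residues 234 and 235, conservation of the PLP-binding site, the three
persulfide-forming cysteines, the SepRS C-terminal anticodon-binding-domain
truncation (SepRS-DeltaC), the full/split/fused status of SepCysE homologs,
and the base 3' of the tRNA anticodon (N37: archaeal-type G37 vs
bacterial-type A37).

All rules are evaluated through a ReferenceMap, which numbers the non-gap
columns of a chosen reference row of an MSA consecutively from 1, so rule
positions written against the reference apply to every aligned member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import yaml

from .homolog_search import (
    DEFAULT_SCHEME,
    PairwiseAlignment,
    ScoringScheme,
    local_align,
    percent_similarity,
)
from .io_formats import SeqRecord
from .msa_phylo import GAP, MSA

HYDROPHILIC = frozenset("DENQKRSTH")
HYDROPHOBIC = frozenset("AILMFVWY")


@dataclass
class ReferenceMap:
    """Reference residue numbering over MSA columns.

    ``pos_to_col`` maps 1-based reference residue numbers to 0-based MSA
    columns, strictly increasing over the reference's non-gap columns.
    """

    msa: MSA
    reference_id: str
    pos_to_col: dict[int, int]

    @property
    def reference_length(self) -> int:
        return len(self.pos_to_col)

    def member_ids(self) -> list[str]:
        return [i for i in self.msa.ids]


def map_reference(msa: MSA, reference_id: str) -> ReferenceMap:
    if reference_id not in msa.ids:
        raise KeyError(f"reference {reference_id!r} absent from the alignment")
    row = msa.row(reference_id)
    pos_to_col = {}
    pos = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            pos += 1
            pos_to_col[pos] = col
    return ReferenceMap(msa=msa, reference_id=reference_id, pos_to_col=pos_to_col)


@dataclass
class RuleSet:
    """Reference positions of the diagnostic features.

    Positions are 1-based reference residue numbers.  PLP positions are
    checked for identity with the reference residue; persulfide positions
    are checked for cysteine.
    """

    plp_positions: tuple[int, ...] = (97, 175, 232)
    persulfide_positions: tuple[int, ...] = (64, 270, 280)
    loop_span: tuple[int, int] = (144, 147)
    indel_point: int = 234        # the indel sits between this and the next residue
    res444_position: int = 444
    hydrophilic: frozenset = HYDROPHILIC
    hydrophobic: frozenset = HYDROPHOBIC

    def validate(self, reference_length: int) -> None:
        positions = [
            *self.plp_positions, *self.persulfide_positions,
            *self.loop_span, self.indel_point, self.indel_point + 1,
        ]
        for pos in positions:
            if not (1 <= pos <= reference_length):
                raise ValueError(
                    f"rule position {pos} outside reference length "
                    f"{reference_length}"
                )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "plp_positions": list(self.plp_positions),
                "persulfide_positions": list(self.persulfide_positions),
                "loop_span": list(self.loop_span),
                "indel_point": self.indel_point,
                "res444_position": self.res444_position,
                "hydrophilic": sorted(self.hydrophilic),
                "hydrophobic": sorted(self.hydrophobic),
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RuleSet":
        data = yaml.safe_load(text)
        return cls(
            plp_positions=tuple(data["plp_positions"]),
            persulfide_positions=tuple(data["persulfide_positions"]),
            loop_span=tuple(data["loop_span"]),
            indel_point=data["indel_point"],
            res444_position=data["res444_position"],
            hydrophilic=frozenset(data["hydrophilic"]),
            hydrophobic=frozenset(data["hydrophobic"]),
        )


@dataclass(frozen=True)
class FeatureReport:
    seq_id: str
    plp_conserved: bool | None = None
    persulfide_cys_count: int | None = None
    loop_present: bool | None = None
    indel_234_235: int | None = None
    res444_class: str | None = None  # hydrophobic | hydrophilic | other | None


def _indel_at_point(refmap: ReferenceMap, member_row: str, point: int) -> int:
    """Signed indel length at the junction between ``point`` and ``point+1``.

    Insertions: member residues in MSA columns strictly between the
    reference columns of ``point`` and ``point+1``.  Deletions: the maximal
    run of member gap columns touching the junction, counting only columns
    where the reference itself has a residue.  The net value is
    insertions minus deletions (0 = reference-like).
    """
    ref_row = refmap.msa.row(refmap.reference_id)
    c_a = refmap.pos_to_col[point]
    c_b = refmap.pos_to_col[point + 1]
    inserted = sum(
        1 for col in range(c_a + 1, c_b) if member_row[col] != GAP
    )
    # maximal member-gap run touching the junction (either side, or between)
    deletion = 0
    if inserted == 0:
        anchor_cols = [c for c in (c_a, c_b) if member_row[c] == GAP]
        between_gap = any(
            member_row[c] == GAP for c in range(c_a + 1, c_b)
        )
        if anchor_cols or between_gap:
            start = anchor_cols[0] if anchor_cols else c_a + 1
            lo = start
            while lo > 0 and member_row[lo - 1] == GAP:
                lo -= 1
            hi = start
            while hi < len(member_row) - 1 and member_row[hi + 1] == GAP:
                hi += 1
            deletion = sum(
                1 for col in range(lo, hi + 1) if ref_row[col] != GAP
            )
    return inserted - deletion


def evaluate_features(
    refmap: ReferenceMap, rules: RuleSet
) -> dict[str, FeatureReport]:
    """Evaluate every rule for every aligned member (reference included).

    The reference evaluated against itself is the fixed point: loop present,
    indel 0, all PLP residues conserved, full persulfide count, and the
    reference's own residue-444 class.
    """
    rules.validate(refmap.reference_length)
    ref_row = refmap.msa.row(refmap.reference_id)
    reports: dict[str, FeatureReport] = {}
    for seq_id in refmap.msa.ids:
        row = refmap.msa.row(seq_id)

        plp = all(
            row[refmap.pos_to_col[p]] == ref_row[refmap.pos_to_col[p]]
            for p in rules.plp_positions
        )
        persulfide = sum(
            1 for p in rules.persulfide_positions
            if row[refmap.pos_to_col[p]] == "C"
        )
        lo, hi = rules.loop_span
        loop_cols = [refmap.pos_to_col[p] for p in range(lo, hi + 1)]
        loop_present = not all(row[c] == GAP for c in loop_cols)
        indel = _indel_at_point(refmap, row, rules.indel_point)

        res444_class = None
        if rules.res444_position in refmap.pos_to_col:
            ch = row[refmap.pos_to_col[rules.res444_position]]
            if ch == GAP:
                res444_class = None
            elif ch in rules.hydrophobic:
                res444_class = "hydrophobic"
            elif ch in rules.hydrophilic:
                res444_class = "hydrophilic"
            else:
                res444_class = "other"

        reports[seq_id] = FeatureReport(
            seq_id=seq_id,
            plp_conserved=plp,
            persulfide_cys_count=persulfide,
            loop_present=loop_present,
            indel_234_235=indel,
            res444_class=res444_class,
        )
    return reports


# ---------------------------------------------------------------------------
# Domain-coverage classifiers


@dataclass(frozen=True)
class DomainModel:
    """A reference sequence with labeled spans (1-based inclusive)."""

    reference: SeqRecord
    spans: dict[str, tuple[int, int]]


def _span_coverage(aln: PairwiseAlignment, span: tuple[int, int]) -> float:
    """Fraction of the subject span covered by the alignment interval."""
    if aln.is_empty:
        return 0.0
    lo, hi = span
    cov_lo = max(lo, aln.subject_start)
    cov_hi = min(hi, aln.subject_end)
    return max(0, cov_hi - cov_lo + 1) / (hi - lo + 1)


def detect_seprs_truncation(
    protein: SeqRecord,
    domain_model: DomainModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    catalytic_min: float = 0.6,
    cterm_min: float = 0.5,
) -> str:
    """Classify a SepRS protein as ``full`` or ``delta_C``.

    ``delta_C`` requires the local alignment to the reference to cover at
    least ``catalytic_min`` of the catalytic span while covering less than
    ``cterm_min`` of the C-terminal anticodon-binding span.  A protein
    matching neither gate is reported ``none`` with a warning.
    """
    aln = local_align(protein, domain_model.reference, scheme)
    cat = _span_coverage(aln, domain_model.spans["catalytic"])
    cterm = _span_coverage(aln, domain_model.spans["cterm"])
    if cat >= catalytic_min and cterm >= cterm_min:
        return "full"
    if cat >= catalytic_min and cterm < cterm_min:
        return "delta_C"
    warnings.warn(
        f"{protein.id}: no confident SepRS domain match "
        f"(catalytic {cat:.2f}, C-terminal {cterm:.2f})"
    )
    return "none"


def classify_sepcysE_homolog(
    protein: SeqRecord,
    n_domain_reference: SeqRecord,
    sepcyss_reference: SeqRecord,
    precedes_sepcyss: bool = False,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    match_similarity: float = 40.0,
    domain_coverage: float = 0.5,
    fused_n_window: int = 120,
    split_max_len: int = 150,
) -> str:
    """Classify a SepCysE homolog: ``full``, ``split_n``, ``fused_N`` or ``none``.

    * ``full``: matches the N-terminal helix-turn-helix domain, extends to at
      least twice the domain length, and shows no SepCysS core.
    * ``fused_N``: the N-domain match lies within the protein's first
      ``fused_n_window`` residues and a SepCysS core follows (SepCysSN).
    * ``split_n``: a short (< ``split_max_len``) N-domain-only gene that
      immediately precedes a SepCysS gene in its operon (SepCysSn).
    """
    n_aln = local_align(protein, n_domain_reference, scheme)
    n_match = (
        not n_aln.is_empty
        and percent_similarity(n_aln, scheme) >= match_similarity
        and _span_coverage(n_aln, (1, len(n_domain_reference.residues)))
        >= domain_coverage
    )
    if not n_match:
        return "none"
    core_aln = local_align(protein, sepcyss_reference, scheme)
    core_match = (
        not core_aln.is_empty
        and percent_similarity(core_aln, scheme) >= match_similarity
        and _span_coverage(core_aln, (1, len(sepcyss_reference.residues)))
        >= domain_coverage
    )
    n_len = len(n_domain_reference.residues)
    if core_match and n_aln.query_start <= fused_n_window:
        return "fused_N"
    if not core_match and len(protein.residues) >= 2 * n_len:
        return "full"
    if (
        not core_match
        and len(protein.residues) < split_max_len
        and precedes_sepcyss
    ):
        return "split_n"
    return "none"


# ---------------------------------------------------------------------------
# tRNA typing


@dataclass(frozen=True)
class TrnaCall:
    trna_id: str
    anticodon: str
    n37: str
    isotype: str  # "Cys" iff anticodon GCA


def classify_trna(trna: SeqRecord, annotation: dict) -> TrnaCall | None:
    """Read the anticodon and N37 from an annotated tRNA gene sequence.

    ``annotation`` must provide ``anticodon_start`` (1-based position of the
    anticodon's first base).  N37 is the base immediately 3' of the
    anticodon.  Returns None (no-call, with a warning) when the annotation
    is missing or the anticodon sits at the sequence end.
    """
    start = annotation.get("anticodon_start")
    if start is None:
        warnings.warn(f"{trna.id}: no anticodon annotation; no call")
        return None
    start = int(start)
    if start < 1 or start + 3 > len(trna.residues):
        warnings.warn(
            f"{trna.id}: anticodon at {start} leaves no N37 position; no call"
        )
        return None
    anticodon = trna.residues[start - 1 : start + 2]
    n37 = trna.residues[start + 2]
    return TrnaCall(
        trna_id=trna.id,
        anticodon=anticodon,
        n37=n37,
        isotype="Cys" if anticodon == "GCA" else (
            "Pyl" if anticodon == "CTA" else "other"
        ),
    )
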