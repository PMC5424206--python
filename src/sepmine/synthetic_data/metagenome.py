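"""Synthetic metagenomes with planted gene systems and ground truth.

Each genome preset fixes a GC target, a mean read depth, a genome size and a
set of loci (ordered gene runs with strand and small intergenic gaps, i.e.
operons).  Proteins are drawn from the family models, back-translated with
codons biased toward the genome GC, and embedded in i.i.d. background DNA;
the genome is emitted as contigs whose per-contig depth is the genome depth
times lognormal noise.  Everything the downstream pipeline is supposed to
recover — contig-to-genome assignment, gene families and clades,
SepRS-SepCysS pairings, sequence features, tRNA N37 identity, Pyl/Sec trait
combinations — is recorded in a machine-readable ground truth.

The default cast of eight genomes emulates the configurations these systems
show in nature: a class I
methanogen-like genome with full SepCysE, two SepCysS copies and the four
selenoprotein families; a Methanosarcinaceae-like genome with a single-gene
pylS cluster; a Bathyarchaeota-like genome with the compact
tRNA(Cys)-SepCysSn-SepCysS-SepRS operon and a novel pylSc lineage; two
Parcubacteria-like genomes (bacterial-type SepRS features, A37 tRNA(Cys),
one SepRS-DeltaC); a Chloroflexi-like genome carrying both the
SepRS-SepCysS operon and a split pylSn/pylSc system; a
Methanomassiliicoccales-like genome (pylSc only, fused SepCysSN); and an
AK8/W8A-19-like genome with full SepCysE, a split SPS and a planted
contaminant contig from a foreign lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from ..io_formats import (
    DepthRow,
    FeatureRow,
    SeqRecord,
    write_depth_table,
    write_fasta,
    write_gff3,
)
from .families import (
    SEPCYSS_INDEL_POINT,
    SEPCYSS_LOOP_SPAN,
    SEPCYSS_PERSULFIDE_SITES,
    SEPRS_CTERM_SPAN,
    SEPRS_RES444,
    FamilyModel,
    Indel,
    MemberPlan,
    default_family_configs,
    make_family_models,
    sample_member,
)

HYDROPHILIC = set("DENQKRSTH")
HYDROPHOBIC = set("AILMFVWY")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Preset vocabulary


@dataclass(frozen=True)
class GenePart:
    """One component of a planted protein: a family member, optionally a
    sub-span (for split/fragment genes), with planned indels and feature
    overrides in reference coordinates."""

    family: str
    lineage: str = "main"
    span: tuple[int, int] | None = None
    indels: tuple[Indel, ...] = ()
    features: dict[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PlantedGene:
    """A gene to plant: protein (one or more parts, >1 = fusion) or tRNA."""

    name: str                    # human-readable role, e.g. "SepCysSn"
    label: str                   # family label written to the annotation
    parts: tuple[GenePart, ...] = ()
    kind: str = "protein"        # protein | trna
    anticodon: str = "GCA"
    n37: str = "G"
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Locus:
    """Genes co-located in one strand-consistent run (operon candidate)."""

    genes: tuple[PlantedGene, ...]
    strand: str = "+"
    colocate: str | None = None  # loci sharing a key land on one contig


@dataclass(frozen=True)
class GenomePreset:
    name: str
    taxon: str
    gc: float
    depth: float
    loci: tuple[Locus, ...] = ()
    length: int = 200_000
    contig_min: int = 5_000
    contig_mean: int = 12_000
    n_markers: int = 2
    sepcysE_mode: str = "none"   # none | full | split_n | fused_N
    contaminant_taxon: str | None = None

    def __post_init__(self):
        if not (0 < self.gc < 1):
            raise ValueError(f"{self.name}: gc target must lie in (0, 1)")
        if self.depth <= 0:
            raise ValueError(f"{self.name}: depth target must be positive")


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    protein_id: str | None
    family: str
    clade: str
    genome: str
    contig: str


@dataclass(frozen=True)
class PairingTruth:
    seprs_gene: str
    partners: tuple[str, ...]
    genome: str
    evidence: str  # strongest expected evidence level


@dataclass(frozen=True)
class TraitTruth:
    genome: str
    has_seprs: bool
    has_sepcyss: bool
    sepcysE_status: str
    pyl_architecture: str
    pyl_accessories: frozenset[str]
    sec_families: frozenset[str]
    sps_split: bool
    sepcyss_copies: int
    seprs_truncated: bool


@dataclass(frozen=True)
class FeatureTruth:
    protein_id: str
    family: str
    res444: str | None = None
    res444_class: str | None = None
    loop_present: bool | None = None
    indel_234_235: int | None = None
    persulfide_count: int | None = None
    plp_conserved: bool | None = None
    truncation: str | None = None


@dataclass(frozen=True)
class TrnaTruth:
    trna_id: str
    anticodon: str
    n37: str
    isotype: str
    genome: str


@dataclass
class GroundTruth:
    contig_genome: dict[str, str] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    pairings: list[PairingTruth] = field(default_factory=list)
    traits: dict[str, TraitTruth] = field(default_factory=dict)
    features: dict[str, FeatureTruth] = field(default_factory=dict)
    trnas: dict[str, TrnaTruth] = field(default_factory=dict)
    taxa: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "contigs.tsv", "w") as fh:
            fh.write("contig_id\tgenome\n")
            for cid, genome in self.contig_genome.items():
                fh.write(f"{cid}\t{genome}\n")
        with open(outdir / "genes.tsv", "w") as fh:
            fh.write("gene_id\tprotein_id\tfamily\tclade\tgenome\tcontig\n")
            for g in self.genes.values():
                fh.write(
                    f"{g.gene_id}\t{g.protein_id or '.'}\t{g.family}\t"
                    f"{g.clade}\t{g.genome}\t{g.contig}\n"
                )
        with open(outdir / "pairings.tsv", "w") as fh:
            fh.write("seprs_gene\tpartners\tgenome\tevidence\n")
            for p in self.pairings:
                fh.write(
                    f"{p.seprs_gene}\t{','.join(p.partners) or '.'}\t"
                    f"{p.genome}\t{p.evidence}\n"
                )
        with open(outdir / "traits.tsv", "w") as fh:
            fh.write(
                "genome\thas_seprs\thas_sepcyss\tsepcysE_status\t"
                "pyl_architecture\tpyl_accessories\tsec_families\tsps_split\t"
                "sepcyss_copies\tseprs_truncated\n"
            )
            for t in self.traits.values():
                fh.write(
                    f"{t.genome}\t{int(t.has_seprs)}\t{int(t.has_sepcyss)}\t"
                    f"{t.sepcysE_status}\t{t.pyl_architecture}\t"
                    f"{','.join(sorted(t.pyl_accessories)) or '.'}\t"
                    f"{','.join(sorted(t.sec_families)) or '.'}\t"
                    f"{int(t.sps_split)}\t{t.sepcyss_copies}\t"
                    f"{int(t.seprs_truncated)}\n"
                )
        with open(outdir / "features.tsv", "w") as fh:
            fh.write(
                "protein_id\tfamily\tres444\tres444_class\tloop_present\t"
                "indel_234_235\tpersulfide_count\tplp_conserved\ttruncation\n"
            )
            for f in self.features.values():
                def _fmt(v):
                    if v is None:
                        return "."
                    if isinstance(v, bool):
                        return str(int(v))
                    return str(v)
                fh.write(
                    "\t".join(
                        [
                            f.protein_id, f.family, _fmt(f.res444),
                            _fmt(f.res444_class), _fmt(f.loop_present),
                            _fmt(f.indel_234_235), _fmt(f.persulfide_count),
                            _fmt(f.plp_conserved), _fmt(f.truncation),
                        ]
                    )
                    + "\n"
                )
        with open(outdir / "trnas.tsv", "w") as fh:
            fh.write("trna_id\tanticodon\tn37\tisotype\tgenome\n")
            for t in self.trnas.values():
                fh.write(
                    f"{t.trna_id}\t{t.anticodon}\t{t.n37}\t{t.isotype}\t{t.genome}\n"
                )
        with open(outdir / "taxa.tsv", "w") as fh:
            fh.write("genome\ttaxon\n")
            for genome, taxon in self.taxa.items():
                fh.write(f"{genome}\t{taxon}\n")


@dataclass
class SyntheticMetagenome:
    contigs: list[SeqRecord]
    depth: list[DepthRow]
    annotations: list[FeatureRow]
    proteins: list[SeqRecord]
    trnas: list[SeqRecord]
    truth: GroundTruth
    references: dict[str, SeqRecord]  # per-family reference sequences

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fna")
        write_depth_table(self.depth, outdir / "depth.tsv")
        write_gff3(self.annotations, outdir / "genes.gff3")
        write_fasta(self.proteins, outdir / "proteins.faa")
        if self.trnas:
            write_fasta(self.trnas, outdir / "trnas.fna")
        write_fasta(
            [self.references[k] for k in sorted(self.references)],
            outdir / "references.faa",
        )
        self.truth.write(outdir / "truth")


# ---------------------------------------------------------------------------
# Sequence-level helpers

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
# X has no codon; encode it as a GC-neutral placeholder
_AA_TO_CODONS.setdefault("X", ["AGC"])


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join("ATGC"[i] for i in rng.choice(4, size=length, p=p / p.sum()))


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def back_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Back-translate with synonymous codons weighted toward the GC target."""
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    out = []
    for aa in protein:
        codons = _AA_TO_CODONS[aa]
        weights = np.array(
            [base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons]
        )
        out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
    return "".join(out)


def evolve_dna(seq: str, distance: float, rng: np.random.Generator,
               frozen: set[int] = frozenset()) -> str:
    """Uniform 4-state substitution; ``frozen`` are 1-based immutable sites."""
    out = list(seq)
    k = rng.poisson(distance, size=len(seq))
    p_same = 1 / 4 + (3 / 4) * (-1 / 3.0) ** k
    u = rng.random(len(seq))
    offs = rng.integers(1, 4, size=len(seq))
    bases = "ACGT"
    idx = {b: i for i, b in enumerate(bases)}
    for i, ch in enumerate(out):
        if (i + 1) in frozen or ch not in idx:
            continue
        if u[i] > p_same[i]:
            out[i] = bases[(idx[ch] + offs[i]) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# Default cast


def _bacterial_sepcyss(
    lineage: str = "cladeI",
    loop_deleted: bool = True,
    persulfide_missing: int = 0,
) -> GenePart:
    """Bacterial-type SepCysS: 8-residue deletion adjacent to the 234/235
    junction, usually the 144-147 loop deleted, optionally missing
    persulfide cysteines."""
    indels = [Indel("del", SEPCYSS_INDEL_POINT + 1, 8)]
    if loop_deleted:
        indels.append(Indel("del", SEPCYSS_LOOP_SPAN[0], 4))
    features: dict[int, str] = {}
    for pos in SEPCYSS_PERSULFIDE_SITES[3 - persulfide_missing :]:
        features[pos] = "S"
    return GenePart(
        family="SepCysS", lineage=lineage, indels=tuple(indels), features=features
    )


def _gene(name: str, label: str, *parts: GenePart, **attrs) -> PlantedGene:
    return PlantedGene(name=name, label=label, parts=tuple(parts), attributes=attrs)


def _trna_cys(n37: str) -> PlantedGene:
    return PlantedGene(
        name="tRNA-Cys", label="tRNA-Cys", kind="trna", anticodon="GCA", n37=n37
    )


_TRNA_PYL = PlantedGene(
    name="pylT", label="pylT", kind="trna", anticodon="CTA", n37="A"
)


def default_presets() -> list[GenomePreset]:
    """The eight-genome default cast (see module docstring)."""
    seprs = lambda lin, **kw: GenePart(family="SepRS", lineage=lin, **kw)
    sepcyss = lambda lin: GenePart(family="SepCysS", lineage=lin)
    simple = lambda fam: GenePart(family=fam)
    return [
        GenomePreset(
            name="methanogen_c1", taxon="Euryarchaeota_classI", gc=0.42, depth=50,
            sepcysE_mode="full",
            loci=(
                Locus((
                    _gene("SepCysE", "SepCysE", GenePart(family="SepCysE")),
                    _gene("SepCysS", "SepCysS", sepcyss("cladeI")),
                    _gene("SepRS", "SepRS", seprs("cladeI")),
                )),
                Locus((_gene("SepCysS2", "SepCysS", sepcyss("cladeI")),)),
                Locus((_gene("SPS", "SPS", simple("SPS")),)),
                Locus((_gene("HdrA", "HdrA", simple("HdrA")),)),
                Locus((
                    _gene("VhuD", "VhuD", simple("VhuD")),
                    _gene("VhuU", "VhuU", simple("VhuU")),
                )),
                Locus((_trna_cys("G"),)),
            ),
        ),
        GenomePreset(
            name="methanosarcina_like", taxon="Methanosarcinaceae", gc=0.40, depth=15,
            loci=(
                Locus((
                    _gene("SepRS", "SepRS", seprs("cladeI")),
                    _gene("SepCysS", "SepCysS", sepcyss("cladeII")),
                )),
                Locus((
                    _TRNA_PYL,
                    _gene(
                        "pylS", "pylS",
                        GenePart(family="PylSn"),
                        GenePart(family="PylRS", lineage="Methanosarcinaceae"),
                    ),
                    _gene("pylB", "pylB", simple("pylB")),
                    _gene("pylC", "pylC", simple("pylC")),
                    _gene("pylD", "pylD", simple("pylD")),
                    _gene("mtmB", "mtmB", simple("mtmB")),
                )),
                Locus((_trna_cys("G"),)),
            ),
        ),
        GenomePreset(
            name="bathyarchaeote_BA2", taxon="Bathyarchaeota", gc=0.50, depth=100,
            sepcysE_mode="split_n",
            loci=(
                # the compact operon: tRNA(Cys)-SepCysSn-SepCysS-SepRS
                Locus((
                    _trna_cys("G"),
                    _gene(
                        "SepCysSn", "SepCysSn",
                        GenePart(family="SepCysE", span=(1, 105)),
                    ),
                    _gene(
                        "SepCysS", "SepCysS",
                        GenePart(
                            family="SepCysS", lineage="cladeVII",
                            indels=(Indel("ins", SEPCYSS_INDEL_POINT, 8),),
                        ),
                    ),
                    _gene("SepRS", "SepRS", seprs("cladeII")),
                )),
                Locus((
                    _TRNA_PYL,
                    _gene("pylSc", "pylSc", GenePart(family="PylRS", lineage="novel1")),
                    _gene("mtbB", "mtbB", simple("mtbB")),
                )),
            ),
        ),
        GenomePreset(
            name="parcubacterium_1", taxon="Parcubacteria_DG74", gc=0.34, depth=6,
            loci=(
                Locus((
                    _gene(
                        "SepRS", "SepRS",
                        seprs("cladeIII", features={SEPRS_RES444: "D"}),
                    ),
                    _gene(
                        "SepCysS", "SepCysS",
                        _bacterial_sepcyss(loop_deleted=True, persulfide_missing=2),
                    ),
                )),
                Locus((_trna_cys("A"),)),
                Locus((_trna_cys("G"),)),
            ),
        ),
        GenomePreset(
            name="parcubacterium_2", taxon="Parcubacteria_CG", gc=0.30, depth=40,
            loci=(
                Locus((
                    _gene(
                        "SepRS_dC", "SepRS",
                        seprs(
                            "orphan1",
                            indels=(
                                Indel(
                                    "del",
                                    SEPRS_CTERM_SPAN[0],
                                    SEPRS_CTERM_SPAN[1] - SEPRS_CTERM_SPAN[0] + 1,
                                ),
                            ),
                            features={SEPRS_RES444: "D"},
                        ),
                    ),
                    _trna_cys("A"),
                )),
                Locus((
                    _gene(
                        "SepCysS", "SepCysS",
                        _bacterial_sepcyss(loop_deleted=False, persulfide_missing=0),
                    ),
                )),
            ),
        ),
        GenomePreset(
            name="chloroflexi_1", taxon="Chloroflexi", gc=0.55, depth=30,
            loci=(
                Locus((
                    _gene(
                        "SepRS", "SepRS",
                        seprs("cladeIII", features={SEPRS_RES444: "D"}),
                    ),
                    _gene(
                        "SepCysS", "SepCysS",
                        _bacterial_sepcyss(loop_deleted=True, persulfide_missing=0),
                    ),
                )),
                Locus((
                    _TRNA_PYL,
                    _gene("pylSc", "pylSc", GenePart(family="PylRS", lineage="Bacterial")),
                    _gene("pylSn", "pylSn", GenePart(family="PylSn")),
                    _gene("mttB", "mttB", simple("mttB")),
                )),
            ),
        ),
        GenomePreset(
            name="methanomassiliicoccus_like", taxon="Methanomassiliicoccales",
            gc=0.60, depth=10, sepcysE_mode="fused_N",
            loci=(
                Locus((
                    _TRNA_PYL,
                    _gene(
                        "pylSc", "pylSc",
                        GenePart(family="PylRS", lineage="Methanomassiliicoccales"),
                    ),
                    _gene("mtmB", "mtmB", simple("mtmB")),
                    _gene("mtbB", "mtbB", simple("mtbB")),
                    _gene("mttB", "mttB", simple("mttB")),
                )),
                Locus((
                    _gene(
                        "SepCysSN", "SepCysSN",
                        GenePart(family="SepCysE", span=(1, 105)),
                        GenePart(family="SepCysS", lineage="cladeVI"),
                    ),
                )),
            ),
        ),
        GenomePreset(
            name="ak8_w8a19", taxon="AK8_W8A19", gc=0.52, depth=8,
            sepcysE_mode="full", n_markers=3,
            contaminant_taxon="Bathyarchaeota",
            loci=(
                Locus((
                    _gene("SepCysE", "SepCysE", GenePart(family="SepCysE")),
                    _gene("SepCysS", "SepCysS", sepcyss("cladeI")),
                ), colocate="ak8_main"),
                Locus((_gene("SepRS", "SepRS", seprs("cladeI")),),
                      colocate="ak8_main"),
                Locus((
                    _gene("SPS_n", "SPS", GenePart(family="SPS", span=(1, 190)),
                          fragment="n"),
                    _gene("SPS_c", "SPS", GenePart(family="SPS", span=(160, 340)),
                          fragment="c"),
                )),
                Locus((_gene("HdrA", "HdrA", simple("HdrA")),)),
                Locus((
                    _gene("VhuD", "VhuD", simple("VhuD")),
                    _gene("VhuU", "VhuU", simple("VhuU")),
                )),
                Locus((_trna_cys("G"),)),
            ),
        ),
    ]


def minimal_presets() -> list[GenomePreset]:
    """Two small genomes for quick end-to-end runs."""
    return [
        GenomePreset(
            name="genome_a", taxon="TaxonA", gc=0.35, depth=10, length=80_000,
            loci=(
                Locus((
                    _gene("SepRS", "SepRS", GenePart(family="SepRS", lineage="cladeI")),
                    _gene("SepCysS", "SepCysS",
                          GenePart(family="SepCysS", lineage="cladeI")),
                )),
                Locus((_trna_cys("G"),)),
            ),
        ),
        GenomePreset(
            name="genome_b", taxon="TaxonB", gc=0.60, depth=60, length=80_000,
            loci=(
                Locus((
                    _TRNA_PYL,
                    _gene(
                        "pylS", "pylS",
                        GenePart(family="PylSn"),
                        GenePart(family="PylRS", lineage="Methanosarcinaceae"),
                    ),
                    _gene("mtmB", "mtmB", simple_part("mtmB")),
                )),
            ),
        ),
    ]


def simple_part(fam: str) -> GenePart:
    return GenePart(family=fam)


# ---------------------------------------------------------------------------
# Feature-truth bookkeeping


def _protein_feature_truth(pid: str, gene: PlantedGene) -> FeatureTruth | None:
    families = [p.family for p in gene.parts]
    if "SepRS" in families:
        part = gene.parts[families.index("SepRS")]
        deleted_444 = any(
            i.kind == "del"
            and i.position <= SEPRS_RES444 <= i.position + i.length - 1
            for i in part.indels
        )
        res444 = None if deleted_444 else part.features.get(SEPRS_RES444, "I")
        cls = (
            None if res444 is None
            else "hydrophilic" if res444 in HYDROPHILIC
            else "hydrophobic" if res444 in HYDROPHOBIC
            else "other"
        )
        span = SEPRS_CTERM_SPAN
        truncated = any(
            i.kind == "del" and i.position <= span[0] and
            i.position + i.length - 1 >= span[1]
            for i in part.indels
        )
        return FeatureTruth(
            protein_id=pid, family="SepRS", res444=res444, res444_class=cls,
            truncation="delta_C" if truncated else "full",
        )
    if "SepCysS" in families:
        part = gene.parts[families.index("SepCysS")]
        loop_deleted = any(
            i.kind == "del"
            and i.position <= SEPCYSS_LOOP_SPAN[0]
            and i.position + i.length - 1 >= SEPCYSS_LOOP_SPAN[1]
            for i in part.indels
        )
        indel = 0
        for i in part.indels:
            if i.kind == "ins" and i.position == SEPCYSS_INDEL_POINT:
                indel = i.length
            elif i.kind == "del" and (
                i.position <= SEPCYSS_INDEL_POINT + 1 <= i.position + i.length - 1
                or i.position <= SEPCYSS_INDEL_POINT <= i.position + i.length - 1
            ):
                indel = -i.length
        persulfide = sum(
            1
            for pos in SEPCYSS_PERSULFIDE_SITES
            if part.features.get(pos, "C") == "C"
        )
        return FeatureTruth(
            protein_id=pid, family="SepCysS",
            loop_present=not loop_deleted, indel_234_235=indel,
            persulfide_count=persulfide, plp_conserved=True,
        )
    return None


# ---------------------------------------------------------------------------
# Generation


def default_models(rng: np.random.Generator) -> dict[str, FamilyModel]:
    return make_family_models(default_family_configs(), rng)


def _trna_template(rng: np.random.Generator) -> str:
    return random_dna(72, 0.55, rng)


def _make_protein(
    gene: PlantedGene, models: dict[str, FamilyModel], rng: np.random.Generator
) -> str:
    chunks = []
    for part in gene.parts:
        model = models[part.family]
        seq = sample_member(
            model, part.lineage, rng,
            plan=MemberPlan(indels=part.indels, features=part.features),
        )
        if part.span is not None:
            lo, hi = part.span
            seq = seq[lo - 1 : hi]
        chunks.append(seq)
    return "".join(chunks)


def generate_metagenome(
    presets: list[GenomePreset],
    models: dict[str, FamilyModel] | None = None,
    rng: np.random.Generator | None = None,
    depth_sigma: float = 0.1,
) -> SyntheticMetagenome:
    """Generate contigs, depth table, annotations, proteins, tRNAs and truth.

    Deterministic under a fixed RNG: identical presets + models + generator
    state yield byte-identical outputs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if models is None:
        models = default_models(rng)
    if not presets:
        raise ValueError("at least one genome preset is required")

    trna_templates = {
        "tRNA-Cys": _trna_template(rng),
        "pylT": _trna_template(rng),
    }

    truth = GroundTruth()
    contigs: list[SeqRecord] = []
    depth_rows: list[DepthRow] = []
    gff: list[FeatureRow] = []
    proteins: list[SeqRecord] = []
    trnas: list[SeqRecord] = []
    counters = {"ctg": 0, "g": 0, "p": 0, "t": 0}

    def next_id(kind: str) -> str:
        counters[kind] += 1
        return f"{kind}{counters[kind]:04d}"

    for preset in presets:
        truth.taxa[preset.name] = preset.taxon
        _generate_genome(
            preset, models, trna_templates, rng, depth_sigma,
            truth, contigs, depth_rows, gff, proteins, trnas, next_id,
        )
        if preset.contaminant_taxon:
            _generate_contaminant(
                preset, models, rng, depth_sigma,
                truth, contigs, depth_rows, gff, proteins, next_id,
            )

    references = {
        fam: SeqRecord(id=f"{fam}_ref", residues=model.reference)
        for fam, model in models.items()
    }
    return SyntheticMetagenome(
        contigs=contigs, depth=depth_rows, annotations=gff,
        proteins=proteins, trnas=trnas, truth=truth, references=references,
    )


def _contig_lengths(preset: GenomePreset, rng: np.random.Generator) -> list[int]:
    lengths: list[int] = []
    total = 0
    while total < preset.length:
        ln = preset.contig_min + int(
            rng.exponential(max(1, preset.contig_mean - preset.contig_min))
        )
        if total + ln > preset.length:
            ln = max(preset.contig_min, preset.length - total)
        lengths.append(ln)
        total += ln
    return lengths


def _generate_genome(
    preset, models, trna_templates, rng, depth_sigma,
    truth, contigs, depth_rows, gff, proteins, trnas, next_id,
) -> None:
    # 1. realize gene sequences and nucleotide blocks per locus
    loci = list(preset.loci)
    # marker genes get their own loci so they land on distinct contigs
    for _ in range(preset.n_markers):
        loci.append(
            Locus((PlantedGene(
                name="marker", label="marker", parts=(GenePart(family="marker"),),
                attributes={"taxon": preset.taxon},
            ),))
        )

    @dataclass
    class _Block:
        locus: Locus
        nt: str
        gene_layout: list  # (gene, protein_or_none, trna_seq_or_none, rel_start, rel_end)

    blocks: list[_Block] = []
    for locus in loci:
        parts_nt: list[str] = []
        layout = []
        offset = 0
        for gi, gene in enumerate(locus.genes):
            if gi > 0:
                gap = int(rng.integers(30, 121))
                parts_nt.append(random_dna(gap, preset.gc, rng))
                offset += gap
            if gene.kind == "trna":
                seq = evolve_dna(
                    trna_templates[gene.label if gene.label in trna_templates
                                   else "tRNA-Cys"],
                    0.05, rng, frozen={34, 35, 36, 37},
                )
                seq = seq[:33] + gene.anticodon + gene.n37 + seq[37:]
                nt = seq
                layout.append((gene, None, seq, offset + 1, offset + len(nt)))
            else:
                protein = _make_protein(gene, models, rng)
                nt = back_translate(protein, preset.gc, rng)
                layout.append((gene, protein, None, offset + 1, offset + len(nt)))
            parts_nt.append(nt)
            offset += len(nt)
        blocks.append(_Block(locus=locus, nt="".join(parts_nt), gene_layout=layout))

    # 2. contig scaffold
    lengths = _contig_lengths(preset, rng)
    contig_ids = [next_id("ctg") for _ in lengths]
    for cid in contig_ids:
        truth.contig_genome[cid] = preset.name

    # 3. assign blocks (grouped by colocate key) to contigs, longest-first
    groups: dict[str, list[_Block]] = {}
    for i, block in enumerate(blocks):
        key = block.locus.colocate or f"__solo_{i}"
        groups.setdefault(key, []).append(block)
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    assignments: dict[int, list[_Block]] = {}
    used: set[int] = set()
    for key, blist in groups.items():
        need = sum(len(b.nt) for b in blist) + 600 * (len(blist) + 1)
        chosen = None
        for ci in order:
            if ci in used:
                continue
            if lengths[ci] >= need:
                chosen = ci
                break
        if chosen is None:
            raise ValueError(
                f"{preset.name}: no contig long enough for locus group "
                f"{key!r} ({need} bp needed)"
            )
        used.add(chosen)
        assignments[chosen] = blist

    # 4. emit contigs with embedded blocks
    for ci, ln in enumerate(lengths):
        cid = contig_ids[ci]
        blist = assignments.get(ci, [])
        seq_parts: list[str] = []
        pos = 0
        for block in blist:
            lead = int(rng.integers(400, 700))
            seq_parts.append(random_dna(lead, preset.gc, rng))
            pos += lead
            strand = block.locus.strand
            block_nt = block.nt if strand == "+" else reverse_complement(block.nt)
            block_start = pos + 1
            seq_parts.append(block_nt)
            pos += len(block_nt)
            for gene, protein, trna_seq, rel_s, rel_e in block.gene_layout:
                if strand == "+":
                    g_start = block_start + rel_s - 1
                    g_end = block_start + rel_e - 1
                else:
                    g_start = block_start + len(block_nt) - rel_e
                    g_end = block_start + len(block_nt) - rel_s
                gid = next_id("g")
                attrs = {"ID": gid, "family": gene.label, "name": gene.name}
                if gene.kind == "trna":
                    tid = next_id("t")
                    attrs["trna_id"] = tid
                    attrs["anticodon"] = gene.anticodon
                    attrs["anticodon_start"] = "34"
                    gff.append(FeatureRow(
                        contig_id=cid, source="sepmine_sim", feature_type="tRNA",
                        start=g_start, end=g_end, strand=strand, attributes=attrs,
                    ))
                    trnas.append(SeqRecord(id=tid, residues=trna_seq))
                    isotype = "Cys" if gene.anticodon == "GCA" else (
                        "Pyl" if gene.anticodon == "CTA" else "other"
                    )
                    truth.trnas[tid] = TrnaTruth(
                        trna_id=tid, anticodon=gene.anticodon, n37=gene.n37,
                        isotype=isotype, genome=preset.name,
                    )
                    truth.genes[gid] = GeneTruth(
                        gene_id=gid, protein_id=None, family=gene.label,
                        clade="", genome=preset.name, contig=cid,
                    )
                else:
                    pid = next_id("p")
                    attrs["protein_id"] = pid
                    clade = "+".join(p.lineage for p in gene.parts)
                    attrs["clade_truth"] = clade
                    attrs.update(gene.attributes)
                    gff.append(FeatureRow(
                        contig_id=cid, source="sepmine_sim", feature_type="gene",
                        start=g_start, end=g_end, strand=strand, attributes=attrs,
                    ))
                    proteins.append(SeqRecord(id=pid, residues=protein))
                    truth.genes[gid] = GeneTruth(
                        gene_id=gid, protein_id=pid, family=gene.label,
                        clade=clade, genome=preset.name, contig=cid,
                    )
                    ft = _protein_feature_truth(pid, gene)
                    if ft is not None:
                        truth.features[pid] = ft
        tail = ln - pos
        if tail < 0:
            raise ValueError(
                f"{preset.name}: contig {cid} shorter than its planted loci"
            )
        seq_parts.append(random_dna(tail, preset.gc, rng))
        contigs.append(SeqRecord(id=cid, residues="".join(seq_parts)))
        noise = float(np.exp(rng.normal(0.0, depth_sigma))) if depth_sigma > 0 else 1.0
        depth_rows.append(DepthRow(contig_id=cid, mean_depth=preset.depth * noise))

    _record_trait_and_pairing_truth(preset, truth)


def _generate_contaminant(
    preset, models, rng, depth_sigma,
    truth, contigs, depth_rows, gff, proteins, next_id,
) -> None:
    """One foreign contig that co-bins with its host (same GC/depth) but
    carries a marker gene of a different taxon; the purge step should drop it."""
    genome = f"{preset.name}_contaminant"
    truth.taxa[genome] = preset.contaminant_taxon
    cid = next_id("ctg")
    truth.contig_genome[cid] = genome
    marker = _make_protein(
        PlantedGene(name="marker", label="marker",
                    parts=(GenePart(family="marker"),)),
        models, rng,
    )
    nt = back_translate(marker, preset.gc, rng)
    lead = int(rng.integers(400, 700))
    total = max(preset.contig_min, lead + len(nt) + 1200)
    seq = (
        random_dna(lead, preset.gc, rng) + nt
        + random_dna(total - lead - len(nt), preset.gc, rng)
    )
    gid, pid = next_id("g"), next_id("p")
    gff.append(FeatureRow(
        contig_id=cid, source="sepmine_sim", feature_type="gene",
        start=lead + 1, end=lead + len(nt), strand="+",
        attributes={
            "ID": gid, "family": "marker", "name": "marker",
            "protein_id": pid, "clade_truth": "main",
            "taxon": preset.contaminant_taxon,
        },
    ))
    proteins.append(SeqRecord(id=pid, residues=marker))
    truth.genes[gid] = GeneTruth(
        gene_id=gid, protein_id=pid, family="marker", clade="main",
        genome=genome, contig=cid,
    )
    contigs.append(SeqRecord(id=cid, residues=seq))
    noise = float(np.exp(rng.normal(0.0, depth_sigma))) if depth_sigma > 0 else 1.0
    depth_rows.append(DepthRow(contig_id=cid, mean_depth=preset.depth * noise))


def _record_trait_and_pairing_truth(preset: GenomePreset, truth: GroundTruth) -> None:
    genes = [g for g in truth.genes.values() if g.genome == preset.name]
    labels = [g.family for g in genes]
    seprs = [g for g in genes if g.family == "SepRS"]
    sepcyss = [g for g in genes if g.family in ("SepCysS", "SepCysSN")]

    pyl_acc = frozenset(
        lab for lab in labels
        if lab in ("pylT", "pylB", "pylC", "pylD", "mtmB", "mtbB", "mttB")
    )
    if "pylS" in labels:
        arch = "single_pylS"
    elif "pylSc" in labels and "pylSn" in labels:
        arch = "split_pylSn_pylSc"
    elif "pylSc" in labels:
        arch = "pylSc_only"
    else:
        arch = "none"
    sec = frozenset(lab for lab in labels if lab in ("SPS", "HdrA", "VhuD", "VhuU"))
    sps_split = sum(1 for lab in labels if lab == "SPS") >= 2

    truncated = any(
        truth.features.get(g.protein_id) is not None
        and truth.features[g.protein_id].truncation == "delta_C"
        for g in seprs
    )
    truth.traits[preset.name] = TraitTruth(
        genome=preset.name,
        has_seprs=bool(seprs),
        has_sepcyss=bool(sepcyss),
        sepcysE_status=preset.sepcysE_mode,
        pyl_architecture=arch,
        pyl_accessories=pyl_acc,
        sec_families=sec,
        sps_split=sps_split,
        sepcyss_copies=len(sepcyss),
        seprs_truncated=truncated,
    )

    partner_ids = tuple(sorted(g.gene_id for g in sepcyss))
    evidence = _expected_evidence(preset)
    for g in seprs:
        truth.pairings.append(PairingTruth(
            seprs_gene=g.gene_id, partners=partner_ids,
            genome=preset.name, evidence=evidence,
        ))
    if not seprs and sepcyss:
        for g in sepcyss:
            truth.pairings.append(PairingTruth(
                seprs_gene="", partners=(g.gene_id,),
                genome=preset.name, evidence="unpaired",
            ))


def _expected_evidence(preset: GenomePreset) -> str:
    """Strongest expected pairing-evidence level, over all locus pairs."""
    seprs_loci = []
    sepcyss_loci = []
    for li, locus in enumerate(preset.loci):
        fams = {g.label for g in locus.genes}
        if "SepRS" in fams:
            seprs_loci.append((li, locus))
        if fams & {"SepCysS", "SepCysSN"}:
            sepcyss_loci.append((li, locus))
    if not seprs_loci or not sepcyss_loci:
        return "unpaired"
    best = "bin"
    for si, s_locus in seprs_loci:
        for ci, c_locus in sepcyss_loci:
            if si == ci:
                return "operon"
            if (
                s_locus.colocate is not None
                and s_locus.colocate == c_locus.colocate
            ):
                best = "contig"
    return best
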