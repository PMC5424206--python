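# Methods

This note documents the models, rules and numerical choices behind
`sepmine`, and what the synthetic benchmark does and does not establish.

## The inference problem

The pipeline targets the discovery workflow for RNA-dependent cysteine
biosynthesis systems in metagenomes. Its stages, and the units they operate
on, are:

1. collect SepRS/SepCysS/SepCysE homologs from a protein database by
   iterative similarity search (sequence level);
2. attribute metagenomic contigs to genomes by GC content and read depth,
   removing contaminants by marker-gene taxonomy (contig level);
3. pair each SepRS with its SepCysS partner(s) by genomic context
   (gene level);
4. delineate clades and flag orphan/novel lineages (family level);
5. read off diagnostic sequence features against structural reference
   coordinates (residue level);
6. tabulate co-occurrence with Pyl- and Sec-utilization traits (bin level).

## Homolog search

Local alignment is exact Smith–Waterman with affine gaps (BLOSUM62, gap
open 11, extend 1; the first gapped column costs the open penalty, each
further column the extension). "Percent similarity" is the BLAST-style
positives fraction: the share of alignment columns whose residue pair has a
strictly positive substitution score, with gap columns kept in the
denominator. This mirrors the "positives" percentage a BLASTp report
prints; the package defines it over the columns of the optimal local
alignment (rather than over full sequence length), which keeps the
statistic meaningful for domain-sized hits.

The iterative search retains database entries at ≥ 40% similarity to any
active query, with a query-coverage gate (default 0.6) added so that
single-domain hits cannot chain the search into unrelated families.
Retained sequences are grouped by single linkage at 60%
similarity (a package default) and one medoid representative per group — maximum mean
similarity to its own group, ties broken lexicographically — joins the
query pool for the next round, up to 10 rounds or until nothing new is
found.

## Contig binning

Contigs of ≥ 2,000 bp are clustered by single linkage under two hard gates:
|ΔGC| ≤ 0.025 (GC computed over unambiguous bases only) and
|log2(depth_a/depth_b)| ≤ 0.5. Depth is compared on a log scale because
coverage noise is multiplicative. Hard gates were chosen over model-based
clustering deliberately: manual metagenome curation works in exactly these
threshold-like terms, and hard gates are auditable. The tolerances are
package defaults calibrated on the synthetic presets. A zero-depth
contig receives a pseudo-depth of 0.01 with a warning.

Contaminant removal generalizes the ad hoc cleanups of individual foreign
lineages into one rule: within a bin, the modal marker-gene taxon defines
the majority; marker-bearing contigs of any other taxon are removed;
unlabeled contigs are kept; a tie removes nothing and flags the bin
low-confidence ("uncertain" in the trait table).

## Gene pairing

Operons are maximal same-contig, same-strand gene runs with successive
intergenic gaps ≤ 150 nt (a package default; prokaryotic operonic spacers
are typically tens of nucleotides); overlapping same-strand genes stay in
one operon with a warning. Cross-strand operons are not called: the compact
RNA-dependent-cysteine operon architecture this rule targets is
co-oriented, and cross-strand calls would be unfalsifiable here.

Pairing walks the hierarchy *same operon > same contig > same bin*. The
reported partner set is **all** SepCysS genes in the SepRS's bin (fused
SepCysSN included), with the evidence field recording the strongest
relation among them. This supports genomes that carry one or two SepCysS
copies: a second SepCysS elsewhere in the bin is a partner even when
the first is operonic. Pairing never crosses bins. SepRS without partners,
and SepCysS in bins without SepRS, are reported unpaired.

## Alignment and phylogenetics

Progressive multiple alignment: 3-mer count distances feed a UPGMA guide
tree (scipy average linkage); profiles are aligned along it by global
affine (Gotoh) dynamic programming on expected-score matrices, with gap
columns carrying no substitution mass. For two sequences this reduces
exactly to the optimal global pairwise alignment, which the tests verify
against an independent aligner.

Distances: per pair, p = mismatch fraction over shared non-gap columns,
corrected as d = −(19/20)·ln(1 − (20/19)p) (the 20-state uniform-model
correction), capped at 5.0 at saturation or when no columns are shared.

Maximum likelihood uses the JTT substitution model with uniform rates. The
exchangeabilities and equilibrium frequencies are the published 1992
counts-derived constants, embedded in `sepmine.jtt` and eigendecomposed
once for fast transition matrices. Likelihoods are computed by Felsenstein
pruning with per-site rescaling; gaps and X are missing data (all-ones
partial likelihoods), so every alignment column contributes — gapped
columns are retained as missing data rather than deleted, and complete
deletion is not implemented. Branch lengths are optimized
one-dimensionally (bounded Brent, tolerance 1e-6, bounds [1e-9, 10]),
sweeping all edges until the log-likelihood gain per sweep falls below the
tolerance. Topology search is nearest-neighbor interchange, accepting moves
that improve log-likelihood by ≥ 1e-6; candidate moves are scored with a
full branch-length pass on trees of ≤ 6 leaves and by re-optimizing the
focal branch only on larger trees (a cost/accuracy trade-off; the 4-taxon
oracle test runs in the full-reopt regime). Bootstrap support (default 100
replicates) resamples alignment columns and runs the full
distance–NJ–ML pipeline per replicate; supports are the percentage of
replicates containing each internal bipartition of the full-data tree.

Clade delineation is deliberately operational rather than visual:
single-linkage clusters of pairwise local-alignment percent similarity at
50%, clusters of ≥ 3 members are major clades, everything else is an
orphan. With `min_clade_size = 3`, singletons and pairs count as orphan
lineages. The ML tree with supports is emitted alongside for inspection.
Assignment to labeled reference clades takes the label of the most similar
reference if that similarity is ≥ 50%, else "novel"; ties break by higher
similarity then lexicographic label.

Known caveat: percent similarity is formally a function of the chosen
optimal alignment; when several co-optimal local alignments exist the
aligner's first, deterministic traceback is used, so similarity is
guaranteed symmetric at the score level and in the cached pairwise matrix
(which canonicalizes pair order), but could in degenerate tie cases differ
slightly between orientations.

## Feature rules

All residue-level rules are evaluated through a reference map: the non-gap
columns of a designated reference row of an MSA are numbered consecutively
from 1, and rule positions refer to that numbering. The synthetic
references adopt the nominal coordinates of the structural reference
proteins (SepRS 444; SepCysS 144–147, 234/235, PLP site, persulfide
cysteines) so that rules written against real coordinates read identically
over synthetic data. The specific PLP and persulfide positions are
rule-file inputs (`RuleSet`, YAML-serializable) with generator-defined
defaults; an analysis of real proteins should supply curated structural
coordinates in the rule file.

* **Loop 144–147**: absent iff all spanned columns are gaps in the member.
* **Indel 234/235**: signed net length. Insertions are member residues in
  columns strictly between the reference columns of 234 and 235; deletions
  are the maximal member-gap run touching the junction, counting only
  columns where the reference has a residue (so all-gap columns elsewhere
  in the MSA cannot perturb the value — an invariant under test).
* **Residue 444**: hydrophobic {A,I,L,M,F,V,W,Y}, hydrophilic
  {D,E,N,Q,K,R,S,T,H}, otherwise "other"; a gap yields no call.
* **PLP conservation**: member equals the reference residue at every PLP
  position. **Persulfide count**: cysteines among the three positions.
* **SepRS-ΔC**: local alignment to the reference must cover ≥ 60% of the
  catalytic span; `delta_C` iff it covers < 50% of the C-terminal
  anticodon-binding span. The 50/60% gates are conservative span-coverage
  choices of this package.
* **SepCysE homologs**: `full` = N-domain match, ≥ 2× the domain length, no
  SepCysS core; `fused_N` = N-domain match within the first 120 residues
  with a SepCysS core downstream (SepCysSN); `split_n` = a short (< 150 aa)
  N-domain-only gene immediately preceding a SepCysS gene in its operon
  (SepCysSn). The 120/150/2× constants are conservative gates, exposed as
  keyword arguments.
* **tRNA N37**: the base immediately 3′ of the annotated anticodon;
  anticodon positions come from the annotation (no secondary-structure
  folding is attempted), and a missing annotation or an anticodon at the
  sequence end yields a warned no-call.

## Trait co-occurrence

Trait calls are bin-level, the unit of attribution. Pyl architecture
follows from which PylRS forms are present (fused pylS; pylSn + pylSc;
pylSc alone); contradictory bins are reported as single_pylS with a warning
note. A "clustered" flag is set when a PylRS gene shares an operon with ≥ 2
accessories. The Sec trait is homology-level only: presence of the four
selenoprotein families, with split SPS called when ≥ 2 sub-full-length
fragments (each < 60% reference coverage) jointly cover ≥ 80% of the SPS
reference. No statistical association test is computed — co-occurrence is
reported descriptively, matching the scope of the observation it
reproduces.

## The synthetic benchmark

### Substitution process

Protein families evolve under a 20-state uniform process: Poisson(d)
substitution events per site, each replacing the residue uniformly among
the 19 others, giving the exact expected identity
1/20 + (19/20)·exp(−(20/19)d) at distance d (verified by simulation in the
tests). The generator deliberately does **not** use JTT: a simple process
keeps the closed form and avoids circularity with the JTT-based inference.

### Clade geometry and calibration

Each family has a random root; lineage seeds sit at a common radius from
the root (a pair's similarity is set by the path-length sum, so a common
radius is the only geometry in which all pairs can share one similarity
band); members are drawn at 0.11 substitutions/site from their seed.
Orphan/novel lineages are singletons or pairs at the same radius — their
status comes from size, not extra divergence.

The generator does not attempt to match the divergence levels of any real
family; its one quantitative anchor is the search's 40% retention
threshold. The default between-lineage distance (1.14 substitutions/site
path length) was calibrated once so that cross-clade percent similarity
straddles that threshold while staying below the 50% clade-linkage
threshold, with within-clade similarity near 84%. Because single linkage is sensitive
to a single stray pair, the sampler validates generated sets against
colinear (alignment-free) similarity bands — seed pairs capped at 47%,
cross-lineage member pairs at 47%, within-clade pairs at ≥ 62%, and every
lineage reachable at ≥ 41% from at least two other lineages' medoids (the
condition for multi-round query expansion to bridge into it) — re-drawing
offending seeds or members deterministically within the RNG stream. Seeds
that read too similar are walked outward by small evolution steps, which
lowers all their pairwise similarities together. Conserved anchors (~6% of
sites, plus feature sites, termini, and the flanks of the loop and indel
regions) stabilize local alignments and pin planned indels where the
feature rules look for them; in particular, positions 230–238 anchor the
junction for insertion carriers while 243–247 re-anchor members whose
residues 235–242 are deleted.

### Metagenome presets

The default cast is eight genomes (about 0.2 Mb each, contigs ≥ 5 kb, mean
12 kb — the low end of a 0.2–1 Mb per-genome scale, chosen so the full
pipeline runs in seconds) emulating the key natural configurations of these
systems: a
class I methanogen-like genome (full SepCysE, two SepCysS copies, all four
selenoproteins, G37 tRNA-Cys); a Methanosarcinaceae-like genome (SepRS +
single-pylS cluster with pylT/pylBCD/mtmB); a Bathyarchaeota-like genome
with the compact tRNA(Cys)–SepCysSn–SepCysS–SepRS operon (+8 indel
SepCysS) and a novel pylSc lineage; two Parcubacteria-like genomes
(bacterial feature set: Asp444, −8 indel, missing loop or missing
persulfide cysteines, A37 tRNA-Cys; one carries SepRS-ΔC paired at bin
level); a Chloroflexi-like genome (bacterial SepRS-SepCysS operon plus a
split pylSn/pylSc system); a Methanomassiliicoccales-like genome (pylSc
only, fused SepCysSN, no SepRS — exercising the unpaired-SepCysS path); and
an AK8/W8A-19-like genome (full SepCysE in operon with SepCysS, SepRS on
the same contig, split SPS, and one planted contaminant contig of a
foreign marker taxon at matching GC/depth, which the purge step must
remove).

GC/depth targets are spaced so that every genome pair is separated by at
least one gate with margin against the generator's own noise (lognormal
depth, σ = 0.1; binomial GC over ≥ 5 kb contigs): either ΔGC ≥ 0.05 or a
depth ratio ≥ 2.5. Proteins are back-translated with synonymous codons
weighted toward the genome GC; intergenic DNA is i.i.d. at the genome GC;
per-contig depth is the genome target times lognormal noise. All outputs
are byte-identical under a fixed seed.

### What the benchmark does not show

The generator plants star-shaped clades with i.i.d. sites, no rate
heterogeneity, no domain shuffling beyond the planned indels and fusions,
no horizontal transfer, no sequencing or assembly error, and no gene
prediction (proteins are emitted directly, mirroring reliance on database
protein predictions). Passing recovery tests therefore demonstrates that
the inference machinery is correct under its stated assumptions — exact
alignment scores, correct likelihoods, correct rule evaluation, correct
bookkeeping — not that the thresholds would transfer unchanged to real
metagenomes, where divergence is heterogeneous and binning signals are far
noisier. The binning tolerances and the clade/grouping thresholds in
particular are calibrated on the synthetic presets only.

## Degenerate inputs and determinism

Empty alignments (no positively scoring local pair) have score 0 and no
percent similarity; saturated distances cap at 5.0; zero-depth contigs get
a pseudo-depth; marker-taxon ties purge nothing; unknown strands, start >
end coordinates, duplicate ids, empty sequences and non-standard residues
are rejected with messages naming the offender. Every stochastic component
takes an explicit seed or RNG; all set/dict iterations that reach output
are ordered, so every subcommand is byte-identical across runs with the
same seed (under test).
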