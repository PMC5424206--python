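"""Protein-family models with planted clade structure.

Synthetic families (SepRS, SepCysS, SepCysE, PylRS, selenoprotein markers,
Pyl-cluster accessories) are generated by evolving a random root sequence
down a star-like lineage tree: each clade has a seed drawn at a controlled
distance from the root, members are drawn at a small distance from their
clade seed, and orphan/novel lineages are single deep branches.  Planned
indels (the 8-residue 234/235 indel, the 144-147 loop deletion, domain
truncations) and feature residues (position 444, PLP-site residues,
persulfide cysteines) are applied on top in reference coordinates.

Substitution process
--------------------
Sites evolve independently under a 20-state uniform ("Jukes-Cantor-like")
process: the number of substitution events per site is Poisson(d) where d is
the branch length in expected substitutions/site, and each event replaces
the residue with one of the 19 others uniformly.  The expected fractional
identity between a sequence and its descendant at total distance d is then

    1/20 + (19/20) * exp(-(20/19) * d)

exactly, which the test-suite checks by simulation.  A deliberately simple
process (rather than JTT) keeps this closed form and avoids circularity with
the JTT-based inference engine.

Similarity bands
----------------
Clade divergences are calibrated so that BLAST-style percent similarity
(positive-scoring column fraction under BLOSUM62) straddles the search
retention threshold: within-clade pairs sit far above the 60% grouping
threshold, while cross-clade and orphan pairs land between the 40%
retention threshold and the 50% clade-linkage threshold.  Because single
linkage is sensitive to a single stray pair, the sampler *validates* the
generated set against these bands (computed column-wise on the colinear,
pre-indel sequences, which is cheap) and re-draws offending seeds or
members; the re-draws are part of the deterministic RNG stream, so output
is still byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

from ..io_formats import SeqRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}

# BLOSUM62 positive-pair indicator over the 20x20 residue space,
# precomputed once for the colinear similarity screen.
_B62 = substitution_matrices.load("BLOSUM62")
_POSITIVE = np.array(
    [[_B62[a, b] > 0 for b in AA] for a in AA], dtype=bool
)

# Colinear percent-similarity bands enforced at generation time (see module
# docstring).  Values are percentages of positively scoring columns.
SEED_CROSS_BAND = (43.0, 47.0)   # clade-seed pairs
MEMBER_CROSS_MAX = 47.0          # any cross-lineage member pair
MEMBER_WITHIN_MIN = 62.0         # any within-clade member pair
REACH_MIN = 41.0                 # best bridge from a clade medoid into each lineage
_MAX_TRIES = 2000


class FamilyConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Indel:
    """A planned indel in reference coordinates (1-based).

    ``del``: remove ``length`` residues starting at ``position``.
    ``ins``: insert ``length`` random residues immediately after ``position``.
    """

    kind: str
    position: int
    length: int

    def __post_init__(self):
        if self.kind not in ("del", "ins"):
            raise FamilyConfigError(f"unknown indel kind {self.kind!r}")
        if self.position < 1 or self.length < 1:
            raise FamilyConfigError("indel position/length must be >= 1")


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _decode(idx: np.ndarray) -> str:
    return "".join(AA[i] for i in idx)


def evolve_sequence(
    seed: str,
    distance: float,
    rng: np.random.Generator,
    indels: tuple[Indel, ...] = (),
    features: dict[int, str] | None = None,
) -> str:
    """Evolve ``seed`` by ``distance`` expected substitutions/site.

    Substitutions are applied first (Poisson(d) events/site, uniform
    replacement among the 19 other residues), then planned indels in
    reference coordinates, then feature-plan residues are re-imposed last so
    planted diagnostic residues are never mutated away.  Feature positions
    falling inside a deleted region are dropped.
    """
    if distance < 0:
        raise FamilyConfigError("distance must be >= 0")
    idx = _encode(seed)
    n = len(idx)
    if distance > 0:
        k = rng.poisson(distance, size=n)
        # exact final-state law of k uniform-over-other-19 replacement steps
        p_same = 1 / 20 + (19 / 20) * (-1 / 19.0) ** k
        u = rng.random(n)
        offsets = rng.integers(1, 20, size=n)
        changed = u > p_same
        idx = np.where(changed, (idx + offsets) % 20, idx)

    # reference position (1-based) -> current 0-based index, through indels
    coord = {pos: pos - 1 for pos in range(1, n + 1)}
    seq = list(_decode(idx))
    for indel in sorted(indels, key=lambda i: i.position, reverse=True):
        if indel.kind == "del":
            lo, hi = indel.position, indel.position + indel.length - 1
            if hi > n:
                raise FamilyConfigError(
                    f"deletion {lo}..{hi} outside sequence of length {n}"
                )
            del seq[lo - 1 : hi]
            for pos in range(lo, hi + 1):
                coord[pos] = None
            for pos in range(hi + 1, n + 1):
                if coord[pos] is not None:
                    coord[pos] -= indel.length
        else:
            if indel.position > n:
                raise FamilyConfigError(
                    f"insertion point {indel.position} outside sequence of length {n}"
                )
            insert = random_protein(indel.length, rng)
            at = coord[indel.position]
            if at is None:
                raise FamilyConfigError("insertion anchored inside a deleted region")
            seq[at + 1 : at + 1] = list(insert)
            for pos in range(indel.position + 1, n + 1):
                if coord[pos] is not None:
                    coord[pos] += indel.length

    if features:
        for pos, residue in features.items():
            if pos < 1 or pos > n:
                raise FamilyConfigError(f"feature position {pos} outside reference")
            at = coord.get(pos)
            if at is not None:
                seq[at] = residue
    return "".join(seq)


def colinear_positives(a: str, b: str) -> float:
    """Percent of positions with a positive BLOSUM62 score, ungapped.

    Cheap stand-in for local-alignment percent similarity on colinear
    (equal-length, pre-indel) sequences; used by the generation-time screen.
    """
    if len(a) != len(b):
        raise ValueError("colinear comparison requires equal lengths")
    return 100.0 * float(np.mean(_POSITIVE[_encode(a), _encode(b)]))


# ---------------------------------------------------------------------------
# Family models


@dataclass(frozen=True)
class LineageSpec:
    """One lineage of a family: a major clade or a singleton orphan/novel line."""

    label: str
    is_major: bool = True


@dataclass(frozen=True)
class FamilyConfig:
    family: str
    length: int
    lineages: tuple[LineageSpec, ...]
    within_distance: float = 0.11      # clade seed -> member
    between_distance: float = 1.14     # path distance between lineage seeds
    anchor_fraction: float = 0.06
    anchors: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lineages:
            raise FamilyConfigError(f"{self.family}: at least one lineage required")
        if not (0 < self.within_distance < 3 and 0 < self.between_distance < 3):
            raise FamilyConfigError(f"{self.family}: distances must lie in (0, 3)")
        if self.within_distance >= self.between_distance:
            raise FamilyConfigError(
                f"{self.family}: within-clade distance must be smaller than "
                "between-clade distance"
            )


@dataclass
class FamilyModel:
    """A realized family: root, per-lineage seeds, anchor plan, distances."""

    family: str
    length: int
    root: str
    seeds: dict[str, str]                # lineage label -> seed sequence
    major: dict[str, bool]
    within_distance: float
    anchors: dict[int, str]

    @property
    def reference(self) -> str:
        """The family reference sequence (the root with anchors imposed)."""
        seq = list(self.root)
        for pos, res in self.anchors.items():
            seq[pos - 1] = res
        return "".join(seq)


def _draw_anchors(
    length: int, root: str, fraction: float, fixed: dict[int, str | None],
    rng: np.random.Generator,
) -> dict[int, str]:
    """Anchor plan: fixed feature anchors plus evenly spread conserved sites.

    A ``None`` in ``fixed`` anchors the root residue at that position.  The
    first and last three positions are always anchored so that local
    alignments of family members do not trim the termini, which keeps
    query-coverage and percent-similarity statistics stable.
    """
    anchors = {
        pos: (res if res is not None else root[pos - 1])
        for pos, res in fixed.items()
    }
    for pos in (1, 2, 3, length - 2, length - 1, length):
        anchors.setdefault(pos, root[pos - 1])
    n_extra = max(0, int(round(fraction * length)) - len(anchors))
    free = [p for p in range(1, length + 1) if p not in anchors]
    chosen = rng.choice(len(free), size=min(n_extra, len(free)), replace=False)
    for i in sorted(chosen):
        pos = free[i]
        anchors[pos] = root[pos - 1]
    return anchors


def _with_anchors(seq: str, anchors: dict[int, str]) -> str:
    out = list(seq)
    for pos, res in anchors.items():
        out[pos - 1] = res
    return out if isinstance(out, str) else "".join(out)


def make_family_models(
    configs: list[FamilyConfig], rng: np.random.Generator
) -> dict[str, FamilyModel]:
    """Build family models with band-validated clade seeds.

    Deterministic under a fixed RNG.  Seeds for distinct lineages are drawn
    from the root and re-drawn (with adaptively nudged distances) until all
    pairwise colinear similarities fall into the configured cross-lineage
    band, which guarantees the planted clade structure downstream thresholds
    assume.
    """
    models: dict[str, FamilyModel] = {}
    for cfg in configs:
        root = random_protein(cfg.length, rng)
        anchors = _draw_anchors(cfg.length, root, cfg.anchor_fraction, cfg.anchors, rng)
        seeds: dict[str, str] = {}
        major: dict[str, bool] = {}
        if len(cfg.lineages) == 1:
            spec = cfg.lineages[0]
            seeds[spec.label] = _with_anchors(root, anchors)
            major[spec.label] = spec.is_major
        else:
            # All lineage seeds sit at the same radius from the root: a pair's
            # similarity is set by the path-length sum, so a common radius is
            # the only geometry in which every pair can land in one band.
            # Orphan lineages differ from major clades by size (singletons),
            # not by extra divergence.
            lo, hi = SEED_CROSS_BAND
            radius = cfg.between_distance / 2
            for spec in cfg.lineages:
                accepted = None
                for _restart in range(300):
                    # start biased close to the root (similarities high) and
                    # walk outward: evolving the candidate itself lengthens
                    # its path to every accepted seed, so all its pairwise
                    # similarities decrease together.  Accept once no pair
                    # exceeds the cap and at least two pairs (one, for the
                    # second seed) remain in the reachable band — the same
                    # connectivity the member-level reach screen enforces.
                    cand = _with_anchors(
                        evolve_sequence(root, radius * 0.9, rng), anchors
                    )
                    if not seeds:
                        accepted = _with_anchors(
                            evolve_sequence(root, radius, rng), anchors
                        )
                        break
                    need = min(2, len(seeds))
                    for _step in range(150):
                        sims = [colinear_positives(cand, s) for s in seeds.values()]
                        if max(sims) <= hi:
                            if sum(1 for s in sims if s >= lo) >= need:
                                accepted = cand
                            break  # restart if too few reachable pairs
                        cand = _with_anchors(
                            evolve_sequence(cand, 0.015, rng), anchors
                        )
                    if accepted is not None:
                        break
                if accepted is None:
                    raise FamilyConfigError(
                        f"{cfg.family}: could not place seed for lineage "
                        f"{spec.label!r} inside the similarity band"
                    )
                seeds[spec.label] = accepted
                major[spec.label] = spec.is_major
        models[cfg.family] = FamilyModel(
            family=cfg.family, length=cfg.length, root=root, seeds=seeds,
            major=major, within_distance=cfg.within_distance, anchors=anchors,
        )
    return models


@dataclass(frozen=True)
class MemberPlan:
    """Extra shaping for one sampled member (indels, feature overrides)."""

    indels: tuple[Indel, ...] = ()
    features: dict[int, str] = field(default_factory=dict)


def sample_member(
    model: FamilyModel,
    lineage: str,
    rng: np.random.Generator,
    plan: MemberPlan | None = None,
) -> str:
    """One member sequence from a lineage, with anchors and plan applied."""
    seed = model.seeds[lineage]
    features = dict(model.anchors)
    if plan:
        features.update(plan.features)
    return evolve_sequence(
        seed, model.within_distance, rng,
        indels=plan.indels if plan else (), features=features,
    )


def sample_clade_set(
    model: FamilyModel,
    sizes: dict[str, int],
    rng: np.random.Generator,
    prefix: str | None = None,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Sample members per lineage and validate/repair the similarity bands.

    Returns records plus a member-id -> lineage-label truth map.  Cross-
    lineage member pairs above ``MEMBER_CROSS_MAX`` and within-clade pairs
    below ``MEMBER_WITHIN_MIN`` trigger a re-draw of one member; afterwards
    every lineage must be reachable from every other lineage's medoid at
    ``REACH_MIN`` (the condition for iterative search to bridge between
    clades), enforced by further re-draws.
    """
    prefix = prefix or model.family
    labels = [lab for lab in model.seeds if lab in sizes]
    members: dict[str, list[str]] = {}
    for lab in labels:
        members[lab] = [
            sample_member(model, lab, rng) for _ in range(sizes[lab])
        ]

    def flat() -> list[tuple[str, int]]:
        return [(lab, i) for lab in labels for i in range(len(members[lab]))]

    def simmat() -> np.ndarray:
        seqs = [members[lab][i] for lab, i in flat()]
        enc = [_encode(s) for s in seqs]
        n = len(enc)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = 100.0 * float(
                    np.mean(_POSITIVE[enc[i], enc[j]])
                )
        return out

    entries = flat()
    for _round in range(_MAX_TRIES):
        sims = simmat()
        bad: tuple[str, int] | None = None
        for i, (la, ia) in enumerate(entries):
            for j in range(i + 1, len(entries)):
                lb, jb = entries[j]
                if la == lb and sims[i, j] < MEMBER_WITHIN_MIN:
                    bad = (lb, jb)
                elif la != lb and sims[i, j] > MEMBER_CROSS_MAX:
                    bad = (lb, jb)
                if bad:
                    break
            if bad:
                break
        if bad is None:
            # reach screen: every lineage must see >= REACH_MIN from the
            # medoid of every other lineage (medoid = max mean within-sim)
            def medoid_index(lab: str) -> int:
                idxs = [k for k, (l, _) in enumerate(entries) if l == lab]
                if len(idxs) == 1:
                    return idxs[0]
                means = [sims[k, idxs].sum() / (len(idxs) - 1) for k in idxs]
                return idxs[int(np.argmax(means))]

            if len(labels) == 1:
                break
            # each lineage must be reachable from the medoids of at least
            # two other lineages (all others when only one exists), so the
            # query-expansion search can bridge into it from whichever clade
            # it was seeded with
            medoids = {la: medoid_index(la) for la in labels}
            weak: tuple[str, int] | None = None
            for lb in labels:
                idxs = [k for k, (l, _) in enumerate(entries) if l == lb]
                reached_by = sum(
                    1
                    for la in labels
                    if la != lb
                    and max(sims[medoids[la], k] for k in idxs) >= REACH_MIN
                )
                if reached_by < min(2, len(labels) - 1):
                    # re-draw the least-connected member of the weak lineage
                    worst = min(
                        idxs,
                        key=lambda k: max(
                            sims[medoids[la], k] for la in labels if la != lb
                        ),
                    )
                    weak = entries[worst]
                    break
            if weak is None:
                break
            bad = weak
        lab, i = bad
        members[lab][i] = sample_member(model, lab, rng)
    else:
        raise FamilyConfigError(
            f"{model.family}: member set failed similarity-band validation"
        )

    records: list[SeqRecord] = []
    truth: dict[str, str] = {}
    for lab in labels:
        for i, seq in enumerate(members[lab], start=1):
            mid = f"{prefix}_{lab}_{i:02d}"
            records.append(SeqRecord(id=mid, residues=seq))
            truth[mid] = lab
    return records, truth


# ---------------------------------------------------------------------------
# Reference-anchored feature coordinates for the synthetic families.  The
# nominal numbering follows the structural reference proteins conventionally
# used for SepRS (position 444 in the anticodon-binding domain) and SepCysS
# (loop 144-147, insertion point 234/235, PLP site, persulfide cysteines), so
# rules over real coordinates read the same way over synthetic data.

SEPRS_LENGTH = 520
SEPRS_RES444 = 444
SEPRS_CATALYTIC_SPAN = (1, 390)
SEPRS_CTERM_SPAN = (391, 520)
SEPRS_DELTA_C = (Indel("del", 391, 130),)

SEPCYSS_LENGTH = 380
SEPCYSS_LOOP_SPAN = (144, 147)
SEPCYSS_INDEL_POINT = 234  # the 8-residue indel sits between 234 and 235
SEPCYSS_PLP_SITES = {97: "K", 175: "D", 232: "S"}
SEPCYSS_PERSULFIDE_SITES = (64, 270, 280)

SEPCYSE_LENGTH = 260
SEPCYSE_N_DOMAIN = (1, 110)

SPS_LENGTH = 340

# Fixed anchors: an explicit residue pins that residue in every member; a
# None value pins whatever the family root carries there (pure conservation
# anchor).  Flanks of the 144-147 loop and of the 234/235 junction are
# anchored so progressive alignment places the planned indels exactly where
# the feature rules look for them.
_SEPRS_ANCHORS: dict[int, str | None] = {SEPRS_RES444: "I"}
_SEPCYSS_ANCHORS: dict[int, str | None] = {
    **SEPCYSS_PLP_SITES,
    **{p: "C" for p in SEPCYSS_PERSULFIDE_SITES},
    # flank anchors around the 144-147 loop and the 234/235 indel region:
    # the 8-residue indel occupies 235-242, so the right flank sits beyond it
    **{p: None for p in (140, 141, 142, 143, 148, 149, 150, 151)},
    # 230-238 pin the junction for members that retain it (insertions);
    # 243-247 lie beyond the indel region and re-anchor members whose
    # residues 235-242 are deleted
    **{p: None for p in (230, 231, 233, 234, 235, 236, 237, 238,
                         243, 244, 245, 246, 247)},
}


def default_family_configs() -> list[FamilyConfig]:
    """Family configurations for the shipped default presets."""
    return [
        FamilyConfig(
            family="SepRS", length=SEPRS_LENGTH,
            lineages=(
                LineageSpec("cladeI"), LineageSpec("cladeII"),
                LineageSpec("cladeIII"),
                LineageSpec("orphan1", is_major=False),
                LineageSpec("orphan2", is_major=False),
            ),
            anchors=dict(_SEPRS_ANCHORS),
        ),
        FamilyConfig(
            family="SepCysS", length=SEPCYSS_LENGTH,
            lineages=tuple(
                LineageSpec(f"clade{r}") for r in ("I", "II", "III", "IV", "V", "VI", "VII")
            ),
            anchors=dict(_SEPCYSS_ANCHORS),
        ),
        FamilyConfig(
            family="SepCysE", length=SEPCYSE_LENGTH,
            lineages=(LineageSpec("main"),),
        ),
        FamilyConfig(
            family="PylRS", length=270,
            lineages=(
                LineageSpec("Methanosarcinaceae"),
                LineageSpec("Bacterial"),
                LineageSpec("Methanomassiliicoccales"),
                LineageSpec("novel1", is_major=False),
                LineageSpec("novel2", is_major=False),
            ),
        ),
        FamilyConfig(family="PylSn", length=110, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="SPS", length=SPS_LENGTH, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="HdrA", length=260, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="VhuD", length=140, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="VhuU", length=70, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="pylB", length=250, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="pylC", length=230, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="pylD", length=220, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="mtmB", length=210, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="mtbB", length=210, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="mttB", length=210, lineages=(LineageSpec("main"),)),
        FamilyConfig(family="marker", length=180, lineages=(LineageSpec("main"),)),
    ]


# Sizes of the stand-alone protein presets used for clade-structure analyses.
PRESET_SIZES = {
    # 3 major clades and 2 singleton orphans, ~30 sequences
    "seprs_default": {
        "cladeI": 10, "cladeII": 9, "cladeIII": 9, "orphan1": 1, "orphan2": 1,
    },
    # 7 major clades, ~40 sequences
    "sepcyss_default": {
        "cladeI": 6, "cladeII": 6, "cladeIII": 6, "cladeIV": 6,
        "cladeV": 6, "cladeVI": 5, "cladeVII": 5,
    },
    # 3 reference-labeled clades plus 2 novel lineages
    "pylrs_default": {
        "Methanosarcinaceae": 6, "Bacterial": 6, "Methanomassiliicoccales": 6,
        "novel1": 2, "novel2": 2,
    },
}

_PRESET_FAMILY = {
    "seprs_default": "SepRS",
    "sepcyss_default": "SepCysS",
    "pylrs_default": "PylRS",
}


def protein_preset(
    name: str, rng: np.random.Generator
) -> tuple[list[SeqRecord], dict[str, str], FamilyModel]:
    """Build one of the shipped protein presets.

    Returns (records, member-id -> lineage truth, family model).  Lineage
    labels beginning with ``orphan``/``novel`` are the planted singleton or
    novel lineages; the rest are major clades.
    """
    if name not in PRESET_SIZES:
        raise FamilyConfigError(f"unknown preset {name!r}")
    family = _PRESET_FAMILY[name]
    cfgs = [c for c in default_family_configs() if c.family == family]
    model = make_family_models(cfgs, rng)[family]
    records, truth = sample_clade_set(model, PRESET_SIZES[name], rng, prefix=family)
    return records, truth, model
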