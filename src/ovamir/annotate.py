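"""Mapping and five-group classification of unique tags.

Tags are matched against a species miRNA reference (mature + precursor),
a broader-clade reference (standing in for the Arthropoda set of
miRBase) and a reference genome, then assigned to one of five groups in
a fixed specific-to-generic decision order:

1. species miRNA hit and a genome hit at the known locus;
2. species miRNA hit and an additional genome locus whose extended
   sequence folds into a hairpin;
3. clade miRNA hit, a hit in a secondary ("other") genome and none in
   the primary genome;
4. clade miRNA hit, no genome hit;
5. no miRNA hit, a genome hit whose extension has hairpin propensity
   (the novel-miRNA candidates).

Tags hitting nothing stay unclassified (piRNA-like reads land there).
Matching is exact k-mer seed-and-extend: tags are <= 30 nt, so no
external aligner is involved.  miRNA-reference hits tolerate up to 2
substitutions but require the tag seed (positions 2-8) exact; genome
hits are exact by default.  Known-miRNA names come from the best species
hit (fewest mismatches, then alphabetical); families are keyed by the
seed sequence; star tags are recognised by mapping to the arm opposite
the mature in a folded known precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import extend_context, hairpin_check, mfe_fold
from .preprocess import ApproxSubstringIndex
from .seq import revcomp_dna, to_dna, to_rna

__all__ = [
    "ReferenceSet",
    "GenomeHit",
    "MirHit",
    "MappingProfile",
    "MirCall",
    "AnnotateConfig",
    "AnnotationResult",
    "map_tags",
    "classify_group",
    "assign_family",
    "detect_star",
    "annotate_tags",
    "make_hairpin_checker",
]

GROUPS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class GenomeHit:
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class MirHit:
    """Alignment of a tag to a reference miRNA (mature or precursor)."""

    name: str
    kind: str        # "mature" | "precursor"
    offset: int      # tag start relative to the reference 5' end
    mismatches: int


@dataclass
class MappingProfile:
    tag_id: str
    seq: str                                  # DNA
    count: int
    hits_species_mir: list = field(default_factory=list)
    hits_clade_mir: list = field(default_factory=list)
    hits_genome: list = field(default_factory=list)
    hits_secondary: list = field(default_factory=list)
    known_locus_overlap: list = field(default_factory=list)  # parallel to hits_genome


@dataclass
class MirCall:
    tag_id: str
    seq: str
    count: int
    group: int
    status: str                  # "known" | "novel-candidate" | "star"
    assigned_name: str
    family: str = ""
    arm: str = "unknown"


@dataclass
class ReferenceSet:
    """References the classifier maps against (all sequences DNA-space)."""

    species_mature: dict[str, str] = field(default_factory=dict)
    species_precursor: dict[str, str] = field(default_factory=dict)
    clade_mature: dict[str, str] = field(default_factory=dict)
    clade_precursor: dict[str, str] = field(default_factory=dict)
    genome: dict[str, str] | None = None
    secondary_genome: dict[str, str] | None = None

    @classmethod
    def from_planted(cls, genome: dict[str, str], planted) -> "ReferenceSet":
        """Build the reference set a simulation implies: reference-known
        planted miRNAs enter the species (and clade) sets; novel ones do
        not appear anywhere except the genome."""
        mature = {p.name: to_dna(p.mature_seq) for p in planted if p.known}
        prec = {p.name: genome[p.contig][p.precursor_start:p.precursor_end]
                for p in planted if p.known}
        return cls(species_mature=mature, species_precursor=prec,
                   clade_mature=dict(mature), clade_precursor=dict(prec),
                   genome=genome)


@dataclass
class AnnotateConfig:
    max_mismatch_mir: int = 2
    max_mismatch_genome: int = 0
    max_overhang: int = 2        # tag bases allowed past a mature reference end
    flank: int = 60
    energy_max: float = -18.0
    pair_min: float = 0.6
    star_pair_min: float = 0.6


# --------------------------------------------------------------------------
# mapping
# --------------------------------------------------------------------------

class _MatureIndex:
    """Seed-anchored matcher of tags against mature reference sequences.

    Valid hits must carry the tag seed (positions 2-8) exactly, so the
    seed 7-mer fully anchors every candidate alignment; up to
    ``max_overhang`` tag bases may fall outside the reference, and
    mismatches are counted over the overlap.
    """

    def __init__(self, matures: dict[str, str]):
        self.matures = matures
        self._seed_pos: dict[str, list[tuple[str, int]]] = {}
        for name, ref in matures.items():
            for pos in range(len(ref) - 6):
                self._seed_pos.setdefault(ref[pos:pos + 7], []).append((name, pos))

    def hits(self, tag: str, max_mm: int, max_overhang: int) -> list[MirHit]:
        out = []
        seen = set()
        for name, pos in self._seed_pos.get(tag[1:8], ()):
            offset = pos - 1
            if (name, offset) in seen:
                continue
            seen.add((name, offset))
            ref = self.matures[name]
            overhang = 0
            mm = 0
            for t in range(len(tag)):
                r = offset + t
                if r < 0 or r >= len(ref):
                    overhang += 1
                elif tag[t] != ref[r]:
                    mm += 1
            if overhang <= max_overhang and mm <= max_mm:
                out.append(MirHit(name=name, kind="mature", offset=offset,
                                  mismatches=mm))
        return sorted(out, key=lambda h: (h.mismatches, h.name, h.offset))


class _PrecursorIndex:
    """Substring matcher of tags against precursor sequences (seed exact)."""

    def __init__(self, precursors: dict[str, str]):
        self.names = sorted(precursors)
        self._idx = ApproxSubstringIndex([precursors[n] for n in self.names])

    def hits(self, tag: str, max_mm: int) -> list[MirHit]:
        out = []
        for ri, start, mm in self._idx.find_all(tag, max_mm):
            ref = self._idx.refs[ri]
            if ref[start + 1:start + 8] != tag[1:8]:
                continue  # seed must be exact
            out.append(MirHit(name=self.names[ri], kind="precursor",
                              offset=start, mismatches=mm))
        return sorted(out, key=lambda h: (h.mismatches, h.name, h.offset))


class _GenomeIndex:
    def __init__(self, genome: dict[str, str]):
        self.contigs = sorted(genome)
        self._idx = ApproxSubstringIndex([genome[c] for c in self.contigs])

    def hits(self, tag: str, max_mm: int) -> list[GenomeHit]:
        out = []
        for ri, start, mm in self._idx.find_all(tag, max_mm):
            out.append(GenomeHit(self.contigs[ri], start, start + len(tag),
                                 "+", mm))
        for ri, start, mm in self._idx.find_all(revcomp_dna(tag), max_mm):
            out.append(GenomeHit(self.contigs[ri], start, start + len(tag),
                                 "-", mm))
        return sorted(out, key=lambda h: (h.contig, h.start, h.strand))


def _known_loci(refset: ReferenceSet) -> list[tuple[str, int, int]]:
    """Genomic intervals occupied by the species reference (mir or miR)."""
    if not refset.genome:
        return []
    gi = _GenomeIndex(refset.genome)
    loci = []
    for ref in (refset.species_mature, refset.species_precursor):
        for name in sorted(ref):
            for hit in gi.hits(ref[name], 0):
                loci.append((hit.contig, hit.start, hit.end))
    return loci


def map_tags(tags, refset: ReferenceSet,
             config: AnnotateConfig | None = None) -> list[MappingProfile]:
    """Map unique tags against the miRNA references and the genome."""
    cfg = config or AnnotateConfig()
    sp_mat = _MatureIndex(refset.species_mature)
    sp_pre = _PrecursorIndex(refset.species_precursor)
    cl_mat = _MatureIndex(refset.clade_mature)
    cl_pre = _PrecursorIndex(refset.clade_precursor)
    gidx = _GenomeIndex(refset.genome) if refset.genome else None
    sidx = (_GenomeIndex(refset.secondary_genome)
            if refset.secondary_genome else None)
    known = _known_loci(refset)

    profiles = []
    for tag in tags:
        seq = to_dna(tag.seq)
        p = MappingProfile(tag_id=tag.id, seq=seq, count=tag.count)
        p.hits_species_mir = (sp_mat.hits(seq, cfg.max_mismatch_mir, cfg.max_overhang)
                              + sp_pre.hits(seq, cfg.max_mismatch_mir))
        p.hits_clade_mir = (cl_mat.hits(seq, cfg.max_mismatch_mir, cfg.max_overhang)
                            + cl_pre.hits(seq, cfg.max_mismatch_mir))
        if gidx is not None:
            p.hits_genome = gidx.hits(seq, cfg.max_mismatch_genome)
            p.known_locus_overlap = [
                any(h.contig == c and h.start < e and h.end > s
                    for c, s, e in known)
                for h in p.hits_genome]
        if sidx is not None:
            p.hits_secondary = sidx.hits(seq, cfg.max_mismatch_genome)
        profiles.append(p)
    return profiles


# --------------------------------------------------------------------------
# hairpin evidence and classification
# --------------------------------------------------------------------------

def make_hairpin_checker(genome: dict[str, str],
                         config: AnnotateConfig | None = None):
    """Return a cached callable judging hairpin propensity at a genome hit.

    For each hit the +/-`flank` window and the two single-sided windows
    are folded; the locus has hairpin propensity if any candidate passes
    :func:`ovamir.fold.hairpin_check` with the tag as the mature span.
    The callable returns (bool, winning HairpinVerdict or None).
    """
    cfg = config or AnnotateConfig()
    cache: dict[tuple, tuple] = {}

    def checker(hit: GenomeHit):
        key = (hit.contig, hit.start, hit.end, hit.strand)
        if key in cache:
            return cache[key]
        result = (False, None)
        for cand in extend_context(genome, key, flank=cfg.flank):
            fr = mfe_fold(cand.seq)
            verdict = hairpin_check(fr, cand.mature_span,
                                    energy_max=cfg.energy_max,
                                    pair_min=cfg.pair_min)
            if verdict.is_hairpin:
                result = (True, verdict)
                break
        cache[key] = result
        return result

    return checker


def classify_group(profile: MappingProfile, hairpin_checker=None,
                   has_secondary: bool = False) -> tuple[int | None, object]:
    """Assign the five-group label (first match wins); None = unclassified.

    Returns (group, hairpin verdict or None).  ``hairpin_checker`` is
    only consulted for groups 2 and 5; without one those groups cannot
    be assigned.
    """
    species = bool(profile.hits_species_mir)
    clade = species or bool(profile.hits_clade_mir)
    genome_hits = profile.hits_genome
    if species and any(profile.known_locus_overlap):
        return 1, None
    if species and hairpin_checker is not None:
        for h, known in zip(genome_hits, profile.known_locus_overlap):
            if not known:
                ok, verdict = hairpin_checker(h)
                if ok:
                    return 2, verdict
    if clade and not genome_hits and has_secondary and profile.hits_secondary:
        return 3, None
    if clade and not genome_hits:
        return 4, None
    if not clade and genome_hits and hairpin_checker is not None:
        for h in genome_hits:
            ok, verdict = hairpin_checker(h)
            if ok:
                return 5, verdict
    return None, None


def assign_family(calls: list[MirCall]) -> dict[str, list[str]]:
    """Group calls by seed (positions 2-8 of the mature-sense sequence).

    Sets ``call.family`` in place and returns {seed: sorted names}.
    Sequences shorter than 8 nt are left without a family.
    """
    families: dict[str, set[str]] = {}
    for call in calls:
        rna = to_rna(call.seq)
        if len(rna) < 8:
            continue
        seed = rna[1:8]
        call.family = seed
        families.setdefault(seed, set()).add(call.assigned_name)
    return {seed: sorted(names) for seed, names in families.items()}


def detect_star(calls: list[MirCall], profiles: list[MappingProfile],
                refset: ReferenceSet,
                config: AnnotateConfig | None = None) -> None:
    """Mark tags lying on the arm opposite the mature of a known precursor.

    A tag is a star when it maps inside a species precursor, the
    precursor folds into a hairpin, the tag does not overlap the
    annotated mature, and at least ``star_pair_min`` of the tag bases
    pair with bases of the mature arm in that fold.  Updates calls in
    place (status="star", arm set to the non-mature arm).
    """
    cfg = config or AnnotateConfig()
    by_id = {p.tag_id: p for p in profiles}
    fold_cache: dict[str, tuple] = {}

    def precursor_fold(name: str):
        if name not in fold_cache:
            prec = refset.species_precursor[name]
            mature = refset.species_mature.get(name, "")
            m_off = prec.find(mature) if mature else -1
            fr = mfe_fold(prec)
            fold_cache[name] = (fr, m_off, len(mature))
        return fold_cache[name]

    for call in calls:
        profile = by_id.get(call.tag_id)
        if profile is None:
            continue
        for hit in profile.hits_species_mir:
            if hit.kind != "precursor" or hit.name not in refset.species_precursor:
                continue
            fr, m_off, m_len = precursor_fold(hit.name)
            if m_off < 0 or not fr.pairs:
                continue
            t0, t1 = hit.offset, hit.offset + len(call.seq)
            if t0 < m_off + m_len and t1 > m_off:
                continue  # overlaps the mature: not a star
            partner = fr.partner()
            paired_to_mature = sum(
                1 for p in range(t0, t1)
                if p in partner and m_off <= partner[p] < m_off + m_len)
            if paired_to_mature / (t1 - t0) >= cfg.star_pair_min:
                call.status = "star"
                call.arm = "3p" if t0 >= m_off + m_len else "5p"
                call.assigned_name = f"{hit.name}*"
                break


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class AnnotationResult:
    calls: list[MirCall]
    profiles: list[MappingProfile]
    unclassified: list[str]                 # tag ids
    group_counts: dict[int, int]
    family_map: dict[str, list[str]]

    @property
    def known_calls(self):
        return [c for c in self.calls if c.status == "known"]

    @property
    def novel_calls(self):
        return [c for c in self.calls if c.status == "novel-candidate"]

    @property
    def star_calls(self):
        return [c for c in self.calls if c.status == "star"]


def annotate_tags(tags, refset: ReferenceSet,
                  config: AnnotateConfig | None = None) -> AnnotationResult:
    """Map, classify, name, star-mark and family-assign a tag set.

    Deterministic in the tag set: tags are processed in (count desc,
    sequence) order regardless of input order.
    """
    cfg = config or AnnotateConfig()
    tags = sorted(tags, key=lambda t: (-t.count, t.seq))
    profiles = map_tags(tags, refset, cfg)
    checker = (make_hairpin_checker(refset.genome, cfg)
               if refset.genome else None)
    has_secondary = refset.secondary_genome is not None

    calls: list[MirCall] = []
    unclassified: list[str] = []
    group_counts = {g: 0 for g in GROUPS}
    novel_serial = 0
    for p in profiles:
        group, verdict = classify_group(p, checker, has_secondary)
        if group is None:
            unclassified.append(p.tag_id)
            continue
        group_counts[group] += 1
        mir_hits = p.hits_species_mir or p.hits_clade_mir
        if mir_hits:
            best = min(mir_hits, key=lambda h: (h.mismatches, h.name))
            status, name = "known", best.name
            arm = "unknown"
        else:
            novel_serial += 1
            status, name = "novel-candidate", f"novel-{novel_serial:03d}"
            arm = verdict.mature_arm if verdict is not None else "unknown"
        calls.append(MirCall(tag_id=p.tag_id, seq=p.seq, count=p.count,
                             group=group, status=status, assigned_name=name,
                             arm=arm))
    detect_star(calls, profiles, refset, cfg)
    family_map = assign_family(calls)
    return AnnotationResult(calls=calls, profiles=profiles,
                            unclassified=unclassified,
                            group_counts=group_counts, family_map=family_map)
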