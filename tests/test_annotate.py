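"""Mapping, five-group classification, families and star detection."""

import random

from ovamir.annotate import (MirCall, ReferenceSet,
                             annotate_tags, assign_family, classify_group,
                             detect_star, make_hairpin_checker, map_tags)
from ovamir.preprocess import UniqueTag
from ovamir.seq import revcomp_dna


def _tag(seq, count=10, tid="t1"):
    return UniqueTag(id=tid, seq=seq, count=count)


def _hairpin_genome():
    """A genome with one designed hairpin locus and unstructured padding."""
    mature = "GATTACAGATTACAGATTACAG"  # 22 nt
    prec = "ACCACAACCA" + mature + "ACCACCAA" + revcomp_dna(mature) + "AACCACCACA"
    pad = "CA" * 60
    genome = {"chr1": pad + prec + pad}
    start = len(pad) + 10
    return genome, mature, (start, start + 22)


class TestMapTags:
    def test_exact_species_mature_hit(self):
        mature = "TACCCTGTAGATCCGAATTTGT"
        refset = ReferenceSet(species_mature={"miR-x": mature},
                              clade_mature={"miR-x": mature})
        [profile] = map_tags([_tag(mature)], refset)
        assert profile.hits_species_mir[0].name == "miR-x"
        assert profile.hits_species_mir[0].mismatches == 0

    def test_minus_strand_genome_hit(self):
        genome, mature, (s, e) = _hairpin_genome()
        tag = revcomp_dna(genome["chr1"][s:e])
        refset = ReferenceSet(genome=genome)
        [profile] = map_tags([_tag(tag)], refset)
        hit = profile.hits_genome[0]
        assert (hit.start, hit.end, hit.strand) == (s, e, "-")

    def test_seed_mismatch_blocks_reference_hit(self):
        mature = "TACCCTGTAGATCCGAATTTGT"
        variant = mature[:3] + ("A" if mature[3] != "A" else "C") + mature[4:]
        refset = ReferenceSet(species_mature={"miR-x": mature},
                              clade_mature={"miR-x": mature})
        [profile] = map_tags([_tag(variant)], refset)
        assert profile.hits_species_mir == []  # seed (nt 2-8) must be exact

    def test_tail_mismatches_tolerated(self):
        mature = "TACCCTGTAGATCCGAATTTGT"
        variant = mature[:-2] + "AA" if mature[-2:] != "AA" else mature[:-2] + "CC"
        refset = ReferenceSet(species_mature={"miR-x": mature},
                              clade_mature={"miR-x": mature})
        [profile] = map_tags([_tag(variant)], refset)
        assert profile.hits_species_mir
        assert profile.hits_species_mir[0].mismatches == 2


class TestClassifyGroup:
    def test_five_group_assignment(self, small_dataset, small_annotation):
        by_group = {g: [c for c in small_annotation.calls if c.group == g]
                    for g in (1, 2, 3, 4, 5)}
        known_names = {p.name for p in small_dataset.planted if p.known}
        # group 1 calls carry species names; group 5 are provisional novels
        assert by_group[1], "expected group-1 calls"
        assert {c.assigned_name.rstrip("*") for c in by_group[1]} <= known_names
        assert by_group[5], "expected group-5 novel candidates"
        assert all(c.assigned_name.startswith("novel-") for c in by_group[5])
        assert not by_group[3], "no secondary genome configured"

    def test_clade_only_hit_without_genome_is_group_four(self):
        mature = "TACCCTGTAGATCCGAATTTGT"
        refset = ReferenceSet(clade_mature={"miR-y": mature},
                              genome={"chr1": "CA" * 300})
        [profile] = map_tags([_tag(mature)], refset)
        checker = make_hairpin_checker(refset.genome)
        group, _ = classify_group(profile, checker)
        assert group == 4

    def test_novel_hairpin_locus_is_group_five(self):
        genome, mature, span = _hairpin_genome()
        refset = ReferenceSet(genome=genome)
        [profile] = map_tags([_tag(mature)], refset)
        checker = make_hairpin_checker(refset.genome)
        group, verdict = classify_group(profile, checker)
        assert group == 5
        assert verdict is not None and verdict.is_hairpin

    def test_no_hits_is_unclassified(self):
        refset = ReferenceSet(genome={"chr1": "CA" * 300})
        [profile] = map_tags([_tag("GGTTGGTTGGTTGGTTGGTT")], refset)
        group, _ = classify_group(profile, make_hairpin_checker(refset.genome))
        assert group is None

    def test_partition_of_all_tags(self, small_tags, small_annotation):
        tags, _ = small_tags
        classified = {c.tag_id for c in small_annotation.calls}
        unclassified = set(small_annotation.unclassified)
        assert classified.isdisjoint(unclassified)
        assert classified | unclassified == {t.id for t in tags}
        assert (sum(small_annotation.group_counts.values())
                == len(small_annotation.calls))

    def test_input_order_invariance(self, small_dataset, small_tags):
        tags, _ = small_tags
        refset = ReferenceSet.from_planted(small_dataset.genome,
                                           small_dataset.planted)
        shuffled = list(tags)
        random.Random(0).shuffle(shuffled)
        a = annotate_tags(tags[:150], refset)
        b = annotate_tags(list(reversed(tags[:150])), refset)
        assert [
            (c.tag_id, c.group, c.status, c.assigned_name) for c in a.calls
        ] == [(c.tag_id, c.group, c.status, c.assigned_name) for c in b.calls]


class TestFamilies:
    def test_shared_seed_is_one_family(self):
        calls = [
            MirCall("t1", "TACCCTGTAGATCCGAATTTGT", 5, 1, "known", "miR-a"),
            MirCall("t2", "TACCCTGTAGCCCCCAAATTAA", 5, 1, "known", "miR-b"),
        ]
        fams = assign_family(calls)
        assert len(fams) == 1
        assert calls[0].family == calls[1].family == "ACCCUGU"

    def test_seed_difference_splits_families(self):
        calls = [
            MirCall("t1", "TACCCTGTAGATCCGAATTTGT", 5, 1, "known", "miR-a"),
            MirCall("t2", "TACCGTGTAGATCCGAATTTGT", 5, 1, "known", "miR-c"),
        ]
        assert len(assign_family(calls)) == 2

    def test_planted_seed_families_recovered(self, small_dataset,
                                             small_annotation):
        counts = (small_dataset.truth
                  .query("label == 'mir-mature'").groupby("source").size())
        planted_seeds = {p.mature_seq[1:8]
                         for p in small_dataset.planted
                         if p.known and counts.get(p.name, 0) >= 10}
        called = {c.family for c in small_annotation.calls
                  if c.status in ("known", "star") and c.group == 1
                  and c.arm == "unknown"}
        # every well-expressed planted known seed appears among the families
        assert planted_seeds <= {f for f in called if f}


class TestDetectStar:
    def test_planted_star_reads_marked(self, small_dataset, small_annotation):
        stars = small_annotation.star_calls
        assert stars, "simulated star reads should be detected"
        star_seqs = {p.star_seq.replace("U", "T") for p in small_dataset.planted
                     if p.known}
        assert all(c.arm == "3p" for c in stars)
        assert any(any(c.seq in s or s in c.seq for s in star_seqs)
                   for c in stars)

    def test_mature_tag_not_star(self, small_annotation):
        for c in small_annotation.calls:
            if c.status == "known":
                assert not c.assigned_name.endswith("*")

    def test_loop_tag_fails_pairing_criterion(self):
        mature = "GATTACAGATTACAGATTACAG"
        loop = "ACCACCAACCACACA"  # 15 nt unpairable loop
        prec = "ACCACAACCA" + mature + loop + revcomp_dna(mature) + "AACCACCACA"
        refset = ReferenceSet(species_mature={"m": mature},
                              species_precursor={"m": prec})
        loop_tag = _tag(prec[32:47], tid="loop")
        profiles = map_tags([loop_tag], refset)
        calls = [MirCall("loop", loop_tag.seq, 10, 1, "known", "m")]
        detect_star(calls, profiles, refset)
        assert calls[0].status == "known"  # unchanged: not a star
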