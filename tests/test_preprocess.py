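"""Read cleanup: filters, trimming, collapsing, histograms."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ovamir.preprocess import (UniqueTag, collapse, contaminant_filter,
                               copy_filter, length_filter, length_histogram,
                               quality_filter, trim_adaptor)
from ovamir.simlib import (LABEL_ARTIFACT, DEFAULT_ADAPTOR, SimConfig,
                           simulate_dataset)

Q35 = chr(35 + 33)
Q10 = chr(10 + 33)


def binom_ci(p, n, conf=0.99):
    lo, hi = stats.binom.interval(conf, n, p)
    return lo / n, hi / n


class TestQualityFilter:
    def test_boundaries(self):
        reads = [("hi", "ACGTACGTACGTACGTACGT", Q35 * 20),
                 ("lo", "ACGTACGTACGTACGTACGT", Q10 * 20)]
        kept = quality_filter(reads, 20)
        assert [r[0] for r in kept] == ["hi"]

    def test_n_bases_dropped(self):
        kept = quality_filter([("n", "ACGNACGT", Q35 * 8)], 20)
        assert kept == []

    def test_malformed_record_names_index(self):
        reads = [("ok", "ACGT", Q35 * 4), ("bad", "ACGT", Q35 * 3)]
        with pytest.raises(ValueError, match="index 1"):
            quality_filter(reads, 20)

    def test_planted_low_quality_fraction_recovered(self):
        cfg = SimConfig(read_total=20_000, n_known=4, n_novel=0,
                        n_pirna_loci=5, genome_length=5_000,
                        low_quality_fraction=0.10, seed=21)
        ds = simulate_dataset(cfg)
        kept = quality_filter(ds.reads, 20)
        drop_frac = 1 - len(kept) / len(ds.reads)
        lo, hi = binom_ci(0.10, len(ds.reads))
        assert lo <= drop_frac <= hi


class TestTrimAdaptor:
    ADAPTOR = DEFAULT_ADAPTOR

    def test_exact_adaptor_at_three_prime(self):
        insert = "ACGTACGTACGTACGTACGTA"
        insert_out, flag = trim_adaptor(insert + self.ADAPTOR, self.ADAPTOR)
        assert (insert_out, flag) == (insert, "trimmed")

    def test_adaptor_dimer_flagged_as_artifact(self):
        assert trim_adaptor(self.ADAPTOR, self.ADAPTOR) == (None, "artifact")

    def test_absent_adaptor_discards_read(self):
        assert trim_adaptor("ACGT" * 9, self.ADAPTOR) == (None, "no-adaptor")

    def test_partial_adaptor_suffix_found(self):
        read = ("ACGTACGTACGTACGTACGTA" + self.ADAPTOR)[:30]
        insert, flag = trim_adaptor(read, self.ADAPTOR)
        assert (insert, flag) == ("ACGTACGTACGTACGTACGTA", "trimmed")

    def test_single_mismatch_tolerated(self):
        insert = "CCCCCCCCCCCCCCCCCCCCC"
        bad = "A" + self.ADAPTOR[1:]
        assert trim_adaptor(insert + bad, self.ADAPTOR) == (insert, "trimmed")

    def test_error_free_simulation_recovers_all_inserts(self):
        cfg = SimConfig(read_total=5_000, n_known=4, n_novel=0, n_pirna_loci=5,
                        genome_length=5_000, error_rate=0.0,
                        low_quality_fraction=0.0, seed=9)
        ds = simulate_dataset(cfg)
        truth = ds.truth.set_index("read_id")
        for rid, seq, _ in ds.reads:
            insert, flag = trim_adaptor(seq, cfg.adaptor_seq)
            row = truth.loc[rid]
            if row.label == LABEL_ARTIFACT:
                assert flag == "artifact"
            else:
                assert flag == "trimmed" and len(insert) == row.insert_len


class TestLengthAndCopy:
    @pytest.mark.parametrize("length,kept", [(14, False), (15, True),
                                             (30, True), (31, False)])
    def test_length_window_boundaries(self, length, kept):
        out = length_filter(["A" * length])
        assert bool(out) is kept

    @pytest.mark.parametrize("count,kept", [(2, False), (3, True)])
    def test_copy_number_floor(self, count, kept):
        tags = [UniqueTag("t1", "ACGTACGTACGTACG", count)]
        assert bool(copy_filter(tags, 3)) is kept

    def test_min_copy_one_is_identity(self):
        tags = [UniqueTag("t1", "ACGTACGTACGTACG", 1)]
        assert copy_filter(tags, 1) == tags

    @given(st.lists(st.sampled_from(["ACGUA" * 4, "CCCGG" * 4, "AAAAA" * 3])))
    @settings(max_examples=25, derandomize=True)
    def test_collapse_conserves_and_filters_idempotent(self, seqs):
        tags = collapse(seqs)
        assert sum(t.count for t in tags) == len(seqs)
        assert len({t.seq for t in tags}) == len(tags)
        once = copy_filter(length_filter(tags), 2)
        again = copy_filter(length_filter(once), 2)
        assert [(t.seq, t.count) for t in once] == [(t.seq, t.count) for t in again]

    def test_collapse_ordering_and_empty(self):
        assert collapse([]) == []
        tags = collapse(["CCC", "AAA", "AAA"])
        assert [(t.seq, t.count) for t in tags] == [("AAA", 2), ("CCC", 1)]


class TestContaminantFilter:
    REFS = {"Rfam-like": [("tRNA-1", "GGGCCCGTAGCTCAGTTGGTAGAGCACGACCTTGCCAAGG")],
            "mRNA-like": []}

    def test_exact_substring_removed_with_class(self):
        tag = self.REFS["Rfam-like"][0][1][5:25]
        kept, removed = contaminant_filter([tag, "T" * 20], self.REFS, 1)
        assert kept == ["T" * 20]
        assert removed["Rfam-like"] == 1

    def test_two_mismatches_retained_at_threshold_one(self):
        ref = self.REFS["Rfam-like"][0][1]
        tag = "TT" + ref[7:25]  # two substitutions vs the reference window
        assert tag not in ref
        kept, removed = contaminant_filter([tag], self.REFS, 1)
        assert kept == [tag]
        assert removed["Rfam-like"] == 0

    def test_planted_contaminant_fraction_recovered(self, small_dataset):
        truth_frac = (small_dataset.truth.label == "contaminant").mean()
        seqs = [seq for _, seq, _ in small_dataset.reads]
        # trim first so contaminants are full-length tags, as in the pipeline
        inserts = []
        for s in seqs:
            insert, flag = trim_adaptor(s, small_dataset.config.adaptor_seq)
            if flag == "trimmed":
                inserts.append(insert)
        kept, removed = contaminant_filter(inserts,
                                           small_dataset.contaminants, 1)
        removed_frac = sum(removed.values()) / len(small_dataset.reads)
        lo, hi = binom_ci(small_dataset.config.contaminant_fraction,
                          len(small_dataset.reads))
        assert lo <= removed_frac <= hi
        assert truth_frac == pytest.approx(removed_frac, abs=0.01)


class TestHistogramAndPipeline:
    def test_single_tag_histogram(self):
        reads, unique = length_histogram([UniqueTag("t", "A" * 22, 5)])
        assert reads[22] == 5 and unique[22] == 1
        assert sum(reads.values()) == 5

    def test_empty_histogram(self):
        reads, unique = length_histogram([])
        assert set(reads.values()) == {0} and set(unique.values()) == {0}

    def test_bimodal_length_distribution(self, small_tags):
        tags, _ = small_tags
        reads, _ = length_histogram(tags)
        short_peak = max(range(21, 24), key=lambda l: reads[l])
        long_peak = max(range(24, 28), key=lambda l: reads[l])
        # local maxima in each mode, long mode more abundant
        assert reads[short_peak] > reads[20]
        assert reads[long_peak] > reads[28]
        assert sum(reads[l] for l in range(24, 28)) > sum(
            reads[l] for l in range(21, 24))

    def test_filter_report_monotone_and_conserving(self, small_tags):
        tags, report = small_tags
        assert report.is_monotone()
        assert report.post_copy_reads == sum(t.count for t in tags)
        assert report.unique_tags >= report.post_copy_tags
        reads_hist, unique_hist = length_histogram(tags)
        assert sum(reads_hist.values()) == report.post_copy_reads
        assert sum(unique_hist.values()) == len(tags)
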