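"""Simulator: determinism, label accounting, planted-truth guarantees."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ovamir.fold import hairpin_check, mfe_fold
from ovamir.simlib import (LABEL_MATURE, PackingError, SimConfig,
                           make_contaminants, make_genome, make_utr,
                           simulate_dataset, simulate_luciferase,
                           simulate_qpcr, simulate_reads)

TINY = SimConfig(read_total=5_000, n_known=4, n_novel=2, n_pirna_loci=5,
                 genome_length=5_000, seed=3)


class TestMakeGenome:
    def test_seeded_determinism(self):
        g1, p1, l1 = make_genome(TINY)
        g2, p2, l2 = make_genome(TINY)
        assert g1 == g2 and p1 == p2 and l1 == l2

    def test_empty_case(self):
        cfg = dataclasses.replace(TINY, n_known=0, n_novel=0, n_pirna_loci=0)
        genome, planted, loci = make_genome(cfg)
        assert planted == [] and loci == []
        assert len(genome["chr1"]) == cfg.genome_length

    def test_loci_disjoint_and_within_bounds(self):
        genome, planted, loci = make_genome(TINY)
        ivals = sorted([(p.precursor_start, p.precursor_end) for p in planted]
                       + [(s, e) for _, s, e in loci])
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            assert b1 <= a2
        assert all(0 <= a < b <= TINY.genome_length for a, b in ivals)

    def test_mature_and_star_inside_disjoint(self):
        _, planted, _ = make_genome(TINY)
        for p in planted:
            assert p.precursor_start <= p.mature_start < p.mature_end <= p.precursor_end
            assert p.precursor_start <= p.star_start < p.star_end <= p.precursor_end
            assert p.mature_end <= p.star_start
            assert 60 <= p.precursor_end - p.precursor_start <= 120

    def test_construction_guarantees_hairpin(self):
        genome, planted, _ = make_genome(TINY)
        for p in planted:
            prec = genome["chr1"][p.precursor_start:p.precursor_end]
            span = (p.mature_start - p.precursor_start,
                    p.mature_end - p.precursor_start)
            assert hairpin_check(mfe_fold(prec), span).is_hairpin

    def test_infeasible_packing_raises(self):
        cfg = dataclasses.replace(TINY, n_known=20, n_novel=0,
                                  genome_length=1_000)
        with pytest.raises(PackingError):
            make_genome(cfg)

    def test_validation_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            dataclasses.replace(TINY, contaminant_fraction=1.5).validate()
        with pytest.raises(ValueError):
            dataclasses.replace(TINY, length_mode_mir=(12, 23)).validate()


class TestSimulateReads:
    def test_read_total_and_label_partition(self):
        ds = simulate_dataset(TINY)
        assert len(ds.reads) == TINY.read_total
        assert len(ds.truth) == TINY.read_total
        assert ds.truth.read_id.is_unique
        assert set(ds.truth.label) <= {"mir-mature", "mir-star", "pirna-like",
                                       "contaminant", "adaptor-artifact"}
        assert ds.truth.label.value_counts().sum() == TINY.read_total

    def test_byte_identical_reruns(self):
        d1, d2 = simulate_dataset(TINY), simulate_dataset(TINY)
        assert d1.reads == d2.reads
        assert d1.truth.equals(d2.truth)
        assert d1.genome == d2.genome

    def test_expression_weight_ratio(self):
        # two miRNAs at 9:1 weights: read split within the binomial 99% CI
        cfg = dataclasses.replace(TINY, n_known=2, n_novel=0, n_pirna_loci=0,
                                  read_total=10_000, pirna_fraction=0.0,
                                  contaminant_fraction=0.0,
                                  artifact_fraction=0.0, star_fraction=0.0)
        genome, planted, loci = make_genome(cfg)
        planted = [dataclasses.replace(planted[0], expression_weight=9.0),
                   dataclasses.replace(planted[1], expression_weight=1.0)]
        reads, truth = simulate_reads(genome, planted, loci, cfg,
                                      make_contaminants(cfg),
                                      np.random.default_rng(77))
        counts = truth[truth.label == LABEL_MATURE].source.value_counts()
        n = counts.sum()
        lo, hi = stats.binom.interval(0.99, n, 0.9)
        assert lo <= counts[planted[0].name] <= hi

    def test_error_free_reads_match_genome_exactly(self):
        cfg = dataclasses.replace(TINY, error_rate=0.0)
        ds = simulate_dataset(cfg)
        g = ds.genome["chr1"]
        by_name = {p.name: p for p in ds.planted}
        mature = ds.truth[ds.truth.label == LABEL_MATURE]
        reads = dict((rid, seq) for rid, seq, _ in ds.reads)
        for _, row in mature.iterrows():
            p = by_name[row.source]
            insert = reads[row.read_id][:row.insert_len]
            assert insert == g[p.mature_start:p.mature_start + row.insert_len]

    def test_mode_lengths_respected(self):
        ds = simulate_dataset(TINY)
        m = ds.truth[ds.truth.label == LABEL_MATURE].insert_len
        p = ds.truth[ds.truth.label == "pirna-like"].insert_len
        assert m.between(*TINY.length_mode_mir).all()
        assert p.between(*TINY.length_mode_pirna).all()


class TestUtrAndAssays:
    def test_utr_carries_planted_sites(self):
        _, planted, _ = make_genome(TINY)
        _, utr = make_utr(planted, seed=1, site_mirs=2)
        from ovamir.seq import revcomp_dna, to_dna
        for p in [q for q in planted if q.known][:2]:
            assert revcomp_dna(to_dna(p.mature_seq)) in utr

    def test_qpcr_table_shape(self):
        # 3 biological x 3 technical rows per condition and target
        ct = simulate_qpcr({"miR-2": 4.0}, n_individuals=3)
        assert len(ct) == 3 * 2 * 3 * 2  # inds x stages x reps x (miR + U6)
        per = ct.groupby(["individual", "stage", "target"]).size()
        assert (per == 3).all()
        assert set(ct.stage) == {"GV", "MI"}

    def test_qpcr_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_qpcr({"m": 0.0})
        with pytest.raises(ValueError, match="individuals"):
            simulate_qpcr({"m": 2.0}, n_individuals=1)

    def test_luciferase_triplicates_and_validation(self):
        df = simulate_luciferase({"miR-2": 0.4})
        assert len(df) == 2 * 3  # NC + one mimic, triplicate
        assert (df.firefly > 0).all() and (df.renilla > 0).all()
        with pytest.raises(ValueError, match="knockdown"):
            simulate_luciferase({"m": 1.2})
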