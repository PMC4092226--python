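"""Planted-truth scoring of an annotation run.

Recovery here is deliberately strict: a reference-known planted miRNA
counts as recovered only if some tag was placed in group 1 with exactly
the planted name, and a reference-absent (novel) one only if a group-5
call's sequence lies within its precursor locus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import AnnotationResult
from .simlib import LABEL_MATURE, SimDataset


@dataclass(frozen=True)
class RecoveryReport:
    eligible_known: int
    recovered_known: int
    eligible_novel: int
    recovered_novel: int

    @property
    def known_rate(self) -> float:
        return (self.recovered_known / self.eligible_known
                if self.eligible_known else float("nan"))

    @property
    def novel_rate(self) -> float:
        return (self.recovered_novel / self.eligible_novel
                if self.eligible_novel else float("nan"))


def score_recovery(dataset: SimDataset, annotation: AnnotationResult,
                   min_copies: int = 10) -> RecoveryReport:
    """Compare group-1/group-5 calls against the planted truth.

    Known miRNAs enter the denominator when at least ``min_copies``
    mature-labeled reads were simulated for them; novel loci always do.
    """
    mature_counts = (dataset.truth[dataset.truth.label == LABEL_MATURE]
                     .groupby("source").size())
    g1_names = {c.assigned_name.rstrip("*") for c in annotation.calls
                if c.group == 1}
    g5_seqs = [c.seq for c in annotation.calls if c.group == 5]
    genome = dataset.genome

    eligible_known = recovered_known = 0
    eligible_novel = recovered_novel = 0
    for p in dataset.planted:
        if p.known:
            if mature_counts.get(p.name, 0) < min_copies:
                continue
            eligible_known += 1
            if p.name in g1_names:
                recovered_known += 1
        else:
            eligible_novel += 1
            locus = genome[p.contig][p.precursor_start:p.precursor_end]
            if any(s in locus for s in g5_seqs):
                recovered_novel += 1
    return RecoveryReport(eligible_known, recovered_known,
                          eligible_novel, recovered_novel)
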