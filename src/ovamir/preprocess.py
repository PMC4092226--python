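"""Raw FASTQ -> clean collapsed unique tags ("clean reads" stage).

Stage order is fixed: quality -> 3' adaptor trim -> contaminant removal
-> length window (15-30 nt) -> collapse to unique tags -> copy-number
floor (>= 3 by default, i.e. "more than two copies").  Contaminant
matching runs per read, before collapsing, so the removed-read
accounting stays simple.  Reads with no detectable adaptor are
discarded: in a small-RNA library an absent 3' adaptor means the insert
was at least as long as the read, outside the 15-30 nt window anyway.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "UniqueTag",
    "FilterReport",
    "PreprocessConfig",
    "ApproxSubstringIndex",
    "quality_filter",
    "trim_adaptor",
    "length_filter",
    "collapse",
    "copy_filter",
    "contaminant_filter",
    "length_histogram",
    "preprocess_reads",
]


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed read sequence with its copy number."""

    id: str
    seq: str
    count: int


@dataclass
class FilterReport:
    """Read/tag accounting across the cleanup stages (monotone by design)."""

    raw_reads: int = 0
    post_quality_reads: int = 0
    post_adaptor_reads: int = 0
    adaptor_artifacts: int = 0
    no_adaptor_reads: int = 0
    post_contaminant_reads: int = 0
    contaminant_removed: dict = field(default_factory=dict)
    post_length_reads: int = 0
    unique_tags: int = 0
    post_copy_tags: int = 0
    post_copy_reads: int = 0

    def read_counts(self) -> list[tuple[str, int]]:
        return [("raw", self.raw_reads),
                ("post_quality", self.post_quality_reads),
                ("post_adaptor", self.post_adaptor_reads),
                ("post_contaminant", self.post_contaminant_reads),
                ("post_length", self.post_length_reads),
                ("post_copy", self.post_copy_reads)]

    def is_monotone(self) -> bool:
        counts = [c for _, c in self.read_counts()]
        return all(a >= b for a, b in zip(counts, counts[1:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.read_counts(), columns=["stage", "reads"])


@dataclass
class PreprocessConfig:
    adaptor: str = "TCGTATGCCGTCTTCTGCTTG"
    min_mean_q: float = 20.0
    min_overlap: int = 6
    adaptor_max_mismatch: int = 1
    contaminant_max_mismatch: int = 1
    length_lo: int = 15
    length_hi: int = 30
    min_copy: int = 3


# --------------------------------------------------------------------------
# per-read filters
# --------------------------------------------------------------------------

def quality_filter(reads, min_mean_q: float = 20.0, drop_n: bool = True):
    """Keep reads whose mean PHRED(+33) quality is >= ``min_mean_q``.

    N-containing reads are dropped here too ("low resolution" reads).
    Malformed records (empty, length mismatch) raise ValueError naming
    the record index.
    """
    out = []
    for idx, (rid, seq, qual) in enumerate(reads):
        if not seq or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at index {idx} ({rid!r}): "
                             f"sequence/quality length mismatch")
        q = qual.encode("ascii")
        if sum(q) / len(q) - 33.0 < min_mean_q:
            continue
        if drop_n and "N" in seq:
            continue
        out.append((rid, seq, qual))
    return out


def trim_adaptor(seq: str, adaptor: str, min_overlap: int = 6,
                 max_mismatch: int = 1) -> tuple[str | None, str]:
    """Locate and strip the 3' adaptor from one read.

    The adaptor prefix is matched against every read suffix of length >=
    ``min_overlap``, leftmost exact occurrence first, then leftmost
    occurrence with <= ``max_mismatch`` substitutions.  Returns
    ``(insert, "trimmed")``, ``(None, "artifact")`` for a zero-length
    insert (adaptor-adaptor ligation) or ``(None, "no-adaptor")``.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    n, na = len(seq), len(adaptor)
    hit = -1
    for p in range(0, n - min_overlap + 1):
        ln = min(na, n - p)
        if seq[p:p + ln] == adaptor[:ln]:
            hit = p
            break
    if hit < 0 and max_mismatch > 0:
        for p in range(0, n - min_overlap + 1):
            ln = min(na, n - p)
            mm = 0
            for a, b in zip(seq[p:p + ln], adaptor[:ln]):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                hit = p
                break
    if hit < 0:
        return None, "no-adaptor"
    if hit == 0:
        return None, "artifact"
    return seq[:hit], "trimmed"


def length_filter(seqs, lo: int = 15, hi: int = 30):
    """Keep items whose sequence length is within [lo, hi] (inclusive)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    key = (lambda x: x.seq) if seqs and hasattr(seqs[0], "seq") else (lambda x: x)
    return [x for x in seqs if lo <= len(key(x)) <= hi]


def collapse(seqs) -> list[UniqueTag]:
    """Collapse sequences to unique tags, ordered by count desc then sequence."""
    counts = Counter(seqs)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [UniqueTag(id=f"t{i + 1:06d}", seq=s, count=c)
            for i, (s, c) in enumerate(ordered)]


def copy_filter(tags, min_copy: int = 3):
    if min_copy < 1:
        raise ValueError("min_copy must be >= 1")
    return [t for t in tags if t.count >= min_copy]


# --------------------------------------------------------------------------
# contaminant matching
# --------------------------------------------------------------------------

class ApproxSubstringIndex:
    """Find short queries inside reference sequences with few mismatches.

    k-mer pigeonhole index: a query matching with <= m substitutions has
    at least one of m+1 equal query segments error-free, so its leading
    k-mer anchors the candidate alignment; candidates are then verified
    base by base.  Exact for queries of length >= (m+1)*k.
    """

    def __init__(self, refs: list[str], k: int = 7):
        self.refs = refs
        self.k = k
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(refs):
            for pos in range(len(ref) - k + 1):
                self._index.setdefault(ref[pos:pos + k], []).append((ri, pos))

    def find(self, query: str, max_mm: int = 1) -> tuple[int, int, int] | None:
        """First (ref_idx, pos, mismatches) where query matches, else None."""
        L, k = len(query), self.k
        if L < (max_mm + 1) * k:
            # too short for pigeonhole anchoring: direct scan (rare path)
            for ri, ref in enumerate(self.refs):
                for start in range(len(ref) - L + 1):
                    mm = 0
                    for a, b in zip(query, ref[start:start + L]):
                        if a != b:
                            mm += 1
                            if mm > max_mm:
                                break
                    else:
                        return ri, start, mm
            return None
        seg = L // (max_mm + 1)
        seen = set()
        for s in range(max_mm + 1):
            off = s * seg
            for ri, pos in self._index.get(query[off:off + k], ()):
                start = pos - off
                if start < 0 or (ri, start) in seen:
                    continue
                seen.add((ri, start))
                ref = self.refs[ri]
                if start + L > len(ref):
                    continue
                mm = 0
                for a, b in zip(query, ref[start:start + L]):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    return ri, start, mm
        return None

    def find_all(self, query: str, max_mm: int = 0) -> list[tuple[int, int, int]]:
        """All (ref_idx, pos, mismatches) alignments of the query."""
        L, k = len(query), self.k
        if max_mm > 0 and L < (max_mm + 1) * k:
            # pigeonhole anchoring incomplete: direct scan (rare path)
            hits = []
            for ri, ref in enumerate(self.refs):
                for start in range(len(ref) - L + 1):
                    mm = 0
                    for a, b in zip(query, ref[start:start + L]):
                        if a != b:
                            mm += 1
                            if mm > max_mm:
                                break
                    else:
                        hits.append((ri, start, mm))
            return hits
        seg = max(k, L // (max_mm + 1))
        hits = []
        seen = set()
        for s in range(max_mm + 1):
            off = min(s * seg, L - k)
            for ri, pos in self._index.get(query[off:off + k], ()):
                start = pos - off
                if start < 0 or (ri, start) in seen:
                    continue
                seen.add((ri, start))
                ref = self.refs[ri]
                if start + L > len(ref):
                    continue
                mm = 0
                for a, b in zip(query, ref[start:start + L]):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    hits.append((ri, start, mm))
        return sorted(hits)


def contaminant_filter(items, contaminant_refs: dict[str, list[tuple[str, str]]],
                       max_mismatch: int = 1):
    """Drop sequences matching any labeled contaminant reference.

    ``items`` may be raw sequences, (id, seq, qual) read tuples or
    UniqueTag objects.  A sequence is contaminant if it occurs inside any
    reference of any class with <= ``max_mismatch`` substitutions over
    its full length.  Returns (kept, removed-per-class dict); empty
    classes are skipped.
    """
    indexes = {}
    for cls, refs in contaminant_refs.items():
        if refs:
            indexes[cls] = ApproxSubstringIndex([seq for _, seq in refs])
    removed = {cls: 0 for cls in indexes}

    def seq_of(x):
        if hasattr(x, "seq"):
            return x.seq
        if isinstance(x, tuple):
            return x[1]
        return x

    kept = []
    for item in items:
        s = seq_of(item)
        hit_cls = None
        for cls, idx in indexes.items():
            if idx.find(s, max_mismatch) is not None:
                hit_cls = cls
                break
        if hit_cls is None:
            kept.append(item)
        else:
            removed[hit_cls] += 1
    return kept, removed


# --------------------------------------------------------------------------
# profiling and orchestration
# --------------------------------------------------------------------------

def length_histogram(tags, lo: int = 15, hi: int = 30):
    """Per-length totals over [lo, hi] for reads and for unique tags."""
    reads = {ln: 0 for ln in range(lo, hi + 1)}
    unique = {ln: 0 for ln in range(lo, hi + 1)}
    for t in tags:
        ln = len(t.seq)
        if not lo <= ln <= hi:
            raise ValueError(f"tag {t.id} of length {ln} outside {lo}-{hi}")
        reads[ln] += t.count
        unique[ln] += 1
    return reads, unique


def preprocess_reads(reads, config: PreprocessConfig | None = None,
                     contaminant_refs: dict | None = None
                     ) -> tuple[list[UniqueTag], FilterReport]:
    """Run the full cleanup on an iterable of (id, seq, qual) records."""
    cfg = config or PreprocessConfig()
    reads = list(reads)
    report = FilterReport(raw_reads=len(reads))
    kept = quality_filter(reads, cfg.min_mean_q)
    report.post_quality_reads = len(kept)

    inserts = []
    for rid, seq, _ in kept:
        insert, flag = trim_adaptor(seq, cfg.adaptor, cfg.min_overlap,
                                    cfg.adaptor_max_mismatch)
        if flag == "trimmed":
            inserts.append(insert)
        elif flag == "artifact":
            report.adaptor_artifacts += 1
        else:
            report.no_adaptor_reads += 1
    report.post_adaptor_reads = len(inserts)

    if contaminant_refs:
        inserts, removed = contaminant_filter(inserts, contaminant_refs,
                                              cfg.contaminant_max_mismatch)
        report.contaminant_removed = removed
    report.post_contaminant_reads = len(inserts)

    inserts = length_filter(inserts, cfg.length_lo, cfg.length_hi)
    report.post_length_reads = len(inserts)

    tags = collapse(inserts)
    report.unique_tags = len(tags)
    tags = copy_filter(tags, cfg.min_copy)
    report.post_copy_tags = len(tags)
    report.post_copy_reads = sum(t.count for t in tags)
    return tags, report
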