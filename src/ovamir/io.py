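"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tag sets use miRDeep-style collapsed
FASTA headers (``>tagID_xCOUNT``); genome hits are BED6 (0-based
half-open, strand in column 6); tables are TSV with header rows.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) tuples; Sanger PHRED+33."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_tag_fasta(path, tags) -> None:
    """Collapsed unique tags as ``>id_xCOUNT`` FASTA."""
    write_fasta(path, ((f"{t.id}_x{t.count}", t.seq) for t in tags))


def read_tag_fasta(path):
    from .preprocess import UniqueTag
    out = []
    for name, seq in read_fasta(path).items():
        tag_id, _, count = name.rpartition("_x")
        out.append(UniqueTag(id=tag_id, seq=seq, count=int(count)))
    return out


BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def write_bed6(path, rows: Iterable[tuple]) -> None:
    """Rows of (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                     dtype={"contig": str, "start": int, "end": int,
                            "name": str, "strand": str})
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
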