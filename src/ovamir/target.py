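"""miRNA target-site discovery in a 3'-UTR.

The screen mirrors classic seed-based hybridisation search: a candidate
site is any UTR span exactly reverse-complementary (Watson-Crick only;
no G·U in the seed) to the miRNA seed (positions 2-8), optionally
labelled with the 3'-UTR box motif it falls in (GY-box / Brd-box /
K-box, motifs from the Drosophila E(spl)/Brd literature; the labels are
annotation only, never a filter).  Each site is then scored by the
minimum free energy of the intermolecular miRNA:site-context duplex
under the same nearest-neighbor table as the folding engine
(intramolecular pairs forbidden, affine bulge/internal penalties, no
dangling ends), and miRNAs are ranked by their best (smallest) site MFE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import energy as en
from .seq import encode_rna, revcomp_rna, to_rna

#: UTR-strand box motifs; literature-derived defaults, editable config
BOX_MOTIFS = {
    "GY-box": "GUCUUCC",
    "Brd-box": "AGCUUUA",
    "K-box": "UGUGAU",
}

SEED_START = 1   # 0-based; seed = miRNA positions 2-8 (1-based)
SEED_LEN = 7
MAX_DUPLEX_LEN = 60

__all__ = [
    "BOX_MOTIFS",
    "UtrRecord",
    "DuplexSite",
    "scan_seed_sites",
    "duplex_mfe",
    "duplex_energy",
    "find_targets",
    "rank_targets",
]


@dataclass(frozen=True)
class UtrRecord:
    """A 3'-UTR sequence, held in RNA space."""

    id: str
    seq: str
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "seq", to_rna(self.seq))


@dataclass(frozen=True)
class DuplexSite:
    """One miRNA binding site: location, seed class, duplex energy, rendering."""

    mirna_name: str
    utr_start: int
    utr_end: int
    seed_class: str
    duplex_mfe: float
    pairing: str = field(repr=False, default="")


def _classify_box(utr: str, start: int, end: int,
                  motifs: dict[str, str]) -> str:
    """Label a seed site with the box motif found at/around it (else generic).

    The motif must appear within the site span extended by 2 nt on each
    side -- the boxes are 6-8 nt and need not coincide exactly with the
    7-mer seed match.
    """
    window = utr[max(0, start - 2):end + 2]
    for name, motif in motifs.items():
        if to_rna(motif) in window:
            return name
    return "generic"


def scan_seed_sites(mirna: str, utr: UtrRecord,
                    motifs: dict[str, str] | None = None) -> list[tuple[int, int, str]]:
    """All UTR spans reverse-complementary to the miRNA seed (nt 2-8).

    Returns ``(start, end, seed_class)`` triples, 0-based half-open on
    the UTR.  Matching is exact Watson-Crick reverse complementarity of
    the 7-nt seed; ``seed_class`` is the box-motif label (decorative).
    """
    mirna = to_rna(mirna)
    if len(mirna) < SEED_START + SEED_LEN + 1:
        raise ValueError(f"miRNA {mirna!r} shorter than 9 nt")
    if motifs is None:
        motifs = BOX_MOTIFS
    seed = mirna[SEED_START:SEED_START + SEED_LEN]
    site = revcomp_rna(seed)
    hits = []
    pos = utr.seq.find(site)
    while pos != -1:
        hits.append((pos, pos + SEED_LEN,
                     _classify_box(utr.seq, pos, pos + SEED_LEN, motifs)))
        pos = utr.seq.find(site, pos + 1)
    return hits


# --------------------------------------------------------------------------
# intermolecular duplex MFE
# --------------------------------------------------------------------------

def duplex_energy(x: str, y: str, matching, allow_gu: bool = True) -> float:
    """Energy of an explicit antiparallel matching between strands x and y.

    ``matching`` is a sequence of (i, j) pairs, i ascending and j strictly
    descending (x 5'->3' against y 3'->5').  Consecutive pairs adjacent on
    both strands contribute a stack term; otherwise an affine
    bulge/internal penalty.  The empty matching has energy 0.  This is the
    objective the duplex DP minimises; it is shared with the exhaustive
    oracle.
    """
    cx, cy = encode_rna(x), encode_rna(y)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    m = list(matching)
    for k, (i, j) in enumerate(m):
        if not pair_ok[cx[i], cy[j]]:
            raise ValueError(f"bases at {(i, j)} cannot pair")
        if k and (i <= m[k - 1][0] or j >= m[k - 1][1]):
            raise ValueError("matching not antiparallel-monotone")
    total = 0.0
    for (i0, j0), (i1, j1) in zip(m, m[1:]):
        l1, l2 = i1 - i0 - 1, j0 - j1 - 1
        if l1 == 0 and l2 == 0:
            total += en.stack_energy((cx[i0], cy[j0]), (cx[i1], cy[j1]))
        elif l1 == 0 or l2 == 0:
            total += en.bulge_penalty(l1 + l2)
        else:
            total += en.internal_penalty(l1, l2)
    return total


def _duplex_dp(cx, cy, pair_ok):
    """D[i, j] = best energy of a matching whose last pair is (i, j)."""
    n, m = len(cx), len(cy)
    D = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if not pair_ok[cx[i], cy[j]]:
                continue
            best = 0.0  # (i, j) as the opening pair
            pij = 4 * cx[i] + cy[j]
            i0_min = max(0, i - en.MAX_LOOP - 1)
            j0_max = min(m - 1, j + en.MAX_LOOP + 1)
            for i0 in range(i0_min, i):
                for j0 in range(j + 1, j0_max + 1):
                    if D[i0, j0] == np.inf:
                        continue
                    l1, l2 = i - i0 - 1, j0 - j - 1
                    if l1 == 0 and l2 == 0:
                        step = en.STACK16[4 * cx[i0] + cy[j0], pij]
                    elif l1 == 0 or l2 == 0:
                        step = en.bulge_penalty(l1 + l2)
                    else:
                        step = en.internal_penalty(l1, l2)
                    e = D[i0, j0] + step
                    if e < best:
                        best = e
            D[i, j] = best
    return D


def _duplex_traceback(cx, cy, D):
    """Recover the pair list of the optimal duplex (deterministic priority)."""
    n, m = D.shape
    best = 0.0
    cell = None
    for i in range(n):
        for j in range(m):
            if D[i, j] < best:
                best, cell = D[i, j], (i, j)
    if cell is None:
        return []
    pairs = [cell]
    i, j = cell
    while D[i, j] != 0.0:
        target = D[i, j]
        pij = 4 * cx[i] + cy[j]
        found = False
        for i0 in range(i - 1, max(-1, i - en.MAX_LOOP - 2), -1):
            for j0 in range(j + 1, min(m, j + en.MAX_LOOP + 2)):
                if D[i0, j0] == np.inf:
                    continue
                l1, l2 = i - i0 - 1, j0 - j - 1
                if l1 == 0 and l2 == 0:
                    step = en.STACK16[4 * cx[i0] + cy[j0], pij]
                elif l1 == 0 or l2 == 0:
                    step = en.bulge_penalty(l1 + l2)
                else:
                    step = en.internal_penalty(l1, l2)
                if D[i0, j0] + step == target:
                    pairs.append((i0, j0))
                    i, j = i0, j0
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover
            raise AssertionError("duplex traceback failed")
    return sorted(pairs)


def _render_pairing(x: str, y: str, pairs) -> str:
    """Three-line text block: target context on top, bars, miRNA below.

    The miRNA (x) is written 3'->5' so paired columns line up with the
    target (y) written 5'->3', the usual hybridisation layout.
    """
    if not pairs:
        return f"target 5' {y} 3'\n          {' ' * len(y)}\nmirna  3' {x[::-1]} 5'"
    by_target = sorted(pairs, key=lambda p: p[1])  # ascending target index
    top, mid, bot = [], [], []
    pos_t, pos_m = 0, len(x) - 1

    def gap(t_to: int, m_to: int):
        t_seg = y[pos_t:t_to]
        m_seg = x[m_to + 1:pos_m + 1][::-1]
        w = max(len(t_seg), len(m_seg))
        top.append(t_seg.ljust(w, "-"))
        mid.append(" " * w)
        bot.append(m_seg.ljust(w, "-"))

    for i, j in by_target:
        gap(j, i)
        top.append(y[j])
        mid.append("|")
        bot.append(x[i])
        pos_t, pos_m = j + 1, i - 1
    gap(len(y), -1)
    return (f"target 5' {''.join(top)} 3'\n"
            f"          {''.join(mid)}\n"
            f"mirna  3' {''.join(bot)} 5'")


def duplex_mfe(mirna: str, site_context: str,
               allow_gu: bool = True) -> tuple[float, str]:
    """Minimum-energy intermolecular duplex between a miRNA and a site context.

    Dynamic programming over the two strands; intramolecular pairs are
    forbidden, bulge/internal loops are capped at 15 nt per side, and the
    empty duplex (energy 0) bounds the optimum from above.  Returns the
    energy (kcal/mol, <= 0) and a three-line pairing rendering.
    """
    x, y = to_rna(mirna), to_rna(site_context)
    if len(x) > MAX_DUPLEX_LEN or len(y) > MAX_DUPLEX_LEN:
        raise ValueError(f"duplex strands must be <= {MAX_DUPLEX_LEN} nt")
    cx, cy = encode_rna(x), encode_rna(y)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    D = _duplex_dp(cx, cy, pair_ok)
    finite = D[np.isfinite(D)]
    e = float(min(0.0, finite.min())) if finite.size else 0.0
    pairs = _duplex_traceback(cx, cy, D)
    return e, _render_pairing(x, y, pairs)


# --------------------------------------------------------------------------
# site discovery and ranking
# --------------------------------------------------------------------------

def find_targets(mirnas: dict[str, str], utr: UtrRecord, flank: int = 15,
                 mfe_max: float = 0.0,
                 motifs: dict[str, str] | None = None) -> list[DuplexSite]:
    """Scan every miRNA against the UTR and score each seed site.

    ``flank`` nt of UTR context on each side of the seed match enter the
    duplex scoring (hybridisation is local); sites with duplex MFE above
    ``mfe_max`` are dropped.
    """
    sites = []
    for name in sorted(mirnas):
        mirna = to_rna(mirnas[name])
        for start, end, seed_class in scan_seed_sites(mirna, utr, motifs):
            ctx = utr.seq[max(0, start - flank):min(len(utr.seq), end + flank)]
            e, pairing = duplex_mfe(mirna, ctx)
            if e <= mfe_max:
                sites.append(DuplexSite(mirna_name=name, utr_start=start,
                                        utr_end=end, seed_class=seed_class,
                                        duplex_mfe=e, pairing=pairing))
    return sites


def rank_targets(sites: list[DuplexSite]) -> list[DuplexSite]:
    """Best site per miRNA, ordered by ascending duplex MFE (ties by position)."""
    best: dict[str, DuplexSite] = {}
    for s in sites:
        cur = best.get(s.mirna_name)
        if (cur is None or s.duplex_mfe < cur.duplex_mfe
                or (s.duplex_mfe == cur.duplex_mfe and s.utr_start < cur.utr_start)):
            best[s.mirna_name] = s
    return sorted(best.values(), key=lambda s: (s.duplex_mfe, s.utr_start))
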