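"""Exhaustive reference implementations for the two energy minimisations.

These enumerate every admissible structure (all nested pair sets for
folding; all antiparallel monotone matchings for duplexes) and evaluate
each with the shared model definition.  They are exponential-time
reference oracles for testing the dynamic programs on short inputs --
never use them on sequences beyond ~18 nt.
"""

from __future__ import annotations

from functools import lru_cache

from . import energy as en
from .fold import structure_energy
from .seq import encode_rna
from .target import duplex_energy


def enumerate_structures(seq: str, allow_gu: bool = True):
    """All nested structures (tuples of pairs) with hairpin loops >= 3 nt."""
    codes = encode_rna(seq)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    n = len(codes)

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> tuple:
        if j - i < 4:
            return ((),)
        out = list(f(i, j - 1))  # j unpaired
        for k in range(i, j - en.MIN_HAIRPIN):
            if pair_ok[codes[k], codes[j]]:
                for left in f(i, k - 1):
                    for inner in f(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        return tuple(out)

    return f(0, n - 1)


def brute_mfe(seq: str, allow_gu: bool = True) -> float:
    """Minimum structure energy by full enumeration (0 for the open chain).

    Structures containing over-long loops evaluate to +inf and drop out of
    the minimum automatically.
    """
    best = 0.0
    for pairs in enumerate_structures(seq, allow_gu=allow_gu):
        e = structure_energy(seq, sorted(pairs), allow_gu=allow_gu)
        if e < best:
            best = e
    return best


def enumerate_duplex_matchings(x: str, y: str, allow_gu: bool = True):
    """All antiparallel monotone matchings between two strands.

    Pairs are (i, j) with i ascending in x and j descending in y, gaps
    between consecutive pairs capped at MAX_LOOP per strand (matching the
    DP's admissible set).  Yields tuples of pairs, including the empty
    matching.
    """
    cx, cy = encode_rna(x), encode_rna(y)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    n, m = len(cx), len(cy)

    def rec(last_i, last_j, current):
        yield tuple(current)
        if last_i is None:
            i_range = range(n)
        else:
            i_range = range(last_i + 1, min(n, last_i + en.MAX_LOOP + 2))
        for i in i_range:
            if last_j is None:
                j_range = range(m - 1, -1, -1)
            else:
                j_range = range(last_j - 1, max(-1, last_j - en.MAX_LOOP - 2), -1)
            for j in j_range:
                if pair_ok[cx[i], cy[j]]:
                    current.append((i, j))
                    yield from rec(i, j, current)
                    current.pop()

    yield from rec(None, None, [])


def brute_duplex_mfe(x: str, y: str, allow_gu: bool = True) -> float:
    """Minimum duplex energy by full enumeration of matchings."""
    best = 0.0
    for matching in enumerate_duplex_matchings(x, y, allow_gu=allow_gu):
        if matching:
            e = duplex_energy(x, y, matching, allow_gu=allow_gu)
            if e < best:
                best = e
    return best
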