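"""Simplified nearest-neighbor energy model shared by the fold and target engines.

The model scores a secondary structure (or an intermolecular duplex) as

    sum of stacking terms over directly adjacent pairs
  + affine length penalties for hairpin loops, bulges and internal loops
  + an affine multibranch-loop term (closing penalty + per-branch + per-unpaired)

Stacking free energies for Watson-Crick steps are classic 37 degC
nearest-neighbor values (kcal/mol); every step involving a G·U wobble is
assigned a single weak constant so that wobbles are permitted but never
preferred over a Watson-Crick alternative. This is deliberately not the
full Turner model (no dangles, no terminal-AU penalties, no tetraloop
bonuses): the point is a self-consistent, exhaustively enumerable model,
not reproduction of any particular server's kcal/mol.

All energies are kcal/mol; lower is more stable.
"""

from __future__ import annotations

import numpy as np

INF = np.inf

#: hairpin loops shorter than this are sterically impossible
MIN_HAIRPIN = 3
#: maximum unpaired length per side of a bulge/internal loop
MAX_LOOP = 15

# --- affine loop penalties -------------------------------------------------

HAIRPIN_A, HAIRPIN_B = 5.4, 0.25   # H(s) = A + B*(s - 3),  s >= 3
BULGE_A, BULGE_B = 3.8, 0.30       # B(s) = A + B*(s - 1),  s >= 1
INTERNAL_A, INTERNAL_B = 4.0, 0.30  # I(s) = A + B*(s - 2), s >= 2 (total length)

# multibranch loop: ML_A (closing) + ML_B per branch incl. the closing pair
# + ML_C per unpaired base inside the loop
ML_A, ML_B, ML_C = 4.6, 0.4, 0.1

#: energy of every stack step containing at least one G·U pair
GU_STACK = -0.5


def hairpin_penalty(size: int) -> float:
    if size < MIN_HAIRPIN:
        return INF
    return HAIRPIN_A + HAIRPIN_B * (size - MIN_HAIRPIN)


def bulge_penalty(size: int) -> float:
    if size < 1 or size > MAX_LOOP:
        return INF
    return BULGE_A + BULGE_B * (size - 1)


def internal_penalty(l1: int, l2: int) -> float:
    if l1 < 1 or l2 < 1 or l1 > MAX_LOOP or l2 > MAX_LOOP:
        return INF
    return INTERNAL_A + INTERNAL_B * (l1 + l2 - 2)


# --- pairing rules ---------------------------------------------------------

_WC = {(0, 3), (3, 0), (1, 2), (2, 1)}           # A·U, U·A, C·G, G·C
_GU = {(2, 3), (3, 2)}                           # G·U, U·G


def pair_matrix(allow_gu: bool = True) -> np.ndarray:
    """4x4 boolean matrix of allowed pairs over the A/C/G/U code."""
    m = np.zeros((4, 4), dtype=np.bool_)
    for a, b in _WC:
        m[a, b] = True
    if allow_gu:
        for a, b in _GU:
            m[a, b] = True
    return m


# Canonical Watson-Crick stack values, keyed by (outer pair, inner pair)
# where a stack is the step 5'-X1 X2-3' / 3'-Y1 Y2-5', outer = X1·Y1,
# inner = X2·Y2.  Rotational symmetry E[(a,b),(c,d)] = E[(d,c),(b,a)]
# closes the table.
_WC_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,   # AA/UU
    (("A", "U"), ("U", "A")): -1.10,   # AU/AU
    (("U", "A"), ("A", "U")): -1.33,   # UA/UA
    (("C", "G"), ("U", "A")): -2.08,   # CU/GA
    (("C", "G"), ("A", "U")): -2.11,   # CA/GU
    (("G", "C"), ("U", "A")): -2.24,   # GU/CA
    (("G", "C"), ("A", "U")): -2.35,   # GA/CU
    (("C", "G"), ("G", "C")): -2.36,   # CG/GC
    (("G", "C"), ("G", "C")): -3.26,   # GG/CC
    (("G", "C"), ("C", "G")): -3.42,   # GC/CG
}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pair_code(a: str, b: str) -> int:
    return 4 * _CODE[a] + _CODE[b]


def stack_table() -> np.ndarray:
    """16x16 table of stack energies indexed by (outer, inner) pair codes.

    A pair code is ``4*base5p + base3p``.  Entries for non-pair codes are
    +inf; GU-containing steps all share the flat :data:`GU_STACK` value.
    """
    t = np.full((16, 16), INF, dtype=np.float64)
    bases = "ACGU"
    pairs_wc = [(bases[a], bases[b]) for a, b in _WC]
    pairs_gu = [(bases[a], bases[b]) for a, b in _GU]
    # WC x WC from the canonical dict + rotational closure
    for (p, q), e in _WC_STACKS.items():
        t[_pair_code(*p), _pair_code(*q)] = e
        rot_p = (q[1], q[0])
        rot_q = (p[1], p[0])
        t[_pair_code(*rot_p), _pair_code(*rot_q)] = e
    # any step touching a GU pair
    for p in pairs_wc + pairs_gu:
        for q in pairs_gu:
            t[_pair_code(*p), _pair_code(*q)] = GU_STACK
            t[_pair_code(*q), _pair_code(*p)] = GU_STACK
    for p in pairs_gu:
        for q in pairs_gu:
            t[_pair_code(*p), _pair_code(*q)] = GU_STACK
    return t


#: module-level singletons used by the DP kernels
STACK16 = stack_table()
PAIR_OK = pair_matrix(allow_gu=True)
PAIR_OK_WC = pair_matrix(allow_gu=False)


def stack_energy(outer: tuple[int, int], inner: tuple[int, int]) -> float:
    """Stack term for outer pair (i,j) on inner pair (i+1,j-1), by base codes."""
    return float(STACK16[4 * outer[0] + outer[1], 4 * inner[0] + inner[1]])
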