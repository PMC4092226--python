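"""RNA secondary-structure engine.

Minimum-free-energy folding of short sequences (precursor candidates are
~60-200 nt) under the simplified nearest-neighbor model in
:mod:`ovamir.energy`, plus the two consumers the annotation stage needs:

* :func:`extend_context` -- cut the genomic windows (default +/-60 nt on
  both sides, plus the two single-sided windows) around a mapped tag that
  serve as precursor candidates;
* :func:`hairpin_check` -- decide whether a fold is a single stem-loop
  that could plausibly be a miRNA precursor (one terminal loop, energy
  below a cutoff, the mature tag on one arm and mostly paired).

The DP is a Zuker-style recursion (paired-interval table V, multibranch
helper WM, external prefix W) with nested structures only, minimum
hairpin loop 3, optional G·U wobbles, and affine loop penalties.  The
kernel is JIT-compiled with numba when available and falls back to the
identical pure-Python function otherwise.

Energies of explicit structures are evaluated by :func:`structure_energy`,
which is shared with the exhaustive enumeration oracle used in testing --
the model definition is common, the optimisation paths are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import energy as en
from .seq import encode_rna, revcomp_dna, to_rna

MAX_FOLD_LEN = 1000

__all__ = [
    "FoldResult",
    "FoldCandidate",
    "HairpinVerdict",
    "mfe_fold",
    "structure_energy",
    "hairpin_check",
    "extend_context",
    "pairs_to_dotbracket",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldResult:
    """An MFE structure: sequence, nested pair list, energy, dot-bracket."""

    seq: str
    pairs: tuple[tuple[int, int], ...]
    energy: float
    dotbracket: str

    def partner(self) -> dict[int, int]:
        """Map each paired position to its partner."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def to_vienna(self) -> str:
        """Sequence + structure + energy in RNAfold-style text."""
        return f"{self.seq}\n{self.dotbracket} ({self.energy:.2f})"


@dataclass(frozen=True)
class HairpinVerdict:
    """Stem-loop diagnostics for a fold with respect to a mature span."""

    is_hairpin: bool
    n_stems: int
    mature_arm: str            # "5p" | "3p" | "none"
    mature_paired_frac: float
    energy: float


@dataclass(frozen=True)
class FoldCandidate:
    """A genomic window cut around a mapped tag, oriented to the hit strand."""

    label: str                 # "both" | "left" | "right"
    contig: str
    window_start: int          # genome coords, 0-based half-open
    window_end: int
    seq: str                   # RNA, hit-strand orientation
    mature_span: tuple[int, int]  # tag location within seq, half-open
    truncated: bool = False


# --------------------------------------------------------------------------
# DP kernel (numba-jitted when available)
# --------------------------------------------------------------------------

def _fold_kernel(codes, pair_ok, stack16, loop_pen, hairpin_pen,
                 ml_a, ml_b, ml_c, max_loop):
    n = codes.shape[0]
    INF = np.inf
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    Wext = np.zeros(n + 1)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # ---- V[i, j]: (i, j) paired
            if pair_ok[codes[i], codes[j]] and span >= 4:
                pij = 4 * codes[i] + codes[j]
                best = hairpin_pen[span - 1]
                # stack on inner pair
                if V[i + 1, j - 1] < INF:
                    pin = 4 * codes[i + 1] + codes[j - 1]
                    e = stack16[pij, pin] + V[i + 1, j - 1]
                    if e < best:
                        best = e
                # bulge / internal loops
                ip_max = i + max_loop + 1
                if ip_max > j - 1:
                    ip_max = j - 1
                for ip in range(i + 1, ip_max + 1):
                    l1 = ip - i - 1
                    jp_min = j - 1 - max_loop
                    if jp_min < ip + 1:
                        jp_min = ip + 1
                    for jp in range(jp_min, j):
                        l2 = j - jp - 1
                        if l1 == 0 and l2 == 0:
                            continue
                        if V[ip, jp] < INF:
                            e = loop_pen[l1, l2] + V[ip, jp]
                            if e < best:
                                best = e
                # multibranch
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # ---- WM[i, j]: multiloop segment with >= 1 branch
            wm = INF
            if V[i, j] < INF:
                wm = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < wm:
                wm = WM[i, j - 1] + ml_c
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    e = WM[i, k - 1] + WM[k, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    for j in range(n):
        w = Wext[j]
        for i in range(0, j + 1):
            if V[i, j] < INF:
                e = Wext[i] + V[i, j]
                if e < w:
                    w = e
        Wext[j + 1] = w
    return V, WM, Wext


_KERNEL = None


def _get_kernel():
    global _KERNEL
    if _KERNEL is None:
        try:
            from numba import njit
            _KERNEL = njit(cache=True)(_fold_kernel)
        except ImportError:  # pragma: no cover - numba present in practice
            _KERNEL = _fold_kernel
    return _KERNEL


def _hairpin_pen_array(n: int) -> np.ndarray:
    h = np.full(n + 1, np.inf)
    for s in range(en.MIN_HAIRPIN, n + 1):
        h[s] = en.hairpin_penalty(s)
    return h


def _loop_pen_array() -> np.ndarray:
    lp = np.full((en.MAX_LOOP + 1, en.MAX_LOOP + 1), np.inf)
    for l1 in range(en.MAX_LOOP + 1):
        for l2 in range(en.MAX_LOOP + 1):
            if l1 == 0 and l2 == 0:
                continue
            if l1 == 0 or l2 == 0:
                lp[l1, l2] = en.bulge_penalty(l1 + l2)
            else:
                lp[l1, l2] = en.internal_penalty(l1, l2)
    return lp


_LOOP_PEN = _loop_pen_array()


# --------------------------------------------------------------------------
# traceback
# --------------------------------------------------------------------------

def _traceback(codes, V, WM, Wext, pair_ok, stack16, hairpin_pen):
    """Recover one optimal structure with a fixed deterministic priority.

    At every decision the first option (in the order stack > bulge/internal
    by increasing loop sizes > multibranch by smallest split > hairpin)
    whose recomputed energy equals the stored optimum is taken, so
    identical input always yields the identical structure.
    """
    n = codes.shape[0]
    pairs: list[tuple[int, int]] = []
    ml_a, ml_b, ml_c = en.ML_A, en.ML_B, en.ML_C

    def trace_v(i, j):
        pairs.append((i, j))
        pij = 4 * codes[i] + codes[j]
        target = V[i, j]
        if V[i + 1, j - 1] != np.inf:
            pin = 4 * codes[i + 1] + codes[j - 1]
            if stack16[pij, pin] + V[i + 1, j - 1] == target:
                trace_v(i + 1, j - 1)
                return
        for ip in range(i + 1, min(i + en.MAX_LOOP + 1, j - 1) + 1):
            l1 = ip - i - 1
            for jp in range(max(j - 1 - en.MAX_LOOP, ip + 1), j):
                l2 = j - jp - 1
                if l1 == 0 and l2 == 0:
                    continue
                if V[ip, jp] != np.inf and _LOOP_PEN[l1, l2] + V[ip, jp] == target:
                    trace_v(ip, jp)
                    return
        for k in range(i + 1, j - 1):
            if WM[i + 1, k] != np.inf and WM[k + 1, j - 1] != np.inf:
                if ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1] == target:
                    trace_wm(i + 1, k)
                    trace_wm(k + 1, j - 1)
                    return
        if hairpin_pen[j - i - 1] == target:
            return
        raise AssertionError("fold traceback failed in V")  # pragma: no cover

    def trace_wm(i, j):
        target = WM[i, j]
        if V[i, j] != np.inf and V[i, j] + ml_b == target:
            trace_v(i, j)
            return
        if i + 1 <= j and WM[i + 1, j] + ml_c == target:
            trace_wm(i + 1, j)
            return
        if i <= j - 1 and WM[i, j - 1] + ml_c == target:
            trace_wm(i, j - 1)
            return
        for k in range(i + 1, j):
            if WM[i, k - 1] != np.inf and WM[k, j] != np.inf:
                if WM[i, k - 1] + WM[k, j] == target:
                    trace_wm(i, k - 1)
                    trace_wm(k, j)
                    return
        raise AssertionError("fold traceback failed in WM")  # pragma: no cover

    j = n - 1
    while j >= 0:
        target = Wext[j + 1]
        done = False
        for i in range(0, j + 1):
            if V[i, j] != np.inf and Wext[i] + V[i, j] == target:
                trace_v(i, j)
                j = i - 1
                done = True
                break
        if not done:
            # j unpaired
            j -= 1
    return sorted(pairs)


def pairs_to_dotbracket(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def mfe_fold(seq: str, allow_gu: bool = True) -> FoldResult:
    """Fold an RNA (or DNA; T is read as U) sequence to its MFE structure.

    Returns a :class:`FoldResult`; the empty structure (energy 0) is
    returned when no negative-energy structure exists.  Raises
    ``ValueError`` on characters outside ACGU/ACGT or absurd lengths.
    """
    rna = to_rna(seq)
    if not 1 <= len(rna) <= MAX_FOLD_LEN:
        raise ValueError(f"sequence length {len(rna)} outside 1..{MAX_FOLD_LEN}")
    codes = encode_rna(rna)
    n = len(codes)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    hp = _hairpin_pen_array(n)
    kernel = _get_kernel()
    V, WM, Wext = kernel(codes, pair_ok, en.STACK16, _LOOP_PEN, hp,
                         en.ML_A, en.ML_B, en.ML_C, en.MAX_LOOP)
    e = float(Wext[n])
    pairs = _traceback(codes, V, WM, Wext, pair_ok, en.STACK16, hp)
    return FoldResult(seq=rna, pairs=tuple(pairs), energy=e,
                      dotbracket=pairs_to_dotbracket(n, pairs))


def _loop_tree(n: int, pairs):
    """Parse a nested pair list into (children-per-node, root children).

    Nodes are pair tuples; ``None`` is the exterior.  Raises ValueError on
    crossing pairs or positions paired twice.
    """
    opens = {}
    closes = {}
    for i, j in pairs:
        if not 0 <= i < j < n:
            raise ValueError(f"pair {(i, j)} out of range")
        if i in opens or i in closes or j in opens or j in closes:
            raise ValueError("position paired twice")
        opens[i] = (i, j)
        closes[j] = (i, j)
    children: dict = {None: []}
    stack = [None]
    for pos in range(n):
        if pos in opens:
            node = opens[pos]
            children[stack[-1]].append(node)
            children[node] = []
            stack.append(node)
        elif pos in closes:
            if stack[-1] != closes[pos]:
                raise ValueError("crossing (pseudoknotted) pairs")
            stack.pop()
    return children


def structure_energy(seq: str, pairs, allow_gu: bool = True) -> float:
    """Energy of an explicit structure under the package's model.

    Shared definition between the DP and the exhaustive oracle: the DP
    minimises exactly this quantity.  Returns ``inf`` when the structure
    contains an over-long bulge/internal loop; raises ``ValueError`` for
    malformed structures (crossing pairs, non-pairable bases, hairpin
    loops shorter than 3 nt).
    """
    codes = encode_rna(seq)
    n = len(codes)
    pair_ok = en.PAIR_OK if allow_gu else en.PAIR_OK_WC
    for i, j in pairs:
        if not pair_ok[codes[i], codes[j]]:
            raise ValueError(f"bases at {(i, j)} cannot pair")
    children = _loop_tree(n, pairs)
    total = 0.0
    for node, kids in children.items():
        if node is None:
            continue  # exterior loop is free
        i, j = node
        if not kids:
            size = j - i - 1
            if size < en.MIN_HAIRPIN:
                raise ValueError(f"hairpin loop of {size} nt at pair {(i, j)}")
            total += en.hairpin_penalty(size)
        elif len(kids) == 1:
            p, q = kids[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                total += en.stack_energy((codes[i], codes[j]),
                                         (codes[p], codes[q]))
            elif l1 == 0 or l2 == 0:
                total += en.bulge_penalty(l1 + l2)
            else:
                total += en.internal_penalty(l1, l2)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += en.ML_A + en.ML_B * (1 + len(kids)) + en.ML_C * unpaired
    return total


def hairpin_check(fold: FoldResult, mature_span: tuple[int, int],
                  energy_max: float = -18.0,
                  pair_min: float = 0.6) -> HairpinVerdict:
    """Judge whether a fold is a miRNA-precursor-like single stem-loop.

    ``is_hairpin`` requires all of: exactly one terminal (hairpin) loop,
    ``energy <= energy_max`` (kcal/mol), the mature span lying entirely on
    one arm without reaching into the terminal loop, and at least
    ``pair_min`` of the mature bases paired.
    """
    n = len(fold.seq)
    a, b = mature_span
    if not 0 <= a < b <= n:
        raise ValueError(f"mature span {mature_span} outside sequence of {n} nt")
    children = _loop_tree(n, fold.pairs)
    terminal = [node for node, kids in children.items()
                if node is not None and not kids]
    n_stems = len(terminal)
    partner = fold.partner()
    paired = sum(1 for p in range(a, b) if p in partner)
    frac = paired / (b - a)
    arm = "none"
    if n_stems == 1:
        p, q = terminal[0]  # innermost pair closing the single terminal loop
        if b <= p + 1:
            arm = "5p"
        elif a >= q:
            arm = "3p"
    ok = (n_stems == 1 and fold.energy <= energy_max
          and arm != "none" and frac >= pair_min)
    return HairpinVerdict(is_hairpin=ok, n_stems=n_stems, mature_arm=arm,
                          mature_paired_frac=frac, energy=fold.energy)


def extend_context(genome, hit, flank: int = 60) -> list[FoldCandidate]:
    """Cut precursor-candidate windows around a genome hit.

    ``genome`` is a contig-name -> DNA-string mapping (a bare string is
    treated as a single contig named ``"genome"``); ``hit`` is
    ``(contig, start, end, strand)`` with 0-based half-open coordinates.
    Returns the symmetric window (both directions) plus the two
    single-sided windows, each oriented to the hit strand and carrying the
    tag location within the window.  Windows are truncated (and flagged)
    at contig ends; an unknown contig raises ``KeyError``.
    """
    if isinstance(genome, str):
        genome = {"genome": genome}
    contig, start, end, strand = hit
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not in genome")
    ref = genome[contig]
    n = len(ref)
    out = []
    for label, ws_want, we_want in (
        ("both", start - flank, end + flank),
        ("left", start - flank, end),
        ("right", start, end + flank),
    ):
        ws, we = max(0, ws_want), min(n, we_want)
        truncated = (ws != ws_want) or (we != we_want)
        window = ref[ws:we]
        if strand == "-":
            window = revcomp_dna(window)
            span = (we - end, we - start)
        else:
            span = (start - ws, end - ws)
        out.append(FoldCandidate(label=label, contig=contig, window_start=ws,
                                 window_end=we, seq=to_rna(window),
                                 mature_span=span, truncated=truncated))
    return out
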