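"""Planted-truth simulator for an ovarian small-RNA sequencing library.

Everything downstream of the sequencer is testable against this module:
it writes a synthetic genome with planted miRNA hairpin loci and
piRNA-like loci, emits a read library whose length distribution is
bimodal (a 21-23 nt miRNA-like mode and a taller 24-27 nt piRNA-like
mode, the shape seen in crustacean and insect ovaries), heavy-tailed
per-miRNA abundances (log-normal weights), 3' adaptor on every read,
adaptor-adaptor ligation artifacts, contaminant reads drawn from
user-visible mRNA/structural-RNA/repeat reference sets, a configurable
fraction of low-quality reads, and uniform substitution errors.  A truth
table labels every read.

Planted hairpins are constructed so the fold module provably accepts
them: the precursor is 5'ext + mature + loop + star(= reverse complement
of the mature, with up to 2 designed wobbles) + 3'ext, and the loop,
extensions and the genomic flanks written around each locus are drawn
from the A/C alphabet, which cannot base-pair internally -- so the
+/-60 nt extension window folds to exactly the designed stem.  Real
genomic flanks are structured; see docs/methods.md for what this does
and does not test.

It also simulates the two wet-lab assay tables (qPCR Ct values against a
U6 control, dual-luciferase firefly/renilla readings) with known ground
truth for the statistics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq import revcomp_dna, to_dna, to_rna

DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"  # classic Solexa 3' adaptor

LABEL_MATURE = "mir-mature"
LABEL_STAR = "mir-star"
LABEL_PIRNA = "pirna-like"
LABEL_CONTAMINANT = "contaminant"
LABEL_ARTIFACT = "adaptor-artifact"

CONTAMINANT_CLASSES = ("mRNA-like", "Rfam-like", "repeat-like")

_AC = np.array(list("AC"))
_ACGT = np.array(list("ACGT"))


class PackingError(ValueError):
    """Raised when the requested loci cannot be placed in the genome."""


@dataclass(frozen=True)
class PlantedMir:
    """A miRNA locus written into the synthetic genome.

    The mature sits on the 5' arm, the star on the 3' arm (the
    arrangement reported for the sequenced star reads).  Coordinates are
    0-based half-open on the plus strand of the single contig.
    """

    name: str
    mature_seq: str          # RNA
    star_seq: str            # RNA
    contig: str
    precursor_start: int
    precursor_end: int
    strand: str
    mature_start: int        # genome coords
    mature_end: int
    star_start: int
    star_end: int
    expression_weight: float
    known: bool              # True -> included in the species reference set

    @property
    def precursor_locus(self) -> tuple[str, int, int, str]:
        return (self.contig, self.precursor_start, self.precursor_end, self.strand)


@dataclass
class SimConfig:
    """Study-condition knobs for the simulator.

    Defaults emulate the sequenced library's structure at desk scale:
    bimodal 15-30 nt lengths with modes 21-23 and 24-27 (the long mode
    more abundant), log-normal per-miRNA abundance skew, ~5% contaminant
    reads, a small adaptor-dimer class, and a planted split of
    reference-known versus reference-absent (novel) miRNA loci.
    """

    genome_length: int = 20_000
    n_known: int = 20
    n_novel: int = 10
    n_pirna_loci: int = 30
    read_total: int = 200_000
    read_length: int = 36
    adaptor_seq: str = DEFAULT_ADAPTOR
    error_rate: float = 0.001
    contaminant_fraction: float = 0.05
    artifact_fraction: float = 0.02
    pirna_fraction: float = 0.55
    low_quality_fraction: float = 0.05
    star_fraction: float = 0.10
    length_mode_mir: tuple[int, int] = (21, 23)
    length_mode_pirna: tuple[int, int] = (24, 27)
    expression_sigma: float = 1.5
    max_stem_mismatches: int = 2
    mature_len: int = 22
    loop_len: int = 8
    ext_len: int = 10
    plant_flank: int = 70
    q_good: int = 35
    q_low: int = 12
    seed: int = 0

    @property
    def n_mirs(self) -> int:
        return self.n_known + self.n_novel

    def validate(self) -> None:
        fracs = (self.contaminant_fraction, self.artifact_fraction,
                 self.pirna_fraction, self.low_quality_fraction,
                 self.star_fraction, self.error_rate)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if self.contaminant_fraction + self.artifact_fraction + self.pirna_fraction > 1.0:
            raise ValueError("read-class fractions exceed 1")
        if self.read_total <= 0:
            raise ValueError("read_total must be positive")
        for lo, hi in (self.length_mode_mir, self.length_mode_pirna):
            if not 15 <= lo <= hi <= 30:
                raise ValueError("length modes must lie within 15-30 nt")
        if self.n_mirs and self.genome_length < 50 * self.n_mirs:
            raise ValueError("genome_length must be >= 50 x n_mirs")


@dataclass
class SimDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    genome: dict[str, str]
    planted: list[PlantedMir]
    pirna_loci: list[tuple[str, int, int]]
    contaminants: dict[str, list[tuple[str, str]]]
    reads: list[tuple[str, str, str]]          # (id, seq, qual)
    truth: pd.DataFrame                        # read_id, label, source
    def true_mir_counts(self) -> pd.Series:
        mir = self.truth[self.truth.label.isin([LABEL_MATURE, LABEL_STAR])]
        return mir.groupby("source").size()


# --------------------------------------------------------------------------
# genome construction
# --------------------------------------------------------------------------

def _random_seq(rng, alphabet, n) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), n)])


def _design_precursor(rng, cfg: SimConfig) -> tuple[str, str, str, int, int]:
    """Return (precursor DNA, mature DNA, star DNA, mature offset, star offset)."""
    mature = _random_seq(rng, _ACGT, cfg.mature_len)
    star = revcomp_dna(mature)
    n_mm = int(rng.integers(0, cfg.max_stem_mismatches + 1))
    if n_mm:
        pos = rng.choice(cfg.mature_len, size=n_mm, replace=False)
        star_l = list(star)
        for p in pos:
            choices = [b for b in "ACGT" if b != star_l[p]]
            star_l[p] = choices[int(rng.integers(0, 3))]
        star = "".join(star_l)
    loop = _random_seq(rng, _AC, cfg.loop_len)
    ext5 = _random_seq(rng, _AC, cfg.ext_len)
    ext3 = _random_seq(rng, _AC, cfg.ext_len)
    precursor = ext5 + mature + loop + star + ext3
    m_off = len(ext5)
    s_off = len(ext5) + cfg.mature_len + cfg.loop_len
    return precursor, mature, star, m_off, s_off


def make_genome(config: SimConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, str], list[PlantedMir], list[tuple[str, int, int]]]:
    """Build the synthetic genome with planted miRNA and piRNA-like loci.

    Loci (precursor plus its low-structure flanks) never overlap; raises
    :class:`PackingError` when they cannot be placed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contig = "chr1"
    genome = list(_random_seq(rng, _ACGT, config.genome_length))
    occupied: list[tuple[int, int]] = []

    def place(footprint: int) -> int:
        for _ in range(200 * max(1, config.n_mirs + config.n_pirna_loci)):
            start = int(rng.integers(0, max(1, config.genome_length - footprint)))
            if all(start + footprint <= a or start >= b for a, b in occupied):
                occupied.append((start, start + footprint))
                return start
        raise PackingError(
            f"cannot place a {footprint} nt locus in a {config.genome_length} nt "
            f"genome already holding {len(occupied)} loci")

    from .fold import hairpin_check, mfe_fold  # deferred: fold never imports simlib

    weights = rng.lognormal(mean=0.0, sigma=config.expression_sigma,
                            size=config.n_mirs) if config.n_mirs else np.array([])
    planted: list[PlantedMir] = []
    for k in range(config.n_mirs):
        known = k < config.n_known
        name = f"mir-k{k + 1:02d}" if known else f"mir-n{k - config.n_known + 1:02d}"
        # construction by design: redraw until the precursor provably passes
        # the fold module's hairpin criteria (a random mature occasionally
        # folds on itself and displaces the designed stem)
        for _attempt in range(100):
            precursor, mature, star, m_off, s_off = _design_precursor(rng, config)
            verdict = hairpin_check(mfe_fold(precursor),
                                    (m_off, m_off + len(mature)))
            if verdict.is_hairpin:
                break
        else:  # pragma: no cover - 100 redraws never exhausted in practice
            raise RuntimeError(f"could not design a valid hairpin for {name}")
        flank = config.plant_flank
        footprint = len(precursor) + 2 * flank
        fp_start = place(footprint)
        p_start = fp_start + flank
        genome[fp_start:fp_start + footprint] = list(
            _random_seq(rng, _AC, flank) + precursor + _random_seq(rng, _AC, flank))
        planted.append(PlantedMir(
            name=name, mature_seq=to_rna(mature), star_seq=to_rna(star),
            contig=contig, precursor_start=p_start,
            precursor_end=p_start + len(precursor), strand="+",
            mature_start=p_start + m_off, mature_end=p_start + m_off + len(mature),
            star_start=p_start + s_off, star_end=p_start + s_off + len(star),
            expression_weight=float(weights[k]), known=known))
    pirna_loci = []
    for _ in range(config.n_pirna_loci):
        start = place(30)
        pirna_loci.append((contig, start, start + 30))
    return {contig: "".join(genome)}, planted, pirna_loci


def make_contaminants(config: SimConfig,
                      rng: np.random.Generator | None = None,
                      n_per_class: int = 3,
                      ref_length: int = 500) -> dict[str, list[tuple[str, str]]]:
    """Random reference sets standing in for mRNA / Rfam / Repbase."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    return {cls: [(f"{cls}-{i + 1}", _random_seq(rng, _ACGT, ref_length))
                  for i in range(n_per_class)]
            for cls in CONTAMINANT_CLASSES}


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def simulate_reads(genome: dict[str, str], planted: list[PlantedMir],
                   pirna_loci, config: SimConfig,
                   contaminants: dict[str, list[tuple[str, str]]] | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit the FASTQ records and the per-read truth table.

    Reads are fixed-length (`read_length`); each is insert + 3' adaptor,
    filled with adaptor repeats and truncated.  miRNA-derived inserts are
    sampled per locus proportionally to the planted expression weights
    with lengths in the short mode; piRNA-like inserts come from the
    piRNA loci with lengths in the long mode.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if contaminants is None:
        contaminants = make_contaminants(config, np.random.default_rng(config.seed + 1))
    contig = next(iter(genome))
    gseq = genome[contig]
    n = config.read_total
    fill = (config.adaptor_seq * (config.read_length // len(config.adaptor_seq) + 2))

    p_pir, p_con, p_art = (config.pirna_fraction, config.contaminant_fraction,
                           config.artifact_fraction)
    p_mir = 1.0 - p_pir - p_con - p_art
    cats = rng.choice(4, size=n, p=[p_mir, p_pir, p_con, p_art])
    low_q = rng.random(n) < config.low_quality_fraction
    if planted:
        w = np.array([p.expression_weight for p in planted])
        mir_idx = rng.choice(len(planted), size=n, p=w / w.sum())
    star_draw = rng.random(n) < config.star_fraction
    mir_lens = rng.integers(config.length_mode_mir[0],
                            config.length_mode_mir[1] + 1, size=n)
    pir_lens = rng.integers(config.length_mode_pirna[0],
                            config.length_mode_pirna[1] + 1, size=n)
    con_lens = rng.integers(15, 31, size=n)
    all_refs = [(cls, name, seq) for cls in CONTAMINANT_CLASSES
                for name, seq in contaminants.get(cls, [])]

    reads: list[tuple[str, str, str]] = []
    rows = []
    q_good = chr(config.q_good + 33)
    q_low = chr(config.q_low + 33)
    err_mask = rng.random((n, config.read_length)) < config.error_rate
    err_sub = rng.integers(1, 4, size=(n, config.read_length))

    for r in range(n):
        cat = cats[r]
        if cat == 0 and planted:
            mir = planted[mir_idx[r]]
            L = int(mir_lens[r])
            if star_draw[r]:
                insert = gseq[mir.star_start:mir.star_start + L]
                label, source = LABEL_STAR, mir.name
            else:
                insert = gseq[mir.mature_start:mir.mature_start + L]
                label, source = LABEL_MATURE, mir.name
        elif cat == 1 and pirna_loci:
            _, ls, le = pirna_loci[int(rng.integers(0, len(pirna_loci)))]
            L = int(pir_lens[r])
            off = int(rng.integers(0, max(1, (le - ls) - L + 1)))
            insert = gseq[ls + off:ls + off + L]
            label, source = LABEL_PIRNA, f"{ls}-{le}"
        elif cat == 2 and all_refs:
            cls, rname, rseq = all_refs[int(rng.integers(0, len(all_refs)))]
            L = int(con_lens[r])
            off = int(rng.integers(0, len(rseq) - L + 1))
            insert = rseq[off:off + L]
            label, source = LABEL_CONTAMINANT, cls
        else:
            insert, label, source = "", LABEL_ARTIFACT, "adaptor"
        seq = (insert + fill)[:config.read_length]
        if err_mask[r].any():
            s = list(seq)
            for pos in np.nonzero(err_mask[r])[0]:
                s[pos] = "ACGT"[("ACGT".index(s[pos]) + err_sub[r, pos]) % 4]
            seq = "".join(s)
        qual = (q_low if low_q[r] else q_good) * config.read_length
        rid = f"r{r:07d}"
        reads.append((rid, seq, qual))
        rows.append((rid, label, source, len(insert)))
    truth = pd.DataFrame(rows, columns=["read_id", "label", "source", "insert_len"])
    return reads, truth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """One seeded end-to-end draw: genome, loci, references, reads, truth."""
    rng = np.random.default_rng(config.seed)
    genome, planted, pirna_loci = make_genome(config, rng)
    contaminants = make_contaminants(config, np.random.default_rng(config.seed + 1))
    reads, truth = simulate_reads(genome, planted, pirna_loci, config,
                                  contaminants, np.random.default_rng(config.seed + 2))
    return SimDataset(config=config, genome=genome, planted=planted,
                      pirna_loci=pirna_loci, contaminants=contaminants,
                      reads=reads, truth=truth)


def make_utr(planted: list[PlantedMir], seed: int = 0, length: int = 600,
             site_mirs: int = 4, utr_id: str = "synthetic-utr") -> tuple[str, str]:
    """A synthetic 3'-UTR carrying perfect binding sites for planted miRNAs.

    For the first ``site_mirs`` reference-known planted miRNAs, the full
    reverse complement of the mature is written into a random background
    at evenly spaced positions, so the target stage has planted
    seed-complementary sites with strongly negative duplex energies.
    Returns (id, DNA sequence).
    """
    rng = np.random.default_rng(seed)
    utr = list(_random_seq(rng, _ACGT, length))
    known = [p for p in planted if p.known][:site_mirs]
    if known:
        gap = length // (len(known) + 1)
        for k, mir in enumerate(known):
            site = revcomp_dna(to_dna(mir.mature_seq))
            start = gap * (k + 1) - len(site) // 2
            utr[start:start + len(site)] = list(site)
    return utr_id, "".join(utr)


# --------------------------------------------------------------------------
# assay simulators
# --------------------------------------------------------------------------

def simulate_qpcr(true_fold_changes: dict[str, float], n_individuals: int = 3,
                  noise_sd: float = 0.25, seed: int = 0,
                  stages: tuple[str, str] = ("GV", "MI"), n_tech: int = 3,
                  baseline_ct: float = 24.0, u6_ct: float = 15.0,
                  individual_sd: float = 0.8) -> pd.DataFrame:
    """Simulate a stem-loop qPCR Ct table with a U6 endogenous control.

    Per miRNA, expression is 1 in the reference stage (first of
    ``stages``) and ``fold`` in the second; Ct = baseline - log2(expr)
    plus a per-individual offset shared across stages (the paired design)
    and Gaussian technical noise per replicate.  U6 has a
    stage-independent mean.  Columns: individual, stage, target, rep, ct.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for name, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {name} must be positive, got {f}")
    rng = np.random.default_rng(seed)
    rows = []
    for ind in range(1, n_individuals + 1):
        u6_eff = rng.normal(0.0, individual_sd)
        effs = {t: rng.normal(0.0, individual_sd) for t in true_fold_changes}
        for stage_i, stage in enumerate(stages):
            for rep in range(1, n_tech + 1):
                rows.append((f"ind{ind}", stage, "U6", rep,
                             u6_ct + u6_eff + rng.normal(0.0, noise_sd)))
            for tgt, fold in true_fold_changes.items():
                expr = fold if stage_i == 1 else 1.0
                mu = baseline_ct + effs[tgt] - np.log2(expr)
                for rep in range(1, n_tech + 1):
                    rows.append((f"ind{ind}", stage, tgt, rep,
                                 mu + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["individual", "stage", "target", "rep", "ct"])


def simulate_luciferase(effects: dict[str, float], n_rep: int = 3,
                        cv: float = 0.05, seed: int = 0,
                        construct: str = "wt-utr", nc_mimic: str = "NC",
                        renilla_mean: float = 20_000.0,
                        base_ratio: float = 2.0) -> pd.DataFrame:
    """Simulate a dual-luciferase plate for one reporter construct.

    ``effects`` maps mimic name -> fractional knockdown of the
    firefly/renilla ratio (0 = inert, 0.4 = 40% knockdown).  The negative
    control mimic is added automatically with zero effect.  Noise is
    multiplicative Gaussian with coefficient of variation ``cv`` on both
    channels; triplicate wells by default.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_effects = {nc_mimic: 0.0, **effects}
    for mimic, kd in all_effects.items():
        if not 0.0 <= kd < 1.0:
            raise ValueError(f"knockdown for {mimic} must be in [0, 1)")
        for rep in range(1, n_rep + 1):
            renilla = renilla_mean * max(1e-6, 1.0 + cv * rng.standard_normal())
            firefly = (renilla * base_ratio * (1.0 - kd)
                       * max(1e-6, 1.0 + cv * rng.standard_normal()))
            rows.append((construct, mimic, rep, firefly, renilla))
    return pd.DataFrame(rows, columns=["construct", "mimic", "rep",
                                       "firefly", "renilla"])
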