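# Methods

This note documents the models, defaults and design decisions behind
`ovamir`, in the spirit of a package methods appendix. Nothing here
states a number the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and data flow

The package reimplements, as a deterministic library, the standard
annotation chain for a small-RNA library from a genome-less species:

```
FASTQ -> quality -> adaptor trim -> contaminant removal -> 15-30 nt
      -> collapse -> copy >= 3  ==>  unique tags
tags  -> map (species miRNA refs, clade refs, genome) -> groups 1-5
      -> families (seed nt 2-8), star detection
loci  -> +/-60 nt extension -> MFE fold -> hairpin verdict (novel calls)
miRNAs -> seed scan of a 3'-UTR -> duplex MFE -> ranked target report
Ct / luciferase tables -> 2^-ddCt, ratio normalization + tests
```

The filter order is fixed. The literature this pipeline style comes
from lists the filters without an order; we run contaminant matching
per read, before collapsing, because it keeps the removed-read
accounting per-class and per-read, and the copy filter must follow
collapsing by definition. Reads with no detectable 3' adaptor are
discarded rather than kept untrimmed: in a small-RNA library an absent
adaptor implies the insert was at least read-length, outside the
15-30 nt window regardless.

## RNA-folding energy model

`ovamir.energy` defines a deliberately small nearest-neighbor model:

* **Stacks.** Watson-Crick/Watson-Crick steps use classic 37 °C
  stacking free energies (kcal/mol), closed under the rotational
  identity E[(a,b),(c,d)] = E[(d,c),(b,a)]. Every step containing a
  G·U wobble is a flat −0.5 kcal/mol, so wobbles extend helices but
  never beat a Watson-Crick alternative.
* **Loops.** Affine penalties: hairpin 5.4 + 0.25·(s−3) (minimum loop
  3 nt), bulge 3.8 + 0.30·(s−1), internal 4.0 + 0.30·(s−2), each side
  of a bulge/internal loop capped at 15 nt. Multibranch loops cost
  4.6 + 0.4 per branch (closing pair included) + 0.1 per unpaired
  base. No dangles, no terminal-AU penalties, no special tetraloops,
  no pseudoknots.

The folding DP (`ovamir.fold.mfe_fold`) is a Zuker-style recursion
(paired-interval table, multibranch helper, external prefix) that
minimises exactly the energy `structure_energy` assigns to an explicit
structure; `ovamir._brute.brute_mfe` enumerates *all* nested structures
and evaluates them with that same function, giving an independent
optimisation path. The duplex DP (`ovamir.target.duplex_mfe`) shares
the pair table, forbids intramolecular pairs, uses the same affine
bulge/internal penalties between consecutive intermolecular pairs, has
no initiation or dangling terms (so a single pair scores 0 and a
perfect n-mer duplex scores the sum of its n−1 stacks), and is checked
against `brute_duplex_mfe`, which enumerates all antiparallel monotone
matchings.

Model fidelity to any external thermodynamic server is explicitly *not*
a goal: the published analyses this mirrors used web servers whose
parameter sets are richer. Correctness is defined internally (oracle
equivalence) plus a structure-level cross-check that ViennaRNA's
RNAfold also folds a planted precursor into a single stem-loop.

Numerical choices: energies are IEEE doubles; the traceback re-derives
decisions by exact float equality against the stored optima (same
arithmetic, so bitwise reproducible) with a fixed priority — stack,
then bulge/internal by increasing loop size, then multibranch by
smallest split, then hairpin. Among co-optimal structures this yields
one deterministic structure; we do not attempt a lexicographic-minimum
dot-bracket, which would require a search over the co-optimal set. The
open chain (energy 0) bounds every optimum from above.

### Hairpin verdict

A locus has "hairpin propensity" when any of the three extension
windows (±60 nt both-sided, and each single-sided window) folds into a
structure with **one** terminal loop, energy ≤ −18 kcal/mol, the tag
entirely on one arm (not reaching the terminal loop) and ≥ 60 % of tag
bases paired. The energy and pairing thresholds are not published
values — the source analyses never quantify "propensity" — so they are
configuration (`AnnotateConfig.energy_max`, `pair_min`) with
miRDeep-era defaults.

## Mapping and classification

Tags are ≤ 30 nt, so mapping is an exact k-mer (k=7) seed-and-extend
scan, not an external aligner. miRNA-reference hits allow ≤ 2
substitutions but require the tag seed (positions 2–8) exact — the
seed 7-mer therefore anchors every candidate alignment, making the scan
complete. Up to 2 tag bases may overhang a mature reference end
(length-variant isomiRs). Genome hits are exact by default (both
strands; minus-strand hits are reported on the hit strand).

Group order 1→5 with first match winning is a design choice: the
published group definitions are presented as counts, not an algorithm,
and specific-to-generic ordering reproduces their partition semantics.
Ambiguities resolved here:

* a tag matching both a known locus and a new hairpin-forming locus
  takes group 1 if the known-locus overlap exists, else group 2;
* "other genome" (group 3) means a user-supplied secondary genome;
  without one, group 3 is unreachable and such tags fall to group 4;
* known-name assignment is the best species hit by (mismatches, then
  alphabetical name) — a deterministic tie-break.

Star calls require the precursor fold, the tag on the arm opposite the
annotated mature, no overlap with the mature, and ≥ 60 % of tag bases
paired to mature-arm bases.

## Target discovery

Candidate sites are exact Watson-Crick reverse complements of miRNA
nt 2–8 (no G·U in the seed, matching the shaded seed complementarity of
the hybridisation figures this follows); G·U is allowed outside the
seed in duplex scoring. Each site is scored against ± 15 nt of UTR
context (hybridisation is local; the exact window of the reference
tools is unpublished, so it is a parameter). The GY-box (GUCUUCC),
Brd-box (AGCUUUA) and K-box (UGUGAU) motif sequences are
literature-derived *configuration*, used only to label sites — never to
filter. Ranking is per-miRNA best (smallest) duplex MFE, ties broken by
UTR coordinate.

## Assay statistics

**2^−ΔΔCt.** Technical replicates are averaged arithmetically;
ΔCt = Ct_miRNA − Ct_U6 per (individual, stage). When individuals are
matched across stages, ΔΔCt is computed per individual
(ΔCt_stage,i − ΔCt_ref,i): each animal is its own reference, so
per-individual baselines cancel exactly and a noise-free simulated
fold change is recovered exactly; with unmatched individuals the
group-mean reference is used and the result is flagged unpaired. The
test is a paired t on ΔCt (Welch fallback when unpaired), α = 0.05.
Zero-variance contrasts degenerate to t=0, p=1 (identical stages) —
tolerance 1e-10 on the difference SD.

**Luciferase.** Per-well ratio firefly/renilla, scaled to the
negative-control mean within each construct. One-way ANOVA across mimic
groups, then per-mimic two-sided t vs NC with Holm correction
(`holm=False` reverts to raw per-test α, since the original analyses do
not state their multiplicity handling). Non-positive signals are
rejected with a logged message; every group needs ≥ 2 replicates.

## What the simulator emulates — and what it does not

`ovamir.simlib` generates, per seeded run: a random ACGT genome with
planted miRNA hairpin loci and piRNA-like loci; reads with a bimodal
15–30 nt length structure (modes 21–23 and 24–27 nt, the long mode more
abundant, as in arthropod ovaries); log-normal per-miRNA abundance
(σ = 1.5, emulating the heavy skew of real libraries); a 3' adaptor on
every read with adaptor-dimer artifacts (insert length 0); contaminant
reads drawn from visible mRNA/structural-RNA/repeat reference sets; a
fraction of uniformly low-quality reads (flat Q12 vs Q35, exercising
the mean-quality filter; no per-cycle error model); and uniform
substitution errors (0.1 %/base).

Planted precursors are ext5 + mature + loop + star + ext3 (~72 nt),
with the star the reverse complement of the mature carrying ≤ 2
designed substitutions. The loop, extensions and ±70 nt genomic flanks
are drawn from the **A/C alphabet**, which cannot base-pair with
itself, so the extension windows fold to exactly the designed stem;
designs are additionally verified by folding at construction time and
redrawn if they fail (a random mature occasionally folds on itself).
This is the central benchmark simplification: real genomic flanks are
structured and can add stems to an extension window, so the planted
recovery rates measure the pipeline's bookkeeping and the fold engine's
criteria — not the false-negative rate of hairpin calling in real
genomic context. Likewise uniform errors, flat quality and perfect
adaptor placement make the preprocessing recovery tests exact rather
than realistic.

qPCR simulation: Ct = baseline − log2(expression) + per-individual
offset (SD 0.8 cycles, shared across stages — the paired design) +
technical Gaussian noise per replicate; U6 has a stage-independent
mean; triplicate technical replicates, 3 individuals by default
(matching the 3–4-animal designs typical of these assays). Luciferase:
multiplicative 5 % CV noise on both channels, triplicate wells,
knockdown as a fractional reduction of the firefly/renilla ratio.

Default read depth (200k) and locus counts (20 known + 10 novel + 30
piRNA-like in 20 kb) are desk-scale choices: large enough for stable
per-miRNA counts and tight binomial checks, small enough that the whole
chain runs in tens of seconds.

## Known limitations

* The energy model is minimal; absolute kcal/mol values are not
  comparable to Turner-parameter tools, only orderings and the internal
  oracle are meaningful.
* Group 2 and group 3 are exercised only by construction in unit tests;
  the default simulation produces no multi-locus known miRNAs and no
  secondary genome.
* piRNA-like tags are deliberately left unclassified (no piRNA
  annotation is attempted, mirroring the source analyses).
* 5' adaptors are assumed already removed by upstream vendor
  processing; no amplification-efficiency (Pfaffl) correction in ddCt.
* `structure_energy` and the DPs share the loop-energy definitions —
  the oracles are independent optimisers, not independent energy
  models.
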