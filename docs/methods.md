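# Methods

## Motif model

The p53 response element (RE) is modelled as two 10-bp half sites scored
by one shared half-site matrix, with an unscored spacer of 0–13 bp
between them. The default position frequency matrix is derived from the
IUPAC consensus `RRRCWWGYYY`: each column gives probability `1 − ε`
split equally over the allowed bases and `ε` over the disallowed ones.
ε defaults to 0.04 — small enough that the consensus 20-mer is always
the global score optimum, large enough that a single off-consensus base
does not disqualify a site at the default cutoff. Any JASPAR-style 4×10
matrix can be substituted, since published p53 matrices differ in
provenance and depth.

Log-odds weights use a background-proportional pseudocount (default 1.0
on probability-normalised columns) and a uniform background; both are
configurable. With the defaults the maximal score is ≈ 13.84 bits and
the score cutoff is 80% of maximal (≈ 11.07 bits). The cutoff is the
one genuinely free parameter of the scanner: no published threshold
exists for this family of scans, so it is exposed as configuration and
the pipeline's set-size behaviour (peaks without a callable RE are
dropped) is exercised through the synthetic generator rather than tied
to a fixed constant.

Numerical conventions:

- `N` bases contribute zero log-odds — unknown sequence neither rewards
  nor penalises a candidate.
- Every (offset, spacer) window is scored on both strands and reported
  once, in canonical orientation: the higher-scoring strand, `+` on an
  exact tie. The consensus is quasi-palindromic, so orientation must be
  pinned for position numbering (C9/G12) to be meaningful. Under
  reverse complement position *i* maps to 21 − *i*: C9 and G12 are dyad
  partners, and a site carrying both carries both in either reading.
- Best-hit ties break deterministically: higher score, then smaller
  start, then `+` strand, then smaller spacer.
- Coordinates are 0-based half-open in memory and in BED; text reports
  print 1-based starts.

## Enrichment statistics

Per-position counts over a set of aligned, spacer-removed 20-mers give a
20×4 matrix; `N` counts toward no base (and a site with `N` at a tested
position counts as "without the base" — conservative, and irrelevant for
clean RE calls). Logo export is per-position frequency plus information
content `2 − H` bits.

Each (position, base) pair yields a 2×2 table (with/without the base ×
set A/set B) tested with a two-tailed Fisher's exact test: the sum of
hypergeometric outcome probabilities not exceeding the observed table's,
with a relative tolerance of 1e-7 on the comparison so floating-point
jitter cannot flip a tie, evaluated in log space (`gammaln`) so
1,000-plus-site tables are stable. This is the convention of standard
statistical packages; the implementation is checked in the test suite
against exact rational enumeration (all tables with total ≤ 30) and
against an independent library implementation on large tables.

Multiplicity: Bonferroni with m = 80 (20 positions × 4 bases),
`p_bonf = min(1, 80·p)`. Fold change is `(a/n_A)/(c/n_B)`; degenerate
tables are flagged explicitly rather than silently numeric (fold +inf
when the base is absent from B only; fold 1 with p 1 when absent from
both, or fixed in both). A concurrent signature — the conjunction
C9 ∧ G12 by default — is tested identically on the joint match
indicator; with a single-position spec it reduces exactly to the
positionwise record.

Exact conditional tests are conservative by construction: at the study's
set sizes (208 vs 1,290) the attained size at nominal 0.05 is ≈ 0.04,
not 0.05. The null-calibration test therefore judges the empirical
rejection fraction against a 3-SD binomial band computed over the number
of independent simulation replicates, since positionwise tests within
one simulated pair are mutually dependent (the four base counts at a
position are linearly constrained).

## Differential integration

- Differential peaks: `(signal_test + 1)/(signal_ctrl + 1) > 2`,
  strictly. The pseudocount (1 signal unit) guards zero controls; the
  upstream normalisation of the signals is the caller's responsibility.
- DE genes: `FDR < 0.05` and `|log2((FPKM_test+1)/(FPKM_ctrl+1))| > 1`,
  strictly; the fold is recomputed from FPKM + 1 rather than trusted
  from the input table. Boundary cases (exactly 2-fold, FDR exactly
  0.05) are excluded and tested.
- Peak–gene linkage: gene-body overlap OR TSS within ±5 kb of the peak
  (configurable). No published rule exists for this step; the chosen
  rule is the simplest one that reproduces the required multi-gene
  behaviour — one peak in the overlap of two gene bodies regulates both.
- Signature flags: C9 and G12, plus the conserved consensus bases at
  positions 4, 7, 14 and 17 with a deviation flag when any of the four
  mismatches. On the written strand the conserved bases are C4, G7, C14
  and **G**17 (position 17 is the dyad partner of C4); annotations that
  label position 17 by its opposite-strand cytosine describe the same
  base pair.

## Synthetic data

The generators emulate the study design at its published scale so the
pipeline's statistical behaviour is observable without sequencing data:

- **RE sets**: sites drawn column-independently from per-position base
  probabilities; defaults place C9 at 73.1% vs 57.2% and G12 at 73.1%
  vs 56.0% in sets of 208 and 1,290.
- **Peaks**: 200-bp sequences, i.i.d. background at GC 0.41, one RE per
  peak at a uniform offset and strand, spacer from a short-spacer
  distribution (80% spacerless, max 3 bp). Defaults: 214 peaks with 6
  RE-free in the signature condition, 1,328 with 38 RE-free in the
  reference condition. Binding signals are log-normal around a per-peak
  intensity with the planted fold (default 3) applied to differential
  peaks, multiplicative noise SD 0.1.
- **DE table**: 194 up + 281 down planted genes at ≥ 4-fold on FPKM+1
  with FDR < 0.05, nulls near fold 1 with FDR uniform on (0.05, 1], in
  a 12,000-gene transcriptome.
- **Integration scenario**: 13 regulated genes on one synthetic
  chromosome linked to 12 differential peaks, one peak inside the
  shared overlap of two gene bodies; 9 of the 12 REs carry C9 ∧ G12;
  distractor genes and non-differential peaks exercise both filters.

Structural guarantees are built in rather than left to chance, because
the fixtures assert exact counts: embedded REs are drawn over
consensus-allowed bases only (so every planted site scores at the PWM
maximum; an `re_epsilon` knob adds off-consensus substitutions for
robustness experiments), RE-free peaks are rejection-sampled until they
contain no window above the score cutoff, and the integration fixture
redraws a peak's noisy signals until they fall on the peak's intended
side of the fold-2 filter. Noisy-threshold recovery is still measured
where it is the point: planted fold-3 peaks against the fold-2 filter
are recovered at > 95% across seeds, and planted RE offsets at ≥ 99%
(the residual misses are genuine score ties with background windows,
resolved by the deterministic tie-break).

All randomness flows through numpy's PCG64 `Generator`; a fixed seed
reproduces every emitted file byte-identically.

### What the generator does not emulate

- **Inter-position dependence.** Sampling is column-independent, so the
  concurrent C9∧G12 frequency is the product of the marginals
  (0.731² ≈ 53.4% vs 0.572 × 0.560 ≈ 32.0%, fold ≈ 1.67). Real RE sets
  show sub-multiplicative co-occurrence (58.2% vs 41.9%, fold 1.39):
  genomic REs carry correlation structure the positionwise model does
  not encode. Concurrent-signature statistics on synthetic data
  therefore overstate the real effect, and the concurrent worked
  example is validated on the printed counts, not on simulation.
- **Genomic background.** Peak flanks are i.i.d.; no repeats, CpG
  structure, or half-site clustering. False-positive RE calls in decoy
  peaks are consequently rarer than in real genomes.
- **Signal realism.** ChIP signals are log-normal summaries, not read
  pileups; peak calling and DE testing (and their error modes) are
  upstream of this package by design.

Passing tests on synthetic data demonstrate the pipeline's correctness
and calibration under its own model assumptions — not the biological
effect sizes, which only the study's sequencing data can provide; the
genome-scale counts from that data (214/1,328 differential peaks, the
published target-gene fold values) are mirrored structurally, never
claimed numerically.

## Problem sizes

The default test and acceptance runs use the published set sizes
(208/1,290 REs, 214/1,328 peaks, 475 DE genes in a 12,000-gene table),
20-seed replication for power statements, and 200 replicate pairs for
null calibration — sizes at which every stage completes in seconds on a
laptop while keeping the binomial noise on proportion estimates below
the effect sizes of interest.
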