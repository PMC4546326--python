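# Methods

## Scales and conventions

Two log scales coexist in copy-number work and the package keeps them
explicit.  SEG files carry the *segment mean*, log2(CN/2), whose neutral
value is 0; gene-level summaries are reported as log2 *absolute* copy
number, log2(CN) = segment mean + 1, whose neutral value is log2(2) = 1.
All state calls happen on the absolute scale, where "> 1 means gain,
< 1 means loss" holds at diploid.  This single +1 conversion is the only
reading under which the gain/loss convention, the diploid reference and
published per-gene log2(CN) values slightly above 1 are simultaneously
coherent.

Coordinates are 0-based half-open internally.  SEG input defaults to the
common 1-based, end-inclusive dialect; `SegmentFileDialect` declares the
alternative conventions and every combination is normalized on read (the
normalization is idempotent on internal coordinates).  Chromosome labels
`"7"` and `"chr7"` are both accepted; autosomes 1–22 only — burden
tabulation in this design is defined over autosomes, and sex chromosomes
are rejected at parse time rather than silently dropped.

A copy-number variant is a segment of at least 1 kb.  Length bins are
1–10 kb, 10–50 kb and >50 kb; the shared endpoints belong to the lower
bin (10,000 → 1–10 kb, 50,000 → 10–50 kb), a tie-break the bin wording
leaves open, fixed here so the bins tile [1 kb, ∞) exactly.

Missing segment means are treated as "no evidence of change": segment mean
0, hence log2(CN) 1, hence neutral, and never an event.  (A literal
alternative reading — missing copy number denoted 1, i.e. a single copy —
would make every missing value a deletion, which contradicts the diploid
neutral convention; the neutral fill is the default and the classification
dead-band ε, default 1e-9, is configurable.)

## Burden statistics

Counts are tabulated per (chromosome, state, length bin) cell for cases and
controls.  The effect measure is the per-sample-normalized ratio
(n_case/N_case)/(n_ctrl/N_ctrl): robust to unequal cohort sizes, and equal
to the naive count ratio when the cohorts match.  A zero control count makes
the ratio undefined; it is reported as missing, never as infinity.

Significance is a sample-label permutation test: the case/control labels
are permuted over samples (the sample, not the segment, is the
exchangeable unit — segment counts within a sample are correlated), the
statistic is |log ratio|, two-sided because both enrichment and depletion
are of interest, and the p-value uses the add-one estimator
(1 + #exceeding)/(R + 1) with R = 1000 replicates by default, so p ≥
1/(R+1) always.  Replicates with an undefined ratio count as non-exceeding.
One set of permutations, drawn once from the seed, is shared by all cells
of a table, which makes the full table byte-reproducible and lets the
per-cell work vectorize; the marginal null per cell is unchanged.  The
p-value column is deliberately uncorrected (each cell is reported as its
own test, as burden tables in this literature are); a Benjamini–Hochberg
q-value column is emitted alongside as a clearly labeled extra.

## Gene calls and the recurrence filter

"Genes located within CNV regions" is implemented as full containment of
the gene interval in the event interval (default); `any_overlap` exists as
a config escape hatch for annotations with very long genes.  Mapping uses
an interval tree per chromosome; a brute-force quadratic scan serves as the
test oracle.  When two events of one sample cover the same gene with
conflicting states, the call further from neutral (larger |log2(CN) − 1|)
wins; exact ties resolve to the gain, deterministically.

The recurrence filter keeps a gene iff a *single* state is called in
strictly more than `min_case_fraction` (default 0.8) of all cases — a gene
duplicated in half the cases and deleted in the other half is not
recurrent — and at most `max_control_fraction` (default 0: none) of
controls carry any call.  The denominator is all cases, with missing data
filled neutral, matching the missing-value rule.  The per-gene copy-number
summary is the mean log2(CN) over the case samples carrying the recurrent
state.

## DEG screen and driver classification

The expression screen is fold-change-only: log2FC = mean(tumor) −
mean(normal) on the already-log2 expression scale, DEG iff |log2FC| > 1
strictly, split into up/down.  No variance model or p-value is applied —
the protocol being implemented screens on the fold change alone — and a
matched-pair mode (mean of within-pair differences) is available for paired
designs, where it equals the group difference on complete pairs.

A CNV-driven gene is a recurrent CNV gene, measured on the expression
platform, that is a DEG, and whose signs agree:
sign(log2(CN) − 1) = sign(log2FC).  Concordance is a sign rule, never a
magnitude rule.  Output is ordered by chromosome, then |log2FC| descending.
Since published driven-gene tables in this setting contain only
concordant-gain rows, the deletion/down branch is validated on synthetic
data.

## Enrichment

Over-representation uses the plain hypergeometric upper tail
P(X ≥ k) for an overlap of k between a query of n and a term of K genes
within a universe of N, with the universe defaulting to the genes measured
on the expression platform (not the genome).  An EASE-style variant
(overlap penalized by one gene before taking the tail, as popularized by
web annotation servers) is available behind a flag; it is strictly more
conservative.  BH q-values are auxiliary output; the significance flag is
p < α with α = 0.05.

## The synthetic cohort

The generator emulates the statistical structure the pipeline must detect,
not array physics.  Defaults, chosen once as the standard study scenario:

| parameter | default | rationale |
|---|---|---|
| cohort | 20 cases / 20 controls | small but comfortably powers a |shift| = 2 screen |
| genome | 3 autosomes × 10 Mb | enough room that genes and events rarely collide |
| genes | 200 × 5 kb, non-overlapping, uniform | gene-scale intervals well below event size |
| planted drivers | 10 concordant (5 gains +2, 5 losses −2) + 2 discordant decoys | exercises both branches of the sign rule |
| carrier fraction | 0.9 | safely above the 0.8 recurrence threshold (18/20 cases) |
| driver events | 30 kb, gain log2(CN) ≈ 1.6 / loss ≈ 0.4, sd 0.05 | focal, mid-bin, clearly non-neutral |
| background events | Poisson per sample per bin: 1.0 / 0.5 / 0.25 (1–10 kb / 10–50 kb / >50 kb), lengths uniform in bin (>50 kb capped at 150 kb) | a scaled-down per-genome CNV load on a 30 Mb toy genome |
| expression | baseline per gene U(4,12), noise N(0, 0.3²), carriers shifted by the planted amount | log-normal-style noise on the log2 scale |

Background events fall in both cohorts and may hit any gene, including a
planted driver in a control — intentionally: removing chance hits is the
frequency filter's job, not the generator's.  Expression shifts are applied
to the *realized* carriers (case samples whose segments contain the gene
with the driver's state), so copy number and expression are concordant by
construction for drivers and anti-concordant for decoys; non-driver genes
never shift.  One integer seed drives everything through four child
streams spawned in a fixed order (genome, segments, expression, gene sets),
so each generator is independently deterministic.

What the generator does *not* emulate: probe-level noise, wavy baselines,
subclonality, aneuploidy, correlated expression programs, paired-sample
effects.  Passing the recovery tests therefore shows the pipeline's logic
and thresholds behave as specified under clean planted signal — not that
the thresholds are optimal for real SNP6/microarray data.

## Test and calibration scenario sizes

The recovery standard is: ≥ 9/10 concordant drivers recovered, zero decoys
and zero unplanted genes called driven, in ≥ 90 % of 20 seeds of the
default scenario.  Null calibration uses a one-chromosome, 20 vs 20,
no-driver scenario with a 1–10 kb background rate of 5 events per sample:
the elevated rate keeps the permutation statistic's discreteness small
relative to the KS ≤ 0.15 uniformity band (with per-sample counts near
Poisson(2.5) per state, the permutation distribution of the case sum has
enough support that the add-one p-values are close to uniform over 200
cohorts at 500 replicates each).  Oracle-equivalence checks run the
interval mapping against the quadratic scan on 100 random instances
(≤ 50 genes × ≤ 200 events), the Monte-Carlo permutation p against full
label enumeration on 2v2 and 3v3 cohorts, and the hypergeometric tail
against draw enumeration for N ≤ 12.

## Known limitations

- Segments are used as delivered: no re-segmentation, no merging of
  adjacent segments, no GISTIC-style focal-peak significance.
- The recurrence filter is a hard threshold, not a statistical test of
  recurrence; its output on real cohorts depends strongly on cohort size.
- The fold-change-only DEG screen inherits the usual caveats (no variance
  moderation, no multiplicity control) — deliberately, to match the
  protocol it implements.
- Burden p-values are not exactly recoverable across implementations of
  this protocol family, because the permutation unit and statistic are
  design choices; this package documents and tests its own.
- Enrichment replaces annotation-server scoring with the plain
  hypergeometric tail; term-level results depend entirely on the
  user-supplied GMT snapshot.
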