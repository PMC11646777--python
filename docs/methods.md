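# Methods

## The problem

Public stress-transcriptome data for a crop accumulate across many
independent projects: different labs, platforms, tissues and designs. The
per-contrast differential-expression (DE) statistics — one log2 fold change
and p-value per gene per treatment-vs-control comparison — are comparable,
but the underlying counts are not: batch effects rule out pooling samples,
and stress conditions are represented by wildly unequal numbers of
contrasts (a popular stress such as drought can carry ten times the
contrasts of a rare one). `kinscore` implements a meta-scoring strategy
that operates entirely on the per-contrast DE summaries, plus the
downstream screens typically run alongside it in a kinome study:
tissue-specificity (Tau), Ka/Ks selection regimes, Ks-based dating of
whole-genome duplication (WGD), and descriptive family-composition
statistics.

## The four scores

For gene *i*, contrast *c* and stress group *g* with *n_g* contrasts, let
the DE indicator be

    s_ic = 1  iff  p_ic < p_threshold  and  |log2FC_ic| >= log2(fc_threshold)

(defaults p < 0.05, linear fold change 2, i.e. |log2FC| >= 1; up- and
down-regulation are treated identically since both directions carry equal
evidence of involvement), and the magnitude m_ic = s_ic * |log2FC_ic|.
Then

    T_i    = sum_c s_ic                                (response frequency)
    TFC_i  = sum_c m_ic                                (response intensity)
    AT_i   = sum_g (1/n_g) sum_{c in g} s_ic           (group-balanced T)
    ATFC_i = sum_g (1/n_g) sum_{c in g} m_ic           (group-balanced TFC)

The group averaging is the entire batch/imbalance mitigation: duplicating
every contrast of one group leaves AT and ATFC of every gene exactly
unchanged while T and TFC inflate, so AT/ATFC cannot be dominated by the
most-sequenced stress. Genes are ranked under each method (descending
score, ties broken by gene id for determinism) and the union of the four
top-k lists (default k = 30) is the selected set, with per-gene provenance
recording which methods chose it. Per-method lists are truncated to exactly
k by the tie rule; a `keep-all` option extends lists through a tie at rank
k for sensitivity analysis.

Interpretation choices worth stating: a "sample" in this scheme is one
treatment-vs-control contrast (DE exists only per comparison); the
fold-change scores accumulate |log2FC|, not linear FC, which makes the
smallest possible nonzero TFC equal to log2(fc_threshold) = 1 at the
default cut; the fold boundary is inclusive and the p boundary strict; the
flag uses the raw p-value column by default, with an adjusted-p column
accepted and selectable. Genes never flagged anywhere keep all-zero scores
and remain in the table — filtering them is a reporting choice, not a
scoring one. Missing log2FC or p never flags.

## Tau tissue specificity

For a gene with non-negative expression x_1..x_N over N >= 2 tissues,

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

the standard Yanai index: 0 for uniform expression, 1 for single-tissue
expression, undefined for a gene silent everywhere (such genes are never
called specific). Genes with tau >= 0.8 are called tissue-specific. Tau is
computed on raw TPM by default; a log2(TPM+1) mode is available (log
compression lowers tau, so thresholds are not transferable between modes).
When several samples share a tissue, average them per tissue first. The
argmax tissue is reported; ties take the first tissue in column order.

## Ka/Ks and WGD dating

Selection regimes over duplicate gene pairs follow the usual reading of
omega = Ka/Ks: > 1 positive, < 1 purifying, = 1 neutral (a 1e-9 numerical
band around 1 absorbs floating-point noise; omega is undefined when Ks is
zero or missing, and such pairs form their own category so the four
regimes partition every table). Summaries (min/max/mean omega, count under
positive selection) are reported per duplication class (WGD, tandem,
proximal, dispersed, singleton); duplication classification itself is
consumed from upstream collinearity tools, not recomputed.

A WGD event leaves a hump in the Ks distribution of duplicate pairs. The
hump location is estimated as the argmax, over a 0.01-step grid, of a
Gaussian kernel density (Silverman bandwidth) fitted to the Ks values
inside a search window, default (0.2, 2]. Both bounds matter: above ~2,
synonymous sites saturate and estimates pile up noisily; below ~0.2,
recent small-scale duplicates and near-allelic pairs produce a mass
against zero that exceeds any WGD hump — with the package's own mixture
generator (70% exponential background, mean Ks 0.15) the full-range KDE
argmax lands near 0.05 in every replicate, while the (0.2, 2] window
recovers the planted 0.54 peak in 20 of 20. Both bounds and the bandwidth
are configurable. If all retained values are identical the KDE degenerates
and the common value is returned directly.

The peak converts to an age by the molecular clock T = Ks / (2r), with
r = 8.25e-9 substitutions per synonymous site per year (a standard
composite dicot rate), reported in million years: Ks = 0.54 gives
32.73 MYA. The package reports full precision; rounding to two decimals is
left to presentation.

## Kinome composition summaries

Plain tabulation over a per-gene catalog: counts and percentages at the
family and subfamily level (and across species, with absent subfamilies
reported at n = 0); per-subfamily intron-count range and variance; and
membrane/secretion cross-tabs (transmembrane helices x signal peptide,
plus the multi-kinase-domain tally). Two conventions are fixed and
documented rather than configurable: percentages round half-up (2 decimals
by default, 1 where tables conventionally print 1), and intron variance is
the population variance (divisor n), which leaves single-member
subfamilies well-defined at 0. Intron counts can be derived from a GFF3
annotation as (exons of the representative transcript) - 1; the
representative is the mRNA with the most exons by default (`longest_mrna`,
ties to the lexicographically smallest transcript id), with `longest_cds`
(largest summed CDS length) and `first` (smallest start coordinate) as
alternatives, since annotations rarely state which isoform a published
count used.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage is testable without downloads; their
defaults define the study conditions the tests and the acceptance script
measure.

**Study generator.** 10 stress groups with unequal contrast counts
(2, 3, 2, 2, 20, 4, 2, 3, 2, 2 — the 20-contrast drought group is 10x the
median, mimicking compendia where one stress dominates), each group's
contrasts split into projects of at most 4, 2,000 genes of which 50 are
broad responders (DE probability 0.9 in every contrast), 50 narrow
responders (DE probability 0.9 in the largest group only) and the rest
null. A true DE event draws |log2FC| ~ Normal(2.5, 1.0) floored at 1.0
with random sign and p ~ Uniform(0, 0.05); a non-event draws
log2FC ~ Normal(0, 0.3) and p ~ Uniform(0, 1). Every contrast of a project
shares an additive log2FC shift ~ Normal(0, 0.3) — the batch effect. The
batch effect is modeled at the statistic level, not the count level,
because the pipeline consumes DE statistics; p-values are marginal, not
derived from a count model, because the scores consume only the (flag,
magnitude) pair. Consequently passing tests demonstrate the scoring's
behavior under batch shift and group imbalance, not robustness to
count-level artifacts (library-size effects, dispersion misestimation,
correlated replicates), which are upstream of this pipeline.

**Expression generator.** 11 tissues; planted specific genes express
LogNormal(5, 0.5) in one random home tissue and LogNormal(-1, 0.7)
elsewhere (expected tau ~ 0.99); null genes draw i.i.d. LogNormal(2, 0.5)
across tissues. The null spread is deliberately moderate: at sigma = 0.5
fewer than 1% of null genes reach tau >= 0.8 (the generator's stated
design requirement of a quiet null), whereas sigma = 1 would push ~30% of
nulls over the threshold. Real tissue atlases sit between these regimes
and include correlated tissues, so real-data Tau screens need threshold
judgment the synthetic null does not exercise.

**Ks generator.** A 0.7 / 0.3 mixture of Exponential(mean 0.15)
small-scale-duplication background and a Normal(0.54, 0.08) WGD peak,
truncated to (0, 2], with the Gaussian center recorded as the planted
truth.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

The recovery checks use 20 replicates at 2,000 genes x 42 contrasts
(scoring), 1,000–2,000 genes x 11 tissues (Tau) and 2,000 Ks draws — sizes
at which the planted-signal recovery rates are stable across seeds while
the whole suite runs in seconds. Scoring is exactly linear algebra on a
dense gene x contrast indicator matrix; the only tolerance anywhere is the
1e-12 agreement bound against the brute-force oracle (double precision
exact up to summation order). Ties are broken lexicographically by gene id
at every ranking step, so all outputs are byte-reproducible; written
tables are sorted by gene id for the same reason.

## Known limitations

- The scoring treats contrasts as exchangeable within a group; it has no
  notion of within-project correlation beyond the group average, and no
  significance model — it is a screening score, not a test statistic.
- Tau on raw TPM is sensitive to a single extreme tissue value; the log
  mode trades that for threshold incomparability.
- KDE argmax peak detection reports one mode; genomes with multiple WGD
  humps need the window moved or narrowed per hump.
- Molecular-clock dating inherits the full uncertainty of the clock rate
  r; reported ages scale exactly as 1/r.
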