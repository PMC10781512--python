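# Methods

## Model and procedure

A-to-I editing by ADAR enzymes converts adenosine to inosine, which
reverse transcriptases and sequencers interpret as guanosine. In small
RNA-seq aligned to miRNA hairpins, editing of a mature miRNA therefore
appears as an A→G mismatch at a fixed mature position, present in a
fraction of the reads. The quantity of interest at a site is the editing
level `k/n` — reads carrying G over reads covering the position — per
sample, and its difference between two groups.

The pipeline has five stages:

1. **Alignment and tally.** Reads are adapter-trimmed (longest read
   suffix exactly matching an adapter prefix, ≥ 6 nt overlap), then
   aligned ungapped and sense-strand-only against every hairpin. The best
   placement is the one with fewest mismatches; reads tying across
   distinct hairpins are discarded rather than fractionally assigned, and
   ties within one hairpin resolve to the smallest offset. Reads shorter
   than 15 nt after trimming are dropped. A read is assigned to a mature
   arm when its start is within 2 nt of the annotated mature start and
   the arm covers ≥ 90% of the read. Mismatch bases are tallied exactly
   as observed — they are the editing signal; `N` never matches and is
   never tallied. Indels are not modelled: mature-length reads on their
   own hairpins essentially never need gaps, and substitutions are the
   phenomenon being measured.

2. **Site calling.** Candidates are reference adenosines inside the
   mature span with G observed. Retention requires (i) ≥ 10 edited reads
   summed across samples, (ii) an upper-tail binomial test
   P(X ≥ k), X ~ Binomial(n, p) with p = 0.01 falling below α = 0.05 in
   at least one sample, and (iii) a mean editing level across samples of
   ≥ 10%. The three rules are independent per-site predicates, so their
   application order is irrelevant. The error-rate p, the tail threshold,
   the read floor and its scope (summed vs per-sample), and the level
   floor are all parameters: the summed-count reading of the 10-read rule
   is the default because a per-sample floor would be far stricter at
   typical coverages. Non-A→G substitutions go to a diagnostics table and
   never into the editing analysis.

3. **Differential editing.** Per retained site, the unpaired two-tailed
   Welch t-test on per-sample levels between the two design groups;
   Benjamini–Hochberg step-up FDR across all testable sites; a site is
   differentially edited when adjusted p < α = 0.05. Degenerate inputs:
   both groups constant with equal means gives t = 0, p = 1; constant
   with unequal means is flagged untestable (rather than reporting an
   infinite statistic) and excluded from the BH family, as are sites with
   fewer than two covered samples in a group. Constancy is detected by
   max = min, not by a variance threshold, to be robust to float
   cancellation.

4. **Target-pool switch.** The seed (positions 2–8) of the edited and
   non-edited isomiRs defines the canonical UTR site strings: 7mer-m8 is
   the reverse complement of the seed; 8mer appends the adenosine
   opposite miRNA position 1 (a literal A in the UTR regardless of the
   miRNA's first base, per TargetScan convention); 7mer-A1 is the reverse
   complement of positions 2–7 plus that A. All overlapping occurrences
   are found; a position is reported once with the strongest type
   (8mer > 7mer-m8 > 7mer-A1). A UTR with ≥ 1 site of any type is a
   target; pools are compared by shared count and Jaccard fraction
   (shared/union), with per-pool fractions also reported since the
   denominator convention for "% shared" is not standardized. No 6mer
   sites, 3'-supplementary pairing, context scoring or conservation — the
   scanner is deliberately the minimal canonical-site definition.

5. **Motif context.** Each called site contributes its X-A-Z
   trinucleotide, using the unedited reference base at the centre (the
   motif question concerns the ADAR substrate, not the G-containing
   product). Mature-boundary sites take the flanking hairpin base when
   available, else a `-` pad. The background is every adenosine in the
   expressed matures. A per-motif two-sided Fisher exact test with BH
   adjustment is available but off by default; the primary output is the
   count ranking.

Supporting utilities follow standard definitions: median-of-ratios size
factors (per-sample median over all-positive rows of count / row
geometric mean), Spearman correlation as Pearson on mid-ranks, and an
edited-on-total OLS regression whose residuals diagnose whether a change
in the edited form merely tracks overall abundance (default transform
log2(CPM+1), with a linear option; the transform is declared in the
output because published residual scales are generally not recoverable).

## Synthetic data

The generator emulates a two-group hippocampal small RNA-seq design and
is the package's validation substrate. Defaults are the modelled study
conditions:

| parameter | default | meaning |
|---|---|---|
| group_sizes | (8, 16) | controls vs cases |
| n_hairpins | 51 | one planted + 50 unedited miRNAs |
| mature_length | 21 nt | typical mature miRNA |
| coverage_mean | 2000 | reads per miRNA per sample |
| coverage_dispersion | 10 | negative-binomial size (CV ≈ 0.33) |
| planted site | position 6, 0.85 vs 0.79 | per-read edit probability per group |
| planted_context | UAG | ADAR-preferred trinucleotide around the planted A |
| error_rate | 0.01 | uniform per-base substitution probability |

Coverage is negative-binomial to mimic library-size variability (the
dispersion is a modelling choice; real coverage structure is
miRNA-dependent). Each read starts as the full-length mature sequence,
is edited at each planted site by an independent Bernoulli draw with its
group's fraction, then passed through uniform substitution errors (each
base to the three others with probability e/3), an optional ±1-nt end
jitter, and an optional 3' adapter. Quality strings are constant; the
pipeline never reads them.

Two routes produce data. The read-level route writes FASTQ and exercises
trimming, alignment and tallying. The count-level route draws the
per-position base tallies directly: the true edited count is drawn first
(Binomial(n, f)) and the observed counts conditional on it, so with
error_rate = 0 the observed G tally equals the ground truth exactly, and
for full-length reads the tallies are distributed identically to aligning
the read-level output. Power and false-discovery studies over many
replicates use the count route; scientific conclusions about the
alignment stage always come from the read route.

What the generator does **not** model: 5'/3' isomiR length heterogeneity
beyond the optional 1-nt jitter, cross-mapping between paralogous miRNA
family members, position- or quality-dependent error rates, multiple
editing chemistries, and PCR duplication. Passing tests therefore show
the statistical machinery behaves correctly under its stated model, not
that real libraries satisfy that model.

## Numerical choices

- Binomial tails via the survival function (stable to n ≥ 10^6); the
  test suite checks agreement with naive pmf summation to 1e-10 for
  n ≤ 1000.
- Editing level at n = 0 is missing (NaN), never 0, and missing cells are
  dropped pairwise in the group test.
- BH adjustment is the standard step-up with running-minimum
  monotonization, capped at 1.
- Tables are written as TSV with 17-significant-digit floats so
  write→read round-trips are exact to well below 1e-9.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline manifest records the seed
  and per-table checksums, and reruns are byte-identical.

## Validation problem sizes

The heavier checks run at deliberately modest scale: fraction recovery
uses 100 replicates of the default cohort (count route), error-model
specificity 20 replicates without planted edits at coverage 500, and the
all-null FDR study 200 replicates of a 100-site level matrix. The planted
0.85 vs 0.79 gap at coverage 2000 yields Welch statistics around |t| ≈ 14,
so detection is essentially certain and the binding checks are the
group-mean recovery (±0.02, which also absorbs the ≈ 0.008 downward bias
the 1% error channel introduces at high editing levels) and the null
behaviour. The realized all-null FDR of the Welch+BH combination sits
slightly above α (≈ 0.06 at these group sizes, a known small-sample
property of the t approximation), within the 0.075 tolerance used in the
tests.

## Known limitations

- Ungapped alignment cannot place reads over (rare) indel-bearing
  hairpins; such reads are lost, not miscounted.
- Ambiguous multi-hairpin reads are discarded, which undercounts editing
  in miRNA families with near-identical matures.
- The binomial error filter assumes a single uniform error rate; real
  error profiles are base- and cycle-dependent.
- Exactly two groups are supported; no covariates, pairing or
  permutation tests.
- The target scanner predicts canonical site presence only; it does not
  score site efficacy, conservation or accessibility.
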