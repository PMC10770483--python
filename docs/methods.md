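# Methods

This note records the models, conventions and numerical choices behind
`phla-audit`, and what the synthetic-data scenarios do and do not establish
about real data.

## Frequency-table cleaning

Allele names are truncated to the two-field form (allele group + specific
protein, e.g. `A*02:01`); higher fields describe synonymous or non-coding
variation that frequency tables and pHLA datasets do not resolve, and
expression suffixes are dropped. Parsing failures and unknown loci are hard
errors naming the offending token — silent coercion of allele names is the
classic way audits go wrong.

Duplicate (population, allele) entries keep the row with the largest reported
sample size, falling back to first-in-file order; every removal is returned
in a log with conflicting-frequency rows flagged. The rule is arbitrary but
deterministic and auditable, which matters more here than any particular
choice.

Each (population, locus) block must sum to 1. Sums within a tolerance
(default 0.05) are accepted and fixed up; sums outside it exclude the block.
Two fix-up modes exist:

* **renormalize** (default): divide by the sum — appropriate when the
  deviation is rounding noise;
* **residual-to-OTHER**: park a deficit 1 − s on a synthetic `OTHER` allele
  that no dataset pair can hit — appropriate when the deficit is real
  (rare unreported alleles), since renormalizing would inflate the hit
  probability of the reported alleles. An excess (s > 1) cannot be parked and
  is always rescaled.

Populations are then restricted to those typed at every configured locus
(default A, B, C), and annotated with the World Bank income level of their
country — resolved by longest-match of the population label against the
classification table's country names, with an explicit override map for
ambiguous labels and an explicit `unclassified` status (never a silent
default). Income bands follow the 2022–2023 classification: low ≤ \$1,085 <
lower-middle ≤ \$4,255 < upper-middle ≤ \$13,205 < high (GNI per capita; the
printed band edges overlap at \$13,205, resolved half-open as shown).

## Coverage model

Per locus, an individual's genotype is two draws from the population's
allele frequencies under Hardy–Weinberg equilibrium; loci are independent
(linkage disequilibrium between A, B and C is ignored, as in the standard
population-coverage construction). A dataset pair is hit when its allele
appears in the genotype; a homozygote hits a pair once, since a data point is
either represented in the genotype or it is not. Dataset alleles absent from
a population's table have frequency 0 and can never be hit.

The per-locus hit pmf is computed exactly by grouping alleles by their hit
count, convolving the two draws and correcting homozygotes allele by allele;
per-locus pmfs are convolved across loci in the fixed order A, B, C (the
result is order-invariant; the order only stabilizes logs). The pmf is
validated to sum to 1 within 1e−9 after every operation.

PC90 defaults to the integer tail definition — the largest n with
P(hits ≥ n) ≥ 0.90 — with linear interpolation of the tail function between
the bracketing integers available behind a flag, since published tools are
not explicit about which they report. sPC90 divides by the dataset size,
defined as the number of unique (peptide, allele) pairs after deconvolution
and deduplication: unique pairs are the input unit of the coverage
computation, so they are the natural denominator.

Two independent oracles guard the implementation: full enumeration of
ordered genotypes on small instances (≤ 3 alleles/locus, ≤ 2 loci) and a
Monte-Carlo sampler of HWE genotypes (100,000 draws, compared bin-wise at
3 standard errors). The Monte-Carlo cross-check runs on 15 randomized
instances: a 3σ per-bin bound over the ~500 bins of all 100 enumeration
instances would be expected to produce ~1.4 chance exceedances, so the
statistical check uses a sample where the expected false-failure count is
far below one.

## Group statistics

sPC90 values are grouped by income level and compared with one-way ANOVA
(scipy's between/within mean-square ratio; the all-values-identical
degenerate case is defined as F = 0, p = 1) and pairwise one-sided
two-sample KS tests asking whether the poorer group's values are
stochastically smaller. D is the supremum of ECDF_poorer − ECDF_richer and
the p-value is the plain Smirnov tail exp(−2mnD²/(m+n)); this is asymptotic
and conservative at small samples (at n ≤ 10 per group a warning is logged;
null rejection reaches the nominal 5% only around 1,000 values per sample,
which is what the calibration test uses). Pairwise p-values are reported raw
and Holm-adjusted, since a claim about every income pair is a multiple-testing
claim. ANOVA and KS are reported separately and never merged into one star.

## Predictor evaluation

Deconvolution assigns each multi-allelic record to the candidate allele with
the lowest percentile rank (highest strength breaks ties), because percentile
rank is the cross-allele-comparable output that the common tools expose.
Records whose best rank is ≥ 0.5 (percentile, i.e. 0.5% — the scale on which
those tools report "%rank"; the cutoff is configurable for the fractional
reading) are excluded as binders to none of their candidates. The cutoff is
inclusive. Mono-allelic records pass through untouched. Predictor failures
flag the record in the log rather than dropping it.

Decoys are substrings sampled uniformly over all (sequence, offset) positions
with replacement, per peptide length 8–11, 500,000 by default; sequences with
non-standard residues are skipped. One decoy set per length is shared across
alleles. Decoys are not filtered against the binder set by default (an
optional exact-match filter exists); with proteome-scale sampling the overlap
is negligible and filtering would bias the negatives.

PPV ranks binders and decoys together from strong to weak and takes the
binder fraction of the top n_a; at tied scores decoys rank ahead of binders,
which makes PPV conservative rather than optimistic. FOOP counts a binder
when its percentile rank — 100 · (# decoys ≥ it) / D — is at most 0.1%;
with D = 500,000 that is exactly decoy rank 500. Both metrics depend only on
the score ordering, hence are invariant under monotone transforms of the
strength scale.

## Synthetic scenarios

The generators emulate the statistical structure of the real inputs, not
their content:

* **Frequencies**: each (population, locus) block is a symmetric
  Dirichlet draw; the default concentration 0.5 over 12 alleles gives the
  long-tailed spectra typical of HLA loci (a few common alleles, many rare).
  Sums are exactly 1 by construction.
* **Income**: one synthetic country per population, five populations per
  income level by default, GNI values placed inside each World Bank band.
* **Dataset**: each record's presenting allele is drawn with weight
  (mean frequency among high-income populations)^β; β = 1 is unbiased, the
  biased scenario uses β = 3. 2,000 records by default, 8–11-mer i.i.d.
  uniform peptides, 30% multi-allelic (the presenting allele plus 1–5 others,
  capped at six — an MS sample's class I complement).
* **Proteome**: i.i.d. uniform residues; no composition bias, no real motifs.
* **Mock predictor**: strength = deterministic standard-normal hash of
  (peptide, allele, seed), plus a separation d_a for designated true binders
  of allele a; percentile rank is the upper tail of the N(0,1) background —
  a frozen reference that keeps strength and rank strictly consistent.

Everything is bit-reproducible under its seed.

Because dataset weights derive from the *high-income* mean frequencies only,
the three non-high income groups are exchangeable under this model: the bias
scenario predicts the high-income group's sPC90 elevation (and an overall
ANOVA signal), not a strict four-way ordering of group means. The end-to-end
bias-recovery test asserts exactly that, plus a positive Spearman correlation
between per-allele training count and PPV when the mock predictor's
separation increases with training count (d_a = 1 + 3·log(1+n_a)/log(1+max),
spanning 1–4 score standard deviations).

What passing these tests shows: the pipeline's machinery — cleaning,
coverage, statistics, deconvolution, evaluation — recovers a known injected
bias of realistic shape at desk scale (20 populations, 36 alleles,
1,500-record datasets, 1,000 decoys per length in the end-to-end test; the
FOOP threshold identity is exercised at the full 500,000-decoy scale). What
it does not show: anything about real allele-frequency structure (population
relatedness, linkage), real peptide chemistry, or any particular production
predictor — auditing those requires feeding the real tables, datasets and an
adapter for the real tool through the same interfaces.

## Known limitations

* Class II loci and within-country ancestry stratification are out of scope;
  populations are grouped only by their country's income level.
* Cross-locus independence (no LD) is assumed by the coverage model.
* The one-sided KS p-value is asymptotic; small income groups (common when
  few populations are typed at all three loci) make it conservative, which
  is flagged but not corrected.
* The mock predictor's binders are designated by construction; it validates
  the evaluation machinery, not any biological binding model.
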