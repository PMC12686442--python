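# Methods

## Motif model

A KFERQ-like motif is modelled as a 5-mer with a terminal anchor and a
composition constraint on the remaining four residues: 1–2 hydrophobic
residues from {F, I, L, V}, 1–2 positive residues from {K, R}, and exactly
one negative residue from {E, D}, with all four residues accounted for by
those classes. Three motif classes are scored:

* **canonical** — anchor Q at position 1 or 5, composition satisfied as-is;
* **phosphorylation-generated** — anchor Q, composition satisfied only when
  exactly one S/T/Y is recounted as the negative residue (so the unmodified
  window must contain no acidic residue; a window already canonical at that
  anchor is not additionally reported as phosphorylation-generated there);
* **acetylation-generated** — terminal K treated as the Q anchor, remaining
  four residues satisfying canonical composition.

Consequences worth noting: a window with K at both termini can be
acetylation-generated at both anchors and both calls are reported, and a
window can never be canonical at both termini (the second Q is an unclassed
residue). Exactly one PTM substitution is considered per classification;
windows combining an acetyl anchor with a phospho substitution form a
distinct optional class that is off by default, since three classes are the
standard reporting convention. Residue classes and ranges are a configurable
`MotifRuleSet` (YAML-loadable) because published motif-finder dialects differ
— e.g. whether W counts as hydrophobic or N as a Q surrogate; the default is
the strict rule above. Ambiguity letters (X, B, Z, U, O, J, `*`) void the
affected window only, not the protein: the conservative, local choice.
Coordinates are 0-based half-open internally and 1-based closed in reports.

Exactly 2 304 of the 20⁵ = 3 200 000 uniform 5-mers are canonical
(7.2 × 10⁻⁴); the test suite verifies this constant by full enumeration
against a closed-form count and uses it as a convergence target for sampled
frequencies.

Abundance comparisons between a query collection and a reference proteome
use one Fisher exact test (two-sided) per motif class on the
contains/not-contains table, BH-adjusted across classes. An exact test is
safe at any sample size; when a zero cell occurs the Haldane–Anscombe
corrected odds ratio is reported with a note. Inclusive counting (a protein
counted in every class it contains) is the default; exclusive counting
assigns each protein its highest-priority class
(canonical > phospho > acetyl).

## CMA transcriptional score

Raw counts are transformed x → log2(x+1); each network gene is z-scored
across samples with the population (n-denominator) standard deviation —
deterministic on two-sample fixtures — and the score is the weighted,
directed average Σ d·w·z / Σ w. Z-scoring makes genes commensurable, which
is what gives the LAMP2 weight of 2 meaning; it also makes the score
invariant to per-gene location/scale changes and gives it mean zero across
samples when no gene is dropped. Genes absent from the matrix or with zero
variance are dropped with a logged warning (sparse single-cell fixtures hit
this routinely) and the weight normalizer is recomputed over the genes used.

The shipped network table (`src/cmaflux/data/cma_network.tsv`) is a
literature-curated default — LAMP2 (weight 2, +), the HSC70 chaperone system
(HSPA8, HSP90AA1, DNAJB1, +), positive modulators (GFAP, NCOR1, NFE2L2,
PHLPP1) and negative modulators (RARA, AKT1, RICTOR, CTSA, EEF1A1, −). The
scoring operation is membership-agnostic and the table is plain TSV/YAML
config; studies should substitute their own curation. Two invariants are
enforced on load: negative modulators carry direction −1, and LAMP2, when
present, carries weight 2 and direction +1. Group comparisons use the
unpaired Student's t test (two-sided).

## Differential N/L testing and substrate calling

Raw-scale intensities are log2-transformed and median-centered per sample
(standard label-free normalization; can be disabled); log2-scale inputs are
used as-is. When complete donor annotations exist the default test is
paired: per-donor condition means are differenced and a one-sample t-test is
applied to the per-donor log2 differences, treating donor lines as the
experimental unit. Otherwise a Welch two-sample t-test per protein.
Requirements: ≥ 2 complete donor pairs (paired) or ≥ 2 quantified values per
group (unpaired); proteins failing this are flagged `insufficient_n`, not
tested, and proteins quantified in only one condition are flagged
`one_condition_only`. No imputation — it would inject untestable
assumptions. Zero within-group variance is reported at the limiting p-value
(0 for unequal means, 1 for identical groups) with a
`degenerate_variance` flag rather than NaN, so downstream filters behave
predictably. The vectorized implementation is verified against scipy's
scalar t-tests to 12 significant digits.

The substrate filter is one-directional by default — accumulation under
lysosomal blockade is what reveals degradation — with a two-sided variant by
flag. The p threshold (0.01) applies to raw p-values, matching the filter's
definition; BH q-values are additionally written for transparency. The
filter is monotone in both thresholds. Jaccard overlap of two empty sets is
defined as 0 with a logged notice.

## Enrichment statistics

The enrichment score is the weighted running-sum statistic: hits increment
by |score|^exponent normalized over in-set members, misses decrement by
1/(N − n_set), ES = signed maximum deviation. Ranking ties keep input order
(stable sort). The default proteome ranking metric is signed log2 fold
change, with the t-statistic available by flag. Null ES values come from
random same-size member sets (gene-set permutation); NES divides ES by the
mean |null ES| of matching sign, and the empirical p uses add-one smoothing
with the full permutation count in the denominator, so p ≥ 1/(n_perm+1)
exactly and is bit-reproducible under a fixed seed. ORA is the
hypergeometric upper tail on the background-intersected set with BH
correction across sets (bespoke multiple-testing schemes of web ORA tools
are out of scope). Pairwise result-set similarity is filtered at
Jaccard ≥ 0.25 by default, producing a plain edge-list TSV.

## Synthetic data

The generators are pure functions of (config, seed); defaults are the study
conditions used throughout the tests and the acceptance script.

* **Proteomes** (default 1000 proteins, lengths uniform 60–240, planted
  fractions 0.15 canonical / 0.15 phospho / 0.10 acetyl): backgrounds are
  rejection-sampled uniform sequences containing no motif of any class —
  rejection rather than alphabet restriction keeps background composition
  realistic. Planted sequences get one inserted pentapeptide of the assigned
  class at a random interior position and are re-sampled until the scanned
  class set equals exactly the assigned class, so recovered fractions equal
  planted fractions exactly.
* **Expression** (200 genes, 8 samples per group, effect 1.0 log2 units,
  noise SD 0.5): Gaussian-on-log baselines; the AMD-like group shifts each
  network gene by −direction × effect, making the planted score difference
  negative. n = 8 per group mirrors a small donor cohort.
* **N/L experiments** (500 proteins, 10% substrates, accumulation FC 2,
  noise SD 0.1 log2 units, 5 donors, donor-offset SD 0.3): log-normal
  intensity noise with additive log2 effects — the conventional label-free
  error model — and donor offsets shared between a donor's conditions to
  exercise the paired test. Planted substrates are always motif-positive;
  background proteins are motif-positive at 0.45, the approximate canonical
  motif prevalence in the human proteome. Missingness is completely at
  random (default 0).

What the generators do **not** emulate: realistic count-depth and dropout
structure of scRNA-seq, intensity-dependent (left-censored) missingness,
peptide-to-protein roll-up, correlated protein modules, and shared-substrate
structure between independently simulated conditions. Passing tests
therefore demonstrate correctness of the statistics and bookkeeping under a
clean error model, not robustness to those real-data pathologies.

## Pipeline

`run_pipeline` executes stages in fixed dependency order, writes plain-text
TSV/JSON everywhere for diffability, and records a manifest of input
checksums, parameters, seeds and output checksums; identical config + seed
reproduces every output byte-identically. A failing stage halts the run with
its name, leaving completed outputs plus a FAILED marker.

## Problem sizes and numerical choices

The test suite and acceptance script run the replicated designs at 50
replicates (500 proteins × 5 donors) for power/FDR estimates and 200 small
null experiments for type-I calibration; the 20⁵ window enumeration is done
once, vectorized. These sizes give Monte-Carlo errors comfortably below the
asserted margins. Permutation tests default to 1000 permutations. Seeds are
threaded explicitly through every stochastic call; nothing reads global RNG
state.

## Known limitations

The scanner ignores structural accessibility, HSC70-binding affinity and
cross-species motif conservation. The CMA score is a transcriptional proxy;
it cannot see post-transcriptional regulation of LAMP-2A. The substrate
caller identifies lysosomal-degradation candidates; distinguishing CMA from
macro- or microautophagy requires comparative inhibitor designs outside
this package's scope. The default CMA network membership is a curation
choice, not a measurement.
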