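# Methods

`colmut` implements an analysis pattern for somatic mutations in a gene
family within a tumor cohort — built around the case of collagen genes in
stomach adenocarcinoma, where individual genes are too rarely mutated for
conventional per-gene significance testing, but the family as a group and
small combinations of its members carry signal. This note records the models,
the statistical constructions, the defaults and why, and what the synthetic
cohorts do and do not establish.

## Mutation model and classification

Somatic variants are read from MC3-dialect MAF tables. Variants are collapsed
to three classes: **missense** (`Missense_Mutation`), **truncation**
(variants predicted to shorten or abolish the protein product: nonsense,
frameshift in either direction, splice-affecting, nonstop, and
translation-start variants), and **other** (silent, UTR/intronic, in-frame
indels, RNA, and anything unrecognized). In-frame indels preserve the reading
frame and are deliberately not counted as truncating. Sample identity is the
full `Tumor_Sample_Barcode` string; an explicit option truncates to the
15-character TCGA sample prefix, but no implicit normalization happens.
Hypermutated (MSIH) samples are analyzed as a stratum, never discarded or
capped: the hypermutator class is an object of study here, not a nuisance.

Protein positions are 1-based residues; gene sizes are coding bases, with
protein length taken as `coding_length // 3`.

## Gene-family burden

Two tests ask whether the family is mutated above background:

1. **Rank-sum on alteration frequencies.** The per-gene fraction of samples
   carrying a qualifying mutation, family vs all other genes, by two-sided
   Wilcoxon rank-sum (midranks; continuity-corrected normal approximation;
   exact enumeration when both groups have ≤ 8 members and no ties). This
   test ignores gene size.

2. **Moderated KS set test (size-aware).** Genes are ranked descending by
   *mutations per coding base* (ties broken by symbol, so the ranking is
   deterministic). For the sorted family ranks r₁ < … < r_k among N genes the
   statistic is

       D = max_j | j/k − r_j/N |,

   the sup distance between the family's rank positions and even spacing: 0
   when the family is spread uniformly through the ranking, → 1 when it
   occupies a narrow extreme block. Significance comes from random gene sets
   of size k; with length matching on (the default), each family gene is
   replaced by a random gene from the same coding-length decile, so null sets
   resemble the family in both size and length. The p-value uses the add-one
   estimator `(1 + #{D_null ≥ D}) / (n_perm + 1)`, which cannot reach zero.
   The ECDF is unweighted; the ranking-vs-reference comparison is isolated in
   one function (`ks_rank_statistic`) so a weighted variant could be swapped
   in without touching the permutation machinery.

   Because the ranking metric is already per-base, gene size enters the
   statistic itself; length-matched sampling additionally protects the null
   when family lengths are unrepresentative. Cohort strata (all / MSS / MSIH)
   are handled by filtering samples upstream, not inside the test.

## Survival primitives

Kaplan-Meier, the two-group log-rank test, and Cox proportional hazards are
implemented from first principles so each has an oracle-testable contract
(`lifelines` serves as an independent cross-check in the test suite, never as
the implementation).

* **KM**: product-limit over distinct event times; censorings at an event
  time count as at risk at that time. The median is the earliest event time
  with S(t) ≤ 0.5 (∞ if never reached).
* **Log-rank**: unweighted; hypergeometric means and variances per risk set;
  (O−E)²/V against χ²(1). Zero total variance yields p = 1 with a warning.
  A precomputed variant factors the risk-set bookkeeping out of the
  group-indicator reductions, making thousands of tests against one cohort
  cheap — the combination scan depends on this.
* **Cox**: Newton-Raphson on the partial likelihood, Efron tie correction by
  default (synthetic follow-up is month-resolution, so ties are heavy;
  Breslow is available and equals Efron exactly on tie-free data).
  Step-halving guards each update. Convergence is a gradient max-norm below
  `tol` (default 1e-7 — the achievable gradient noise floor on cohorts of a
  few hundred subjects sits near 1e-8, so a tighter default would flag
  fully-converged fits) with a negligible-step fallback. A converged flag
  with a diverging coefficient (|β| > 15) is reclassified as monotone
  likelihood (complete separation) and warned. Wald tests and 95% CIs on the
  log scale, exponentiated. The carry-forward rule for multivariate fits —
  screen covariates by univariate p < 0.05 — exists as an explicit optional
  step (`univariate_screen`), off by default.

## Combination-survival scan

The scan enumerates subsets of 2–3 *expressed* family genes (mean RSEM
strictly > 200 by default), marks each tumor by "≥ 1 qualifying mutation in
any subset gene", drops subsets below 5% prevalence, and tests mutated vs
wildtype survival by log-rank. Direction is the sign of the KM median
difference, falling back to the observed-vs-expected event balance when a
median is undefined.

**Background null.** For each candidate, random gene sets are drawn
genome-wide (family genes excluded by default): genes accumulate one at a
time, a gene that would overshoot is skipped, until the running mutation
total lands within ±5 of the candidate's own observed mutation count.
Candidates sharing a target total share one background sample of
`n_background` draws. Each draw is scored by the identical
indicator/prevalence/log-rank procedure; draws failing the prevalence rule
are excluded from the null denominator (at least 10 valid draws are
required). Matching on mutation count makes the null automatically account
for gene size and cohort mutation rate. The alternative reading of the
matching target — every candidate matched to the family-wide mutation
total — is available behind `match_family_total`.

**q-values.** With F₀ the add-one empirical null CDF evaluated at the
candidate's p, candidates are ranked by p and

    q_i = F₀(p_i) · m / rank(p_i),

monotonized by the Benjamini-Hochberg step-up sweep and capped at 1. This
empirical-null plug-in is a reconstruction of a bootstrap q-value; it is
deliberately conservative: the smallest attainable q at rank 1 is
`m / (n_background + 1)`, so resolving a lone signal among m candidates
requires `n_background ≳ 20·m`. Subset sizes are staged: pairs are scored
first, and any triple containing a pair already significant at the q
threshold is excluded (keyed on significance; q-values are computed within
each size stratum). Per-gene inclusion frequencies among significant
combinations are reported separately by direction.

## Clinicopathological association and germline comparison

Fisher's exact test is computed directly from the hypergeometric pmf
(two-sided p = sum of table probabilities ≤ the observed probability, with a
1e-12 tie tolerance); the odds ratio is the sample OR with a Haldane
half-count when a cell is zero. The r×c chi-square (Pearson, no continuity
correction) and Kruskal-Wallis (midrank tie correction, χ²(k−1) reference)
delegate to scipy; an exact-enumeration Kruskal-Wallis is available for
total n ≤ 10. Somatic-vs-germline position comparison reports the
Kruskal-Wallis p, shared-bin histograms, medians, and recurrent positions
(≥ 2 observations per source). Any N-/C-terminal bias is visible in the
histograms and medians but is not formally tested. Table strata are built
from user-declared categorical columns; no age or stage cutpoints are
hard-coded, and no multiple-testing correction is applied inside this module.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with planted
ground truth for recovery testing:

* Two microsatellite classes with Poisson per-sample mutation counts, mean
  `rate × total coding length`; defaults 3/Mb (MSS) and 30/Mb (MSIH) with 30%
  MSIH — the order-of-magnitude burden contrast of stomach cohorts. MSIL is
  not simulated as a distinct class.
* Mutations land on genes with probability ∝ coding length (× an optional
  family rate multiplier, 1 = null); truncating with probability 0.3, else
  missense; protein position uniform, with an optional recurrent-hotspot
  override for one gene (off by default).
* Survival is exponential at `baseline_hazard × exp(Σ active log-HRs)`
  (default 0.02/month), where an effect set is active for a sample mutated in
  any of its genes; censoring is an independent exponential (default
  0.015/month); observed times are rounded up to whole months, which produces
  the heavy ties that motivate Efron's correction. Administrative cutoff is
  not modeled.
* Expression is uniform on an RSEM-like range; gene annotation and a truth
  record (per-sample MSI class and hazard multiplier, planted sets, lengths)
  are emitted alongside MAF-dialect and clinical TSVs so the pipeline is
  exercised through its I/O layer.

Not emulated: copy-number events, subclonality, trinucleotide signatures,
covariate-dependent background mutation rates (expression, replication
timing), EBV / H. pylori status, and germline-somatic joint inheritance.
Passing recovery tests therefore show the estimators are correct and
calibrated under the stated generative model, not that real cohorts satisfy
that model.

## Study conditions used by the tests and acceptance script

Problem sizes are chosen so the whole battery runs in minutes on one core:

* **Burden calibration**: 200 null cohorts (100 samples, 300 genes, family of
  20 placed exchangeably, equal MSS/MSIH rates), 200 permutations; the
  rejection fraction at 0.05 must lie in [0.02, 0.09]. **Power**: 100 cohorts
  (150 samples, 500 genes, family of 20, rate ×3), 1000 permutations.
* **Cox recovery**: 20 cohorts of n=600 with planted HR 0.5 and ~30%
  censoring (mean β̂ within 0.1); 40–60 null cohorts of n=500 (mean β̂ within
  0.15, Wald p uniform).
* **Scan calibration**: 10 null cohorts (n=300, 40 family genes among 200,
  pairs + triples, 500 background draws); ≤ 10% of candidates at q ≤ 0.05.
* **Scan power**: 10 cohorts of n=400 with a planted protective pair
  (HR 0.4), 14 expressed family genes among 150, coding lengths 4–6 kb and
  mixed MSS/MSIH burden so the pair's joint prevalence concentrates near 10%,
  ~25% censoring, pairs only, 2000 background draws. The background size
  follows from the q-value floor above: with ~90 candidate pairs,
  `m/(n_background+1) ≈ 0.045` is the smallest q a lone rank-1 signal can
  attain, so 500 draws would make detection at q ≤ 0.05 arithmetically
  impossible regardless of effect size. Detection is required in ≥ 8/10
  replicates, with the planted genes topping the inclusion table.

## Known limitations

* The empirical-FDR construction is granular at small `n_background`; q
  near the floor `m/(n_background+1)` should be read as "at the resolution
  limit", and the scan reports draw counts in its metadata for this reason.
* The Cox implementation targets a handful of covariates (dense Hessian,
  no stratification, no time-varying effects, no Firth correction).
* The background sampler requires the target window to be reachable from the
  pool's per-gene counts; targets smaller than every single gene's count
  raise after a bounded number of restarts.
* Exact rank-sum enumeration assumes tie-free data and small groups; with
  ties the continuity-corrected normal approximation is used regardless of
  size.
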