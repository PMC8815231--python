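# colmut

Somatic mutation burden, combination-survival, and germline-comparison
analysis for gene families in tumor cohorts.

Some gene families — the motivating case is the 40-odd collagen genes in
stomach adenocarcinoma — are mutated too rarely per gene for standard
driver-detection tools, yet carry clear signal as a group: the family's
mutation burden exceeds what gene size predicts, and small *combinations* of
mutated family genes stratify patients by overall survival. `colmut`
packages that analysis pattern for anyone with a MAF-style mutation table,
a clinical table with overall survival, per-gene expression, and gene sizes:

* **Burden** (`colmut.burden`) — is the family mutated above background,
  accounting for gene size? Genes are ranked by mutations per coding base;
  the family's rank positions are compared to uniform spacing by the sup
  distance `D = max_j |j/k − r_j/N|`, with significance from random
  (optionally length-decile-matched) gene sets of the same size. A plain
  Wilcoxon rank-sum on per-gene alteration frequencies is included as the
  size-naive companion.
* **Survival** (`colmut.survival`) — Kaplan-Meier, two-group log-rank, and
  Cox proportional hazards (Efron/Breslow ties, Wald inference) implemented
  from first principles with oracle-tested contracts.
* **Combination scan** (`colmut.combos`) — enumerate subsets of 2–3
  expressed family genes (mean RSEM > 200), test mutated-vs-wildtype
  survival by log-rank, and assign empirical q-values against a bootstrap
  background of random gene sets matched to the candidate's mutation count
  within ±5 — so gene size and cohort mutation rate are built into the null.
  Per-gene inclusion frequencies summarize which family members drive the
  significant combinations.
* **Association** (`colmut.assoc`) — Fisher exact (direct hypergeometric
  sum), r×c chi-square, Kruskal-Wallis (with exact small-sample option), and
  somatic-vs-germline variant-position comparison with recurrent-position
  tables.
* **Synthetic cohorts** (`colmut.synthetic`) — a generator with two
  microsatellite burden classes (MSS ≈ 3/Mb, MSIH ≈ 30/Mb),
  length-proportional mutation placement, missense/truncation labels,
  proportional-hazards survival with planted effect gene sets, and a ground
  truth record, used throughout the tests to verify calibration and recovery.

## Worked example

Simulate a 400-sample cohort in which mutations in either of two family
genes (joint prevalence ≈ 13% here) multiply the death hazard by 0.4, then
scan all expressed family pairs:

```python
import numpy as np
import colmut as cm
from colmut.combos import CombinationConfig

config = cm.SimulationConfig(
    n_samples=400, n_genes=150, n_family_genes=14,
    gene_length_range=(4000, 6000), censoring_rate=0.006,
    effect_sets=[(frozenset({"FAM001", "FAM002"}), np.log(0.4))],
    expression_range=(250.0, 2000.0), seed=505)
mutations, clinical, expression, genes, truth = cm.simulate_cohort(config)
records = cm.records_from_frame(mutations)
lengths = dict(zip(genes["gene"], genes["coding_length"]))

scan = cm.run_combination_scan(
    records, clinical.set_index("sample"),
    expression.set_index("gene")["mean_rsem"], lengths,
    config.family_gene_names(),
    CombinationConfig(subset_sizes=(2,), n_background=2000, seed=5))
print(scan.to_frame().sort_values("q_value").head(3).to_string(index=False))
```

prints

```
        genes  n_mutated  prevalence    logrank_p direction  q_value
FAM001,FAM002         52      0.1300 1.359650e-09 longer_OS 0.008269
FAM001,FAM003         47      0.1175 4.786501e-04 longer_OS 0.008269
FAM001,FAM007         47      0.1175 1.456774e-05 longer_OS 0.008269
```

The planted pair tops the list: its 52 mutated tumors separate from wildtype
at log-rank p ≈ 1.4e-9, far beyond anything its mutation-count-matched
random gene sets achieve, giving q ≈ 0.008 with direction `longer_OS`
(mutated tumors live longer — the planted hazard ratio was 0.4). The two
runner-up pairs ride on the same signal, since each contains FAM001; the
inclusion-frequency table makes that explicit — FAM001 and FAM002 each
appear in 13 significant pairs, every other gene in at most 2:

```python
print(scan.inclusion["longer_OS"])   # {'FAM001': 13, 'FAM002': 13, 'FAM003': 2, ...}
```

The same objects drive the family burden test; here the family's per-base
mutation rate was *not* inflated, and the test correctly finds nothing:

```python
profiles = cm.gene_profiles(records, lengths, config.family_gene_names())
res = cm.moderated_ks_burden(profiles, config.family_gene_names(),
                             n_permutations=1000, seed=505)
print(f"D = {res.ks_statistic:.3f}, p = {res.p_value:.3f}")   # D = 0.192, p = 0.338
```

A command-line interface mirrors the library (`colmut simulate`, `colmut
burden`, `colmut survival`, `colmut combos`, `colmut assoc`,
`colmut compare-germline`); run `colmut --help` for the options.

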