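# covnet

Group-level **structural covariance networks** from regional brain volumes,
with weighted graph measures and permutation inference.

Given a table of per-subject regional volumes (e.g. FreeSurfer cortical,
subcortical and thalamic-nuclei segmentations) with group labels, age and
sex, `covnet`:

1. residualizes each region's volumes on `[1, age, sex]` by OLS within each
   group;
2. Pearson-correlates the residuals across subjects and zeroes negative
   coefficients, giving one symmetric weighted adjacency matrix per group
   (the covariance network exists at the group level, not per subject);
3. computes weighted network measures — global efficiency, local efficiency,
   mean clustering coefficient (Onnela), characteristic path length, average
   strength, average degree, and degree assortativity;
4. compares two groups with label-permutation tests (the full pipeline is
   recomputed per shuffle), percentile null confidence intervals, and
   Benjamini–Hochberg FDR across the measure set of each comparison.

A synthetic cohort generator with known covariate effects and prescribed
group-specific inter-regional correlation structure makes the whole pipeline
testable without patient data.

## CLI

```sh
covnet demo --seed 7 --permutations 200 --out demo_out
covnet generate --config examples/synthetic.yaml --out cohort.csv
covnet network  --cohort cohort.csv --group HC --out net_HC.tsv
covnet measures --matrix net_HC.tsv
covnet compare  --config examples/run.yaml
```

`demo` generates a three-group cohort (sizes 45 / 56 / 25, age ≈ 69.9 ± 11.9,
~47 % male) over an 82-region whole-brain set and a 50-nucleus thalamic set,
then runs all three pairwise comparisons on both networks and writes, per
(network, comparison): the group connectivity matrices (labeled square TSV),
a measures table, and a comparison table with columns
`measure, group_a, group_b, difference, ci_lower, ci_upper, p_value,
adjusted_p_value, significant`.

Cohort files are delimited text (comma or tab auto-detected) with header
`subject_id, group, age, sex, <region>, ...`; sex is accepted as 0/1 or F/M.

### Run configuration (YAML)

```yaml
cohort_path: cohort.csv
networks:
  global: [lh_bankssts, lh_cuneus, ...]   # exact column names
  thalamic: [thal_lh_AV, thal_lh_CeM, ...]
comparisons:
  - [HC, AD_no_epilepsy]
  - [AD_no_epilepsy, AD_epilepsy]
permutation: {n_permutations: 1000, seed: 0, alpha: 0.05, ci_level: 0.95}
distance_convention: inverse-weight       # or one-minus / neg-log
include_average_degree: true
dump_null: false                          # also write the raw null matrices
output_dir: results
```

## Conventions & caveats

- Shortest-path edge length defaults to `1 / weight`; alternatives
  (`1 - w`, `-ln w`) are available via `distance_convention`.
- "Partial correlation controlling age and sex" is implemented as Pearson
  correlation of OLS residuals on `[1, age, sex]` (covariate-adjusted
  correlation), not a partial correlation over all other regions, which is
  ill-posed for ~80 regions at n ≈ 25.
- The reported confidence interval is the **percentile interval of the
  permutation null distribution of differences** — it is not centered on the
  observed difference and need not bracket it.
- The permutation p-value uses the `(b + 1) / (m + 1)` estimator; with 1000
  permutations the smallest attainable p is ≈ 0.001.
- Undefined assortativity (zero degree variance, < 2 edges) is reported as
  `NA`, never coerced to 0, and is excluded from the FDR family of its
  comparison.
- `fdr_bh` is the standard step-up procedure. Published tables sometimes mix
  corrections; for the worked examples bundled in the tests, all cells except
  the largest raw p per table (which matches a Bonferroni-style `m·p`) are
  reproduced exactly.

## Library use

```python
import covnet as cv

spec = cv.SyntheticSpec(
    group_sizes={"A": 45, "B": 25},
    region_count=20,
    mean_volumes=3000.0, age_effect=-8.0, sex_effect=120.0,
    target_correlation={
        "A": cv.make_correlation_template(20, "modular", 0.5),
        "B": cv.make_correlation_template(20, "modular", 0.3),
    },
    noise_sd=250.0, seed=1,
)
cohort = cv.generate_cohort(spec)
net = cv.group_network(cohort, "A")
print(cv.all_measures(net))
results = cv.compare_groups(
    cohort.restrict_group("A"), cohort.restrict_group("B"),
    cv.PermutationConfig(n_permutations=1000, seed=1),
)
```
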