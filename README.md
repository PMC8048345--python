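# trajsurv

Coupling sparse Cox survival models with multivariate time-series clustering
for longitudinal transcriptomics.

## The problem

In prospective clinical cohorts, gene expression is measured repeatedly over
days or weeks while the clinical outcome is a time-to-event — here, the day a
trauma patient is discharged from hospital (length of stay). Two obstacles
make the joint analysis hard: the data are high-dimensional (tens of
thousands of genes, at most a few hundred patients), and the per-patient time
series are short, irregularly sampled, and truncated at discharge.

`trajsurv` implements a two-phase framework for this setting:

1. **Static phase — gene selection.** For each early sampling day, an
   elastic-net-penalized Cox model links that day's expression snapshot to
   the discharge hazard,

   h(t; xᵢ) = h₀(t) exp(xᵢᵀβ),   with penalty λ·Ψ(β), Ψ(β) = α‖β‖₁ + (1−α)‖β‖₂²,

   fitted by cyclical coordinate descent on the Breslow partial likelihood.
   The mixing parameter α is tuned by held-out Harrell c-index on a 70/30
   split; λ by cross-validated partial-likelihood deviance. Stability is
   enforced by leave-one-out cross-validation: only genes with a nonzero
   coefficient in *every* leave-one-out refit enter a day's stable set, and
   the union of the per-day sets is the gene signature.

2. **Longitudinal phase — trajectory clustering.** Restricted to the
   signature, the irregular series are completed on a reduced day grid
   (days with < 50% missingness) by a mixed imputation rule — carry the
   nearest draw within 2 days (LOCF/NOCB), otherwise linearly interpolate —
   and split into complete-case horizon datasets. Patients are then
   clustered with partition-around-medoids on the normalized triangular
   Global Alignment Kernel distance

   d(i, j) = 1 − exp( log k(i,j) − ½[log k(i,i) + log k(j,j)] ),

   where k sums, over all monotone alignments of the two series, products of
   a Gaussian-type local kernel on the per-day gene vectors. The number of
   clusters is chosen by the log-rank test separation of the clusters'
   Kaplan-Meier curves.

A fully-tested synthetic-cohort generator with planted prognostic genes,
trajectory clusters, irregular sampling and censoring makes every stage
testable without any external data.

## Worked example

```python
import trajsurv as ts

cfg = ts.CohortConfig(n_patients=120, n_genes=200, n_active_genes=8,
                      n_clusters=3, seed=1)
expression, survival, truth = ts.simulate_cohort(cfg)

pipe = ts.PipelineConfig(selection_days=(0, 1, 4), k_range=(2, 3, 4, 5),
                         n_folds=5, seed=1)
bundle = ts.run_pipeline(pipe, expression, survival, out_dir="run/")

sel = bundle["selection"]
print("alpha:", sel.alpha_opt)
print("signature:", sel.union_signature)
print("recovered:", sorted(set(sel.union_signature) & set(truth.active_genes)))
res = bundle["clustering"][7]
print("k_opt:", res["k_opt"], "log-rank p:", res["logrank"].p_value)
```

Output:

```
alpha: 0.2
signature: ('G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'G0006', 'G0007', 'G0008', 'G0134')
recovered: ['G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'G0006', 'G0007', 'G0008']
k_opt: 2 log-rank p: 6.109706790596188e-09
```

The tuned α is 0.2; the 9-gene signature contains all 8 planted prognostic
genes plus one false positive; the day-7 complete cases split into clusters
whose discharge curves differ far beyond chance (log-rank p ≈ 6·10⁻⁹).

The same pipeline is available from the shell:

```bash
trajsurv simulate --seed 1 --out cohort/
trajsurv run-all --expression cohort/expression.csv \
                 --survival cohort/survival.csv --seed 1 --out run/
```

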