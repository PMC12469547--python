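# metabloc

Differential analysis of two-group urinary metabolomics matrices, built
around the question of how preterm birth reshapes the neonatal urine
metabolome. The package takes a samples × metabolites intensity table
(LC-MS- or NMR-derived), a binary group labelling (preterm "Prem" vs
full-term "Term"), and a metabolite → biological-function annotation,
and runs the complete workflow:

1. **PQN** — probabilistic quotient normalization removes per-sample
   urinary dilution (division by the median intensity/reference
   quotient); **autoscaling** centers and unit-scales each metabolite.
2. **Univariate screen** — per-metabolite Mann–Whitney U, BH-FDR, and
   log2 fold change (Prem over Term); the volcano rule calls a
   metabolite significant when p_adj < 0.05 and |log2FC| > 0.6.
3. **PLS-DA** — NIPALS partial least squares on the centered dummy
   class, with R2Y, stratified-7-fold Q2Y, label-permutation validation
   (p = (1 + #{perm ≥ obs})/(B + 1)), and VIP scores
   (VIP_j = √(p·Σ_a SSY_a w²_aj/Σ_a SSY_a)) thresholded on a normality
   plot or at a manual cut-off.
4. **Multiblock model** — metabolites sharing a function form blocks
   (≥3 members); each block's OPLS-DA predictive score t1 is weighted
   by √n_k/√Σn_m into a samples × blocks superscore matrix, checked
   against the unblocked model, and screened by random-forest
   mean-decrease-Gini importance.
5. **Networks** — per group, shrinkage partial correlations
   (R* = λI + (1−λ)R, analytic λ; pcor_ij = −Ω_ij/√(Ω_ii Ω_jj)) over
   block superscores with exact-null edge p-values; the minimal network
   keeps the smallest p-ordered edge prefix covering every node;
   subtracting the Term network from the Prem one leaves the
   Prem-specific network, whose hubs are ranked by betweenness
   centrality.

A fully seeded synthetic-data generator (`metabloc.synthdata`) emulates
the study conditions — unbalanced groups (96 vs 45), log-normal
abundances, dilution, a planted fraction of differential metabolites,
block-structured correlation, and group-specific rewiring of the
inter-block dependence — with complete ground truth, so every stage is
testable without access to clinical data.

## Worked example

```python
from metabloc.synthdata import SynthConfig, generate_dataset
from metabloc.pipeline import PipelineConfig, analyze

ds = generate_dataset(SynthConfig(seed=4))      # 141 x 74, 14 blocks
res = analyze(ds.features, ds.metadata, ds.blocks,
              PipelineConfig(n_permutations=200, seed=5))

c = res["volcano_counts"]
print(f"significant: {c.up} up, {c.down} down of {c.up + c.down + c.ns}")
print(f"R2Y={res['plsda'].r2y:.2f}  Q2Y={res['permutation'].observed_q2y:.2f} "
      f"pQ2={res['permutation'].p_q2y:.3f}")
print("blocked vs unblocked |r| =",
      round(res["blocked_report"]["t1_abs_correlation"], 2))
print("hub blocks:", res["hubs"])
```

prints

```
significant: 9 up, 9 down of 74
R2Y=0.71  Q2Y=0.52 pQ2=0.005
blocked vs unblocked |r| = 0.99
hub blocks: ['B10', 'B14', 'B06']
```

18 of 74 metabolites pass the volcano rule; the discriminant model is
permutation-significant with Q2Y ≈ 0.5; the weighted block scores
reproduce the unblocked sample mapping almost perfectly; and three of
the fourteen functional blocks stand out as betweenness hubs of the
Prem-specific dependence network.

The same workflow runs from the shell:

```bash
metabloc simulate fixtures/ --seed 3
metabloc run -c config.yaml          # paths + thresholds + seed
metabloc subgroups --by sex --features fixtures/features.csv \
    --metadata fixtures/metadata.csv
```

`metabloc run` writes CSV/JSON stage outputs (normalized matrix,
univariate table, scores, VIPs, block scores, importances, per-group
minimal networks, differential edges, betweenness) plus `report.json`
and a reproducibility manifest under the configured run directory.

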