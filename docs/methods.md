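# Methods

`metabloc` implements a complete two-group urinary-metabolomics
differential analysis: dilution normalization, univariate screening,
latent-variable discriminant modelling, hierarchical multiblock scoring
of biological functions, and group-wise partial-correlation networks.
This note records the models, their assumptions, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Preprocessing

**Probabilistic quotient normalization (PQN).** Urine intensities are
dominated by per-sample dilution. The reference spectrum is the
per-metabolite median over *all* samples (both groups pooled — the
standard choice); each sample's dilution coefficient is the median of
its intensity/reference quotients over metabolites with a positive
reference, and the sample row is divided by it. Inputs must be strictly
positive with no missing values; the package refuses rather than
imputes, since silent imputation would propagate into every downstream
statistic. PQN is exactly idempotent only when rows differ purely by
dilution; on noisy data a second pass moves coefficients by a few
percent because the reference itself changes. Note that with ~46% of
metabolites genuinely shifted between groups, the median quotient is
protected only by the near-balance of up- and down-shifts.

**Autoscaling.** Each metabolite is centered to mean 0 and scaled to
unit sample sd (n−1 denominator) *after* PQN. Columns that are
numerically constant (sd at the rounding level of the mean) are dropped
with a warning. Scaling parameters are retained so that held-out
samples (cross-validation test folds) are scaled with training-fold
parameters only. The pipeline scales raw intensities, not
log-intensities — a consequential convention: large multiplicative
variation is exponentially skewed on the raw scale, which attenuates
linear correlations (see the generator notes below).

## Univariate screen

Per metabolite: two-sided Mann–Whitney U (exact enumeration when the
pooled n ≤ 12 without ties; otherwise the normal approximation with
midrank tie correction and continuity correction), Benjamini–Hochberg
step-up adjustment, and the log2 ratio of group means on PQN-normalized
(pre-autoscaling) intensities with Term as reference, so positive
log2FC means elevated in the preterm group. A metabolite is
"significant" under the volcano rule: adjusted p < 0.05 **and**
|log2FC| > 0.6. The group center is the mean by default (median
available); fold change must be computed before autoscaling because
autoscaled values can be negative.

## PLS-DA / OPLS-DA

The class is dummy-coded {0, 1} and centered, so PLS-DA reduces to
single-response NIPALS, non-iterative per component
(w ∝ X'y, t = Xw, p = X't/t't, c = y't/t't, deflate). Sign convention:
the largest-magnitude element of each weight vector is positive. R2Y is
the in-fit explained fraction of the centered dummy response. Two
predictive components by default.

**Q2Y** is estimated by stratified 7-fold cross-validation:
Q2Y = 1 − PRESS/SS_tot with autoscaling re-estimated inside each
training fold. Q2Y ≤ 0 means no predictive value.

**Permutation validation** re-draws the labels uniformly (200
permutations by default), recomputes R2Y and Q2Y per permutation
(cross-validation folds re-drawn each time), and reports
p = (1 + #{permuted ≥ observed}) / (B + 1), which can never be zero.
Because autoscaling does not involve the labels, the in-fold scaling is
identical across permutations and the test is exact for exchangeable
rows; null simulations show the rejection rate at 0.05 is at or below
nominal.

**OPLS-DA** follows the orthogonal-signal-correction scheme: from the
current weight w, the loading component orthogonal to w defines an
orthogonal weight, its score/loading pair is deflated from X, and the
final predictive component is extracted from the filtered matrix. Each
orthogonal score has exactly zero covariance with y and with the final
t1 by construction. When no y-orthogonal structure remains (e.g. a
rank-1 X), the remaining orthogonal components are left at zero rather
than raising — the model degrades to plain PLS-DA, which is the
behavior the degenerate case calls for.

**VIP.** VIP_j = sqrt(p · Σ_a SSY_a w_aj² / Σ_a SSY_a) with
SSY_a = c_a² t_a't_a; squared VIPs average to 1 over features. The
selection threshold comes from the normality plot (below) or a manual
value (the study configuration used 1.5 for LC-MS and 1.4 for NMR
data).

## The normality-plot threshold

Several stages select "the scores that start to deviate from a normal
distribution": VIP scores, random-forest Gini importances, betweenness
centralities. The procedure is traditionally applied visually; the
package operationalizes it as follows. Scores are placed on a normal QQ plot
(Blom plotting positions), a reference line is least-squares fitted
through the central 50% of points, and the largest score is compared
against a pointwise band of half-width
`k_sd · max(s_robust, sigma_top)`, where `s_robust` is the scaled MAD
of the central residuals and `sigma_top` is the asymptotic sd of the
top order statistic under the fitted line — the same pointwise band a
QQ-plot envelope draws. A score outside its band is peeled off and the
plot recomputed without it; peeling stops at the first in-band maximum.
The threshold is the smallest peeled score (+inf if nothing peels).

Two design points matter. First, peeling with recomputed positions is
essential: a contaminated upper tail displaces the plotting positions
of the bulk, so a single-pass rule flags bulk points far too often.
Second, the band grows toward the tail (`sigma_top`), since the top
order statistic of a normal sample fluctuates much more than central
ones; a constant MAD band misclassifies the bulk maximum in a sizable
fraction of samples. `k_sd` defaults to 2.0 and the central window is
configurable; a manual threshold always overrides.

Gini importances are **log-transformed** before thresholding: null
importances are positive, sum-constrained and strongly right-skewed
(increasingly so with more blocks), and on the raw scale the top block
is flagged in up to half of label-permuted runs. After the log
symmetrization the null selector returns an empty set in roughly
80–90% of permuted-label runs at 14 blocks; residual skew keeps it from
perfect specificity, which is a known limitation of normal-reference
selection applied to importance scores.

## Hierarchical multiblock model

Metabolites carry up to three biological-function annotations; the
inverse map (block → members, restricted to metabolites present) drops
blocks with fewer than three members. Each block gets an OPLS-DA with
one predictive + one orthogonal component on the globally autoscaled
columns (no per-block rescaling); its t1 is the block score. t1 is
normalized to unit sample sd and multiplied by the block-size weight
ω_k = sqrt(n_k)/sqrt(Σ n_m), so Σ ω_k² = 1 and the weight, not the raw
score norm, carries the size information (linear weighting available).
Degenerate blocks (rank < 2) fall back to a one-component PLS-DA score
with a warning.

A PLS-DA refit on the block-score matrix is compared with the unblocked
model: |Pearson r| between the two first predictive scores ≥ 0.7 (and
both permutation-significant) counts as "similar mapping". Note that
block scores are supervised projections: they separate the classes
in-sample even on label-independent data, and the blocked model's
permutation test is therefore anti-conservative under the null. The
calibrated null guard in this workflow is the *unblocked* model's
permutation test; the blocked comparison is a distortion check
conditional on a significant unblocked model, not an independent test.

Block selection uses a random forest (500 trees, Gini criterion,
sqrt(p) features per split, seeded) classifying group from the block
scores; mean-decrease-Gini importances are thresholded on the (logged)
normality plot as above.

## Partial-correlation networks

Per group, the correlation matrix R of block superscores is shrunk
toward the identity, R* = λI + (1−λ)R, with the analytic
Ledoit–Wolf/Schäfer–Strimmer weight λ = Σ Var̂(r_ij) / Σ r_ij² clipped
to [0, 1]; partial correlations come from the inverse:
pcor_ij = −Ω_ij/√(Ω_ii Ω_jj). Edge p-values use the exact null density
of sample partial correlations, r² ~ Beta(1/2, (κ−1)/2) with
κ = n − (G−2) − 1 floored at 3 — an analytic, deterministic replacement
for an empirical-null mixture fit. Since κ is shared by all edges of a
group, p-ordering equals |pcor|-ordering.

The **minimal network** is the shortest prefix of edges sorted by
(p ascending, |pcor| descending, lexicographic pair) in which every
node is incident to at least one edge ("coverage"; a connectivity
variant is available). Coverage is mandatory: a node whose best edge
has p = 1 still keeps that edge. The **differential network** is the
Prem minimal edge set minus the Term minimal edge set (attributes from
Prem, isolated nodes kept). Hubs are ranked by unweighted Brandes
betweenness (each unordered pair counted once, no normalization) and
selected by the normality-plot threshold (≥ 10 nodes; manual otherwise).

A structural property of the coverage-prefix definition is worth
stating: an edge whose endpoints are already covered when coverage
completes is excluded *regardless of its strength*. For a planted
spanning-tree dependence structure this caps the recoverable fraction
of true edges at roughly 0.75–0.77 at n = 45 even when the block
scores are replaced by the true latent factors — the sensitivity limit
is a property of the network definition, not of the estimation chain.

## Synthetic data generator

The generator emulates the study conditions: 96 Term vs 45 Prem
samples with 74 features in 14 functional blocks (NMR-like arm;
the LC-MS-like arm is 96/28 × 521 with 66 blocks), per-sample
log-normal dilution (sd 0.4 on the log scale), log-normal baselines,
multiplicative measurement noise (CV 10%), ~46% differential
metabolites with |log2FC| in [0.2, 1.5] split ~50/50 up/down, and
block-structured correlation. Per sample i and metabolite j:

```
x_ij = m_j · exp(s·zbar_ij) · exp(fc̃_j·(I[prem] + γ·vbar_ij)) · d_i · exp(τ·e_ij)
```

with block-activity factors z (class-independent; within-block
correlation 0.2), block expression-intensity factors v (sd multiplier
γ = 0.7 on each differential member's effect), dilution d and noise e.
The v factors are correlated along a spanning tree of blocks (edge
correlation 0.7, node degrees capped at 3) — the system's
inter-function wiring — and the Prem group's tree is an edge-disjoint
rewiring of the Term tree; the rewired edges are the planted
Prem-specific dependencies that the differential network should
recover. Group-mean log2 fold changes equal the planted values exactly
because the modulation has zero mean in both groups.

Several structural choices were driven by identifiability of the
planted network under the analysis chain itself, and double as honest
documentation of what the method can and cannot see:

* Inter-block dependence must live **along the fold-change pattern**
  (intensity modulation of differential members). A class-independent
  shared factor is precisely what the per-block OPLS-DA removes as
  orthogonal variation, so dependence planted there is invisible to
  superscore correlations.
* Differential metabolites are **single-function** markers. A strong
  differential column shared by several blocks couples their
  class-predictive scores and floods the partial-correlation matrix
  with spurious edges.
* Effect signs balance within each block, so block-intensity swings
  shift the per-sample median quotient (PQN) negligibly; net-signed
  blocks leak a common-mode factor into every normalized metabolite.
* Every block keeps at least two differential "anchor" members with
  the largest drawn magnitudes (lead markers); a block with no real
  effect mass has an uninformative score. The remaining differential
  metabolites concentrate in a 25% subset of "hot" blocks (sampling
  weight ×4), giving the random-forest stage genuine targets.
* The intensity-modulation sd γ is moderate (0.7): the pipeline
  autoscales raw intensities, so large log-scale modulations are
  exponentially squashed and the linear correlation between a block
  score and its intensity factor degrades.

What the generator does **not** emulate: raw spectra and their
processing artifacts (drift, batch effects, co-eluting features),
missing values, heavy-tailed or zero-inflated intensity distributions,
realistic annotation databases (function labels are exchangeable
symbols), and clinical covariate biology (the `sex` column is a pure
coin flip, present so the confounder-stratified models can be
exercised). Passing tests therefore demonstrate correctness of the
statistical machinery under a controlled generative model, not
performance on real urine matrices.

## Problem sizes and known limitations

The test suite and the acceptance script run the full pipeline at the
study's two dimensions (141×74/14 blocks and 124×521/66 blocks) with
200 permutations, and the simulation-based checks use 8–20 seeds;
these sizes keep every Monte-Carlo estimate stable at the asserted
tolerances while the whole suite stays fast.

Known limitations: (i) differential-network sensitivity is bounded
near 0.75 by the coverage-prefix definition (see above) and measures
~0.65 end-to-end at study scale — precision holds near 0.8–0.9;
(ii) the normality-plot selector is not exactly null-calibrated for
skewed scores even after symmetrization; (iii) the blocked model's
permutation p-value is optimistic under the null (supervised scores),
so it must be read as a distortion check only; (iv) PQN idempotence
and dilution recovery are exact only in the pure-dilution limit.
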