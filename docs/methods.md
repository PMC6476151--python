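# Methods

## Model

Let `X` be an n × p expression matrix and `y` a continuous phenotype, both
standardized with training statistics (candidate models carry no intercept;
centering absorbs it). Genes are organized into K groups
`G_1, …, G_K` — biological pathways (possibly overlapping), sequential
blocks, or marginal-correlation rank blocks. The fitted predictor is

    ŷ(x) = Σ_j w_j x_{G_j}ᵀ β̂_j ,

a weighted average of K group-wise linear candidate models.

**Candidate fits.** Each candidate is ridge-stabilized least squares,
`β̂_j = (G_jᵀG_j + δ I)⁻¹ G_jᵀ y`. The constant δ (default 1, applied
uniformly to every group) exists to keep the fit defined when `m_j > n`,
which is common for pathway groups; it is an ad hoc stabilization, not a
tuned penalty. When `m_j > n` the dual (kernel) form
`β̂_j = G_jᵀ(G_jG_jᵀ + δI)⁻¹y` is used, and the hat diagonal is computed as
`h_ii = 1 − δ[(G_jG_jᵀ + δI)⁻¹]_ii`, so cost scales with min(m_j, n).

**Jackknife weights.** Weights minimize the leave-one-out criterion
`CV(w) = ‖y − Ỹw‖²` where column j of `Ỹ` is candidate j's LOO prediction
vector, subject to box constraints `lower ≤ w_j ≤ upper` (default [0, 1]; a
[−1, 1] relaxation is available via the bounds). There is deliberately no
sum-to-one constraint: with only a few truly active pathways, the optimum
often zeroes most candidates and gives several informative ones weights
near 1. Because dropping observation i from a penalized linear smoother is
equivalent to replacing `y_i` by its LOO prediction, the PRESS shortcut

    ỹ_i = ŷ_i − h_ii (y_i − ŷ_i) / (1 − h_ii)

is *exact* for this estimator at any δ ≥ 0; the test suite certifies this
against an explicit n-fold refit oracle to 1e−8. If any `h_ii` reaches 1
(saturated candidate, e.g. δ = 0 with an identity-like design) the LOO
residual is undefined and fitting raises a `DegenerateFitError` telling the
user to increase δ — never a silent clamp, which would bias the criterion.

**Solver.** The criterion is bound-constrained least squares; we solve it
with a deterministic active-set/reflective method (`scipy.optimize.lsq_linear`,
BVLS when n ≥ K, TRF otherwise, tol 1e−12). Tests assert the KKT conditions
at every returned solution and agreement with exhaustive grid search. When
candidate columns are collinear the minimizer may be non-unique; the
criterion value is the canonical quantity and any returned minimizer is
accepted. Numerically bound-active weights are snapped to the bound so
"weight exactly zero" is meaningful.

## Group construction

* **GMT pathways** (`groups_from_gmt`): Broad-style GMT, case-sensitive
  identifier matching. Pathways with no expressed member are dropped with a
  log message; genes in no pathway are excluded from all candidates by
  default, or pooled into a `__remainder__` group on request — the original
  analysis does not say which was done, so both are provided.
* **Sequential blocks** (`groups_sequential`): K contiguous blocks with
  sizes differing by at most one (the simulation-study partitions 50/200/300).
* **Marginal correlation** (`groups_by_marginal_correlation`): genes ranked
  by |Pearson r with y| and split into K rank blocks — the comparator that
  builds candidates without external information. Zero-variance genes rank
  last; ties break by original column order for determinism.

## Synthetic data

`make_dataset` emulates the benchmark design: phenotypes

    y = Σ_j G_j β_j + e,   e ~ N(0, σ_e² I),

with 5 active groups drawn uniformly from K, and per-group nonzero-effect
proportions by scenario — I: (1,1,1,1,1); II: (1,1,.5,.5,.5);
III: (1,1,.8,.5,.2); IV: (.9,.7,.5,.3,.1). Nonzero counts are
round-half-up of proportion × m_j with a minimum of one; positions are
uniform within the group; effects are i.i.d. normal with one shared
variance, and a gene in two active overlapping groups receives the sum of
its draws (consistent with the additive model).

**PVE enforcement.** The genetic component `g = Xβ` is rescaled so its
empirical variance equals the target PVE exactly; then `σ_e² = 1 − PVE`, so
Var(y) ≈ 1 and `realized_pve = Var(g)/Var(y)` fluctuates around the target
only through the O(n^{−1/2}) sampling noise of Var(e). How the original
variance parameters were "carefully chosen" is unstated; empirical
rescaling is adopted because with correlated, overlapping groups the
analytic variance is partition-dependent, and it guarantees calibration for
any generator. The effect-scale σ_l² is absorbed by the rescaling.

**Expression surrogate.** Real tumour expression is replaced by a
block-exchangeable Gaussian: blocks of 50 consecutive genes share a common
factor giving within-block correlation 0.3 (both exposed parameters),
columns standardized. This reproduces the correlated-predictor regime but
*not* heavy-tailed/zero-inflated RNA-seq marginals, empirical pathway size
spread, or inter-pathway correlation structure — so green tests establish
method correctness and calibration under a stated Gaussian world, not
performance on real tumour data. The `overlapping-pathway-like` partition
assigns a configurable fraction (default 0.21, matching the reported share
of multi-pathway genes) of genes to a second random group.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
spawning, so datasets are bit-reproducible end to end.

## Evaluation protocol

Monte Carlo cross-validation: `n_splits` (100 in the full protocol, 20 in
desk-scale tests) random 80/20 train/test partitions, shared across methods
so per-split R differences are paired. Each method — including its
standardization and penalty tuning — sees only the training fold; a canary
test (a gene equal to y on test samples but noise on training) guards
against leakage. The score is test-set Pearson R; a constant prediction is
recorded as R = 0 with a flag rather than NaN, keeping summaries finite and
auditable. Baselines: scikit-learn `LassoCV` and `ElasticNetCV` with
l1_ratio 0.5 (the full protocol tuned by 100-fold CV; default here is
10-fold for speed, configurable), plus the equal-weight (1/K) averager.
Statistical tests on R differences are out of scope; the comparison is
descriptive, as in the original protocol.

## Preprocessing conventions

* Gene filter: drop genes with a zero-expression fraction **strictly
  greater** than 0.5 ("more than 50 %"); survivors standardized (mean 0,
  sample SD 1). In the CLI `fit` pipeline standardization is deferred to
  the estimator so the training means/scales are stored in the model
  archive and applied to new data at prediction time.
* Phenotype quantile normalization: rank-based inverse-normal transform
  `Φ⁻¹((rank_i − 0.5)/n)` with average ranks for ties. The exact offset
  convention used originally is unstated; the 0.5/n (Blom-like) offset is
  documented here and is rank-invariant under monotone transforms.
* Expression orientation is fixed (samples in rows, genes in columns); no
  auto-transposition.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| δ | 1.0 | ridge stabilization of candidate fits; accuracy is insensitive over 0.1–10 (tested) |
| (lower, upper) | (0, 1) | weight box; no sum-to-one constraint |
| n, p | 500, 6000 | simulated cohort size / transcriptome size |
| PVE | 0.3 (also 0.5, 0.8) | target variance explained by the genetic component |
| active groups | 5 | signal-carrying groups per dataset |
| block size / within-block r | 50 / 0.3 | expression correlation structure |
| n_splits / train fraction | 100 / 0.8 | MCCV protocol |
| zero-fraction threshold | 0.5 | gene filter, strict inequality |

## Known limitations

* Continuous phenotypes only; no generalized-linear candidates.
* δ is global; no per-group adaptation.
* The weight solution is reported as returned when candidates are collinear
  (criterion value is unique, the weight vector may not be).
* The synthetic generator is Gaussian; conclusions about real RNA-seq
  performance require real data.
* Identifier matching is exact and case-sensitive; no symbol/Entrez mapping.
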