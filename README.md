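# pathjma

Pathway-grouped **jackknife model averaging** for predicting a continuous
phenotype (e.g. cancer onset age) from high-dimensional gene expression.

## The problem and the method

Penalized regressions treat the transcriptome as a flat list of predictors,
ignoring the group structure that pathway databases (e.g. KEGG) provide.
`pathjma` instead builds one small candidate linear model per pathway/group
and averages them:

1. **Candidate models.** For each of K (possibly overlapping) gene groups,
   fit the group's genes `G_j` to the standardized phenotype by
   ridge-stabilized least squares,
   `β̂_j = (G_jᵀG_j + δ I)⁻¹ G_jᵀ y` (default δ = 1), so the fit stays
   well defined even when a pathway has more genes than samples.
2. **Jackknife weights.** Combine the candidates with weights `w` chosen to
   minimize the leave-one-out cross-validation criterion
   `CV(w) = ‖y − Ỹ w‖²`, where column j of `Ỹ` holds candidate j's
   leave-one-out predictions, subject only to box constraints
   `0 ≤ w_j ≤ 1`. The weights are **not** required to sum to one, so null
   pathways can be zeroed while several informative pathways contribute
   fully. LOO predictions come exactly from a single fit via the PRESS
   shortcut `ỹ_i = ŷ_i − h_ii (y_i − ŷ_i)/(1 − h_ii)`.
3. **Prediction.** `ŷ(x) = Σ_j w_j x_jᵀ β̂_j` on the training-standardized
   scale.

The package also ships the simulation design used to validate the method
(group-structured effects under scenarios I–IV with controlled phenotypic
variance explained, PVE) and a Monte Carlo cross-validation (MCCV) harness
that scores methods by test-set Pearson correlation R over repeated 80/20
splits, with lasso / elastic-net baselines and an equal-weight averager.

## Worked example

```python
import numpy as np
from pathjma import (JMARegressor, SimulationSpec, make_dataset,
                     make_splits, evaluate_estimator, compare_methods)
from pathjma.evaluate import summarize

ds = make_dataset(SimulationSpec(n=500, p=1000, partition="sequential-50",
                                 scenario="I", pve=0.5, seed=1))
model = JMARegressor(groups=ds.groups, delta=1.0).fit(ds.X, ds.y)
for j in np.argsort(-model.weights_)[:5]:
    print(ds.groups.group_names[j], round(model.weights_[j], 3))

plan = make_splits(500, n_splits=20, seed=1)
jma = evaluate_estimator(model, ds.X, ds.y, plan, name="jma")
eq = evaluate_estimator(JMARegressor(groups=ds.groups, weight_strategy="equal"),
                        ds.X, ds.y, plan, name="equal")
print(summarize(compare_methods([jma, eq], reference="jma")).to_string(index=False))
```

Output:

```
block_3 0.873
block_20 0.842
block_2 0.69
block_42 0.449
block_11 0.431
method   mean_R     sd_R  mean_R_difference  sd_R_difference  n_splits
 equal 0.355888 0.085767          -0.228646          0.05277        20
   jma 0.584534 0.056378           0.000000          0.00000        20
```

The dataset's five truly active groups are blocks 2, 3, 11, 20 and 42 — the
five largest weights recover exactly those groups, 26 of the 45 null groups
are zeroed outright, and the jackknife weights beat the fixed 1/K averager
by 0.23 in mean test-set R over 20 MCCV splits.

## Command line

```bash
pathjma simulate --n 500 --p 1000 --partition sequential-50 --pve 0.5 --seed 1 --out sim/
pathjma fit      --expression sim/expression.tsv --phenotype sim/phenotype.tsv \
                 --gmt sim/groups.gmt --out fit/        # model.json + weights.tsv
pathjma predict  --model fit/model.json --expression sim/expression.tsv --out pred.tsv
pathjma evaluate --expression sim/expression.tsv --phenotype sim/phenotype.tsv \
                 --gmt sim/groups.gmt --n-splits 100 --seed 1 --out eval/
```

`fit` accepts real data: a samples × genes TSV/CSV (gzip OK), a
two-column phenotype file, and a standard GMT pathway file; genes with more
than 50 % zero expression are removed and the phenotype can be
inverse-normal transformed with `--quantile-normalize`. Every command
writes a run manifest and is byte-reproducible under a fixed seed.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This regenerates, from scratch, 50 replicate synthetic datasets at each of
the lowest and highest PVE settings of the simulation design (n=500,
p=1000, 50 sequential groups, scenario I) and reports the mean realized
PVE — the calibration check that the phenotype generator hits its stated
variance-explained targets.
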