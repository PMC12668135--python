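# mmstack

**How much multimodal feature integration does brain-based behaviour
prediction actually need?**

`mmstack` is a Python package for researchers who predict psychometric
scores (cognition, emotion, personality) from many types of brain-derived
feature blocks — resting-state and task functional connectivity,
autoregressive time-varying FC, network statistics, diffusion-map gradient
loadings, morphometry and morphometric covariance, structural connectome
blocks — and want a statistically defensible answer to *which feature types
are necessary* rather than just a single pooled accuracy.

## The method

For a target $y$ and $F$ feature-type blocks, within every fold of a
family-aware repeated $k$-fold cross-validation:

1. **Feature-wise models.** Each block gets an elastic-net model. The eight
   confounds (age, age², gender, age·gender, age²·gender, handedness, brain
   size, ICV; gender coded 1=female, 2=male) are regressed from the target
   with training-only coefficients; features are z-scored with training
   statistics; the L1 ratio and penalty $\alpha$ come from an inner 5-fold
   grid search. A *confound model* (confounds as features, no
   deconfounding) competes on equal terms.
2. **Stacking at every integration level.** Blocks are ranked by
   training-split accuracy computed from nested-CV predictions (no test
   information). For level $k = 2 \dots F$, the top-$k$ models'
   predictions form a meta-feature matrix — training rows from nested 5-fold
   predictions, test rows from the outer models — and a Random-Forest
   meta-model is tuned and fitted on it. Level 1 is the top-ranked base
   model itself.
3. **Saturation inference.** Fold-wise accuracies (Pearson $R$ and COD
   $R^2 = 1 - SS_{res}/SS_{tot}$) of all levels are compared pairwise with
   the corrected resampled t-test,

   $$t = \frac{\bar d}{\sqrt{\left(\tfrac{1}{J} + \tfrac{n_{test}}{n_{train}}\right) s_d^2}},\qquad df = J-1,$$

   Holm-corrected over all pairs. The **best** set is the level with the
   highest mean accuracy; the **necessary** set is the lowest level whose
   corrected $p$ against the best is $\ge \alpha$ — where performance
   saturates. A validity filter keeps only targets with necessary-level
   mean COD $> 0$.

Every group-level parameter — confound coefficients, feature
standardisation, gradient templates, morphometric-covariance z-scoring,
meta-features — is estimated on training subjects only, per fold, and
family members never straddle a train/test boundary.

Because real multimodal cohorts of this kind are access-restricted, the
package ships a synthetic-cohort generator that plants a known latent trait
in a chosen subset of blocks (with configurable sharing, confound
contamination and noise) and records the exact linear combination in a
manifest, so every stage can be validated against ground truth.

## Worked example

```python
import mmstack as ms

spec = ms.CohortSpec(
    n_subjects=200, folds_hint=5,
    informative=("fc_rest", "fc_task", "morph_gmv"),
    signal_r2=0.6, confound_r2=0.1, latent_sharing=0.0)

model = ms.MultimodalStacking.from_synthetic(
    spec, seed=5, repeats=2, folds=5,
    enet_grid=ms.HyperparamGrid(l1_ratios=(0.5,), alphas=(0.01, 0.1, 1.0)),
    rf_grid=ms.RFGrid(n_estimators=(50,), max_depths=(3,),
                      max_features=(1.0,)))
res = model.fit(seed=0)
print(res.mean_accuracy("pearson_r").round(3))
print(res.summary())
```

prints the integration curve (mean correlation accuracy per level)

```
level
1    0.297
2    0.328
3    0.344
4    0.375
5    0.359
6    0.369
7    0.369
```

and a summary table reporting `Best level: 4 (mean 0.375 R, 0.107 COD)`,
`Necessary level: 1 (mean 0.297 R, 0.050 COD)`, `Validity (COD>0): True`,
followed by the necessary-set composition (here `fc_task` 0.50,
`morph_gmv` 0.30, `confounds` 0.20 across the ten folds). Read: with three
complementary planted blocks, accuracy rises from $R=0.30$ (best single
feature type) and saturates around $R\approx0.37$ once the informative
blocks are integrated; at this desk-scale $J=10$ the conservative corrected
test already calls level 1 statistically comparable to the best.
`res.composition()` shows which blocks populate the necessary set across
folds, and `res.plot_integration_curve()` draws the curve.

The same run is available from the shell via a YAML config:

```bash
mmstack run --config demo.yaml     # stages: simulate features base stack saturate report
```

which persists every stage (TSV/JSON) under the configured output
directory and can resume from completed stages.

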