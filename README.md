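# sstclassify

Label-free classification of somatostatin (SST) interneuron subtypes from
in vivo two-photon calcium imaging, with the downstream learning-plasticity
and behavioral quantifications.

## The problem

Layer 2/3 SST interneurons of mouse barrel cortex are molecularly
heterogeneous. The Martinotti-type subpopulation expressing calbindin-2
(SST-Calb2) is selectively suppressed when mice learn a whisker-stimulus /
water-reward association (sensory association training, SAT), while the
remaining SST neurons (SST-O) are not. SST-Calb2 cells also show higher
stimulus response probability and evoked peaks already before training.
This package implements the full analysis that exploits that signature:
starting from raw ROI/neuropil fluorescence traces it classifies putative
SST-Calb2 neurons from pretraining activity alone — no genetic label — and
quantifies the training-epoch plasticity and home-cage behavior.

## The method

1. **Preprocessing.** Neuropil correction
   `F_corrected = F_ROI − 0.7·F_neuropil`; frames displaced > 20 px are
   interpolated (runs of 1–2 frames) or invalidate the overlapping trial
   (runs ≥ 3). Trial ΔF/F₀ uses the 1-s pre-onset mean as `F₀` over
   −3…+5 s windows; spontaneous ΔF/F₀ uses a 1-min sliding 20th-percentile
   baseline.
2. **Features.** A grid of 126 first-order features per cell (averaged over
   acclimation days ACC4–6): response probabilities at thresholds
   k·σ₁ (k ∈ {1,2,3,5,10}, σ₁ = SD of concatenated pre-trial baselines);
   in-trial peak / latency / center of mass / AUC over named periods;
   spontaneous event counts and amplitudes at prominence thresholds k·σ₂
   (k ∈ 1…10, σ₂ = whole-session ΔF/F₀ SD) plus block AUC.
3. **Classification.** Features ranked by unpaired t-tests between genetic
   labels; the top 30 are z-scored, embedded with UMAP, and clustered
   (k-means, spectral, DBSCAN) over a hyperparameter grid. Solutions are
   ranked by silhouette score in embedding space; the cluster with the
   highest mean stimulus response probability and evoked peak (rank sum)
   becomes putative SST-Calb2. Predictions are evaluated against genetic
   labels by confusion-matrix metrics.
4. **Plasticity & behavior.** Daily mean evoked peaks, fold changes of
   training epochs (SAT1/2, SAT5/6, SAT9/10) against the ACC4–6 baseline,
   paired t-tests with Bonferroni correction and repeated-measures ANOVA;
   anticipatory-lick performance (`f_stimulus − f_blank` in the 300-ms
   pre-reward window, 4-hour bins with a ≥10-trial filter).

A synthetic-session generator (`sstclassify.synthetic`) produces labeled
experiments with the same statistical structure — trial schedule,
subtype-specific response statistics, training-epoch suppression, neuropil
mixing, shift artifacts — so every stage is testable end to end with known
ground truth.

## Worked example

```python
import pandas as pd
from sstclassify import make_fixture, build_feature_matrix, evaluate
from sstclassify.classify import (SubtypeClusterPipeline,
                                  small_embedding_grid, small_cluster_grid)

exp, truth = make_fixture("two-class-labeled", seed=2)
X, grid = build_feature_matrix(exp)                  # cells x 126 features
y = pd.Series([exp.registry.true_label(c) for c in X.index], index=X.index)

pipe = SubtypeClusterPipeline(embed_grid=small_embedding_grid(2),
                              cluster_grid=small_cluster_grid(),
                              random_state=2).fit(X, y)
res = evaluate(pipe.predicted_, y)
print("best solution:", pipe.solution_.method, pipe.solution_.params,
      "silhouette=%.3f" % pipe.solution_.silhouette)
print("confusion: TP=%d FP=%d TN=%d FN=%d" % (res.tp, res.fp, res.tn, res.fn))
print("F1=%.3f accuracy=%.2f" % (res.metrics["f1"], res.metrics["accuracy"]))
```

prints

```
best solution: kmeans {'n_clusters': 2} silhouette=0.890
confusion: TP=14 FP=0 TN=14 FN=0
F1=1.000 accuracy=1.00
```

i.e. on a 28-cell synthetic population with the documented subtype effect
sizes, the label-free pipeline recovers the planted classes perfectly (real
recordings are harder; the confusion-matrix utilities reproduce any printed
counts exactly). Adding training days and running the plasticity stage:

```python
from dataclasses import replace
from sstclassify import (GeneratorConfig, generate_experiment,
                         plasticity_table, epoch_fold_changes)
from sstclassify.synthetic import default_subtypes

spec = replace(default_subtypes()[0], n_cells=28)   # Calb2-like class
cfg = GeneratorConfig(subtypes=(spec,),
                      days=("ACC4", "ACC5", "ACC6", "SAT1", "SAT2",
                            "SAT5", "SAT6", "SAT9", "SAT10"))
sat_exp, _ = generate_experiment(cfg, seed=1)
fc = epoch_fold_changes(plasticity_table(sat_exp), "true_label")
print(fc.round(3).to_string(index=False))
```

```
    group   epoch  n  mean   sem
SST-Calb2  SAT1/2 28 0.572 0.029
SST-Calb2  SAT5/6 28 0.515 0.027
SST-Calb2 SAT9/10 28 0.439 0.022
```

The group mean fold changes track the generating suppression schedule
(0.62 → 0.56 → 0.46 at its anchor days) within the population SEM.

There is also a thin CLI (`sstclassify simulate / features / classify /
plasticity / behavior`) over the same functions.

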