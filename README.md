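# healthspace

Multivariate treatment effects are easy to measure and hard to read: a
plasma panel of clinical chemistry, proteomics and metabolomics easily runs
to hundreds of parameters, and ordination methods (PCA, plain PLS-DA)
project them onto axes defined by variance, not biology.  `healthspace`
implements a *process-anchored* alternative for placebo-controlled
cross-over intervention studies: each axis of the space is a predefined
biological process (for example oxidation, inflammation, metabolism), and a
subject's coordinate on that axis is the prediction score of a supervised
multivariate model built from that process's parameters only.  The result
is a low-dimensional map in which group effects, responder subgroups and
individual responses can all be read off in biological terms.

It is aimed at biostatisticians and systems-biology researchers analysing
two-arm cross-over trials (nutrition, pharma, lifestyle) with wide omics
panels and curated parameter-to-process annotations.

## Method

For each process axis with parameter set *P*:

1. **Features** — per subject and arm, each parameter in *P* contributes
   its baseline value and/or its mean over the period's timepoints
   (configurable per parameter).
2. **PLS-DA** — the features are autoscaled (mean 0, unit SD per column)
   and a NIPALS PLS1 model regresses the arm code *y* (treated = 0,
   control = 1) on them.  The number of latent variables is chosen by
   **double cross-validation**: outer folds over subjects (both arms of a
   subject always travel together) produce out-of-fold prediction scores
   `ŷ`, while an inner cross-validation inside each outer training set
   selects the component count with the lowest misclassification rate.
3. **Anchor scaling** — per axis, scores are mapped by
   `s' = (s − m_T) / (m_C − m_T)` with `m_T`, `m_C` the treated/control
   mean scores, so the treated-group mean sits exactly at 0 ("health", the
   average state after the active intervention) and the control mean at 1.
   Scores are comparable within an axis, deliberately not across axes.
4. **Responder subgroups** — per subject, the response vector is the
   per-axis difference control − treated.  Vectors are clustered by
   hierarchical clustering (Euclidean distance, average/UPGMA linkage, no
   additional scaling); extreme singleton branches are flagged as
   outliers.  Clusters are characterized parameter-by-parameter with an
   interaction-first two-way ANOVA (cluster × treatment, Type II sums of
   squares) under Benjamini–Hochberg FDR control at α = 0.05.

A synthetic-study generator (`healthspace.synth`) simulates the whole
design — cross-over arms, timepoints, process blocks with correlated
noise, planted responder subgroups — so every stage is testable with known
ground truth.

## Worked example

```bash
healthspace simulate --preset full --seed 42 --out run/sim
healthspace fit --samples run/sim/samples.csv --axes run/sim/axes.yaml \
    --seed 42 --out run/fit
healthspace cluster --scores run/fit/scores.tsv \
    --samples run/sim/samples.csv --out run/cluster
healthspace plot --scores run/fit/scores.tsv --out run/figures
```

The `fit` step logs one line per axis (values from the run above):

```
INFO healthspace: axis oxidation: oof misclassification 0.379, components per fold [1, 1, 1, 1, 1, 2, 1], anchors treated=0.4385 control=0.5646
INFO healthspace: axis inflammation: oof misclassification 0.379, components per fold [1, 1, 3, 4, 2, 1, 1], anchors treated=0.446 control=0.6288
INFO healthspace: axis metabolism: oof misclassification 0.333, components per fold [1, 1, 1, 1, 1, 1, 1], anchors treated=0.4035 control=0.5869
```

`oof misclassification` is the out-of-fold error of each axis model (0.5 ≈
uninformative axis, warned about), `components per fold` the latent
variables chosen per outer fold, and the anchors are the raw score means
that the scaling maps to 0 and 1.  `run/fit/scores.tsv` then holds one row
per subject and arm with the anchored coordinates; per axis the treated
rows average exactly 0 and the control rows exactly 1.  The cluster step
writes `responses.tsv` (per-subject response vectors, cluster labels,
outlier flags), a Newick dendrogram, a heatmap figure and `anova.tsv` with
per-parameter interaction/main-effect F, p, q values and a verdict column.

The same pipeline is available as a library:

```python
import healthspace as hs

cfg = hs.preset_config("full", seed=42)
table, truth = hs.generate_study(cfg)
model, scores = hs.build_health_space(table, hs.default_axes(cfg), seed=42)
clusterer = hs.ResponseClustering(n_clusters=2).fit(scores)
anova = hs.characterize_clusters(table, clusterer.responses_)
```

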