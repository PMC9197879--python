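# morphotime

Morphological cell typing and developmental pseudotime for single-neuron
reconstructions.

Cerebellar molecular-layer interneurons (MLIs) — the basket and stellate
cells that inhibit Purkinje cells — have been argued to form either two
discrete types or one continuously varying population, and it was unclear
whether the two phenotypes diverge early in development or only after cells
settle at their final laminar depth. `morphotime` implements the
quantitative-morphology toolkit for attacking both questions from SWC
reconstructions: morphometric feature extraction, two-clade clustering with
stability cross-validation and feature ablation, diffusion-map pseudotime
ordering of developmental snapshots, and a nearest-neighbor fate co-sorting
statistic with per-bin nulls. It is aimed at neuroanatomists and
computational biologists working with reconstruction archives
(NeuroMorpho-style SWC plus per-cell annotation tables) or precomputed
morphometric tables.

## The statistics at the core

**Clustering.** Feature tables are zero-mean standardized
(x → (x − μ)/σ) and clustered by Ward's method on Euclidean distance; the
merge tree is cut into two clades. Robustness is assessed by subsample
cross-validation — recluster random subsets, name each clade by the
majority reference label, score accuracy = #correct/#drawn over 20 trials
per size — and by recursive feature elimination scored with the adjusted
Rand index.

**Pseudotime.** A kNN affinity graph W with adaptive Gaussian kernel
(bandwidth = distance to the k-th neighbor) yields the transition operator
P = D⁻¹W; its non-trivial right eigenvectors ψ_i, weighted λ_i/(1 − λ_i)
(multiscale diffusion distance), give the diffusion components. Pseudotime
is the distance from a start cell in the axis-standardized 2-D embedding,
min–max normalized to [0, 1]. Louvain communities on a k = 20 graph define
discrete morphological states.

**Fate co-sorting.** For each cell, the fraction of its 5 nearest
embedding neighbors sharing its birthdate-cohort fate; binned into 0.2-wide
pseudotime intervals and compared per fate and bin against the null
(#fate-in-bin / #cells-in-bin) with percentile-bootstrap 95% CIs and a
one-sided one-sample t-test. Early fate divergence shows up as
above-null co-sorting already in the earliest bin.

Synthetic generators with analytic ground truth (Gaussian two-class mature
populations, latent-maturation developmental cohorts with a controllable
divergence point, and randomized SWC trees whose features are known by
construction) make every stage testable offline; see `docs/methods.md`.

## Worked example

```python
import morphotime as mt

# mature population: two clades and their stability
table, truth = mt.simulate_mature(seed=0)          # 19 + 60 cells, 27 features
results = mt.MorphologyClustering(table).fit()
print(results.summary())
cv = results.subsample_cv(sizes=[10, 20, 40], trials=20, seed=0)
print(cv.to_frame())

# development: pseudotime ordering and fate co-sorting
dtab, dtruth = mt.simulate_development(seed=0)     # 732 cells, 28 features
pt = mt.PseudotimeModel(dtab).fit(seed=0)
print(pt.summary())
cosort = pt.cosort().fit(reps=1000, seed=0)
print(cosort.summary())
```

prints

```
Morphological clustering
========================================
cells:            79
features:         27
linkage/metric:   ward/euclidean
clades:           2
  clade A: 20 cells
  clade B: 59 cells
silhouette:       0.183

 size  mean_accuracy      sem  trials
   10         0.9800 0.011698      20
   20         0.9825 0.006564      20
   40         0.9900 0.002810      20
```

— the two simulated classes are recovered (clade A captures the basket-like
class, 20 vs the 19 generated) and as few as 10–20 subsampled cells
reclassify at ~98% accuracy — and

```
Diffusion pseudotime
========================================
cells:             732 (732 on the main component)
knn / components:  10 / 5
start cell:        dev0598
eigenvalues:       [0.994 0.987 0.976 0.97  0.958]
communities:       8
pseudotime range:  [0.000, 1.000]

Fate co-sorting (k nearest neighbors per pseudotime bin)
============================================================
cells: 732   k: 5   bin width: 0.2   bootstrap reps: 1000

fate         bin     n    mean    null                CI         p
BC_fated       0   175   0.755   0.612    [0.712, 0.795]   1.6e-10
SC_fated       0   111   0.632   0.388    [0.571, 0.686]   2.1e-13
...
```

— in the earliest fifth of the maturation timeline, early-born (BC-fated)
cells already have 75.5% same-cohort neighbors against a 61.2% chance
level (and late-born cells 63.2% against 38.8%): the two fates are
morphologically distinguishable from the start, the signature of early
subtype divergence.

A `morphotime` console script exposes the same stages
(`simulate`, `features`, `cluster`, `cv`, `pseudotime`, `cosort`); run
`morphotime --help`.

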