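# emtscape

Multiphasic analysis of the epithelial–mesenchymal spectrum in bulk
transcriptomes.

## The problem

Epithelial–mesenchymal transition (EMT) converts rigid epithelial cells into
motile mesenchymal ones, and tumour cells occupy the whole spectrum in
between — including *hybrid* states in which both the epithelial (E) and
mesenchymal (M) gene programs are highly active at once.  `emtscape` is for
computational biologists who want to place samples in a two-dimensional E–M
score plane, find the subpopulations that live there, and reconstruct the
nonlinear paths cells take between the E and M poles.

## What it computes

* **E/M scores.**  Each sample gets a score in [−1, 1] per signature gene
  set, via the kernel-ECDF → cross-sample ranking → symmetric rank statistic
  → weighted Kolmogorov–Smirnov random-walk procedure of gene set variation
  analysis: for gene *i* in sample *j*,
  `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with `h_i = sd_i/4` on
  log2(x+1)-transformed abundance; genes are ranked per sample by decreasing
  `z`, weighted by `|p/2 − r|`, and the walk's signed extrema give the
  enrichment score.
* **Subpopulations.**  Diagonal-family Gaussian mixtures over (E, M) pairs
  with the six axis-aligned covariance structures (EII, VII, EEI, VEI, EVI,
  VVI), selected by BIC = −2 log L + d log n (lower is better), components
  labelled semantically: E, I0 (low–low), I1 (hybrid high–high), I2
  (M-adjacent), M.
* **EMT paths.**  Rotated coordinates u = (E−M)/√2 (progression) and
  v = (E+M)/√2 (deviation); minimal cluster paths from E to M over an
  adjacency graph of component means; segmented (broken-line) regression of
  v on u with iteratively estimated breakpoints ψ, Davies and pseudo-score
  breakpoint-existence tests, and score-inversion confidence intervals.
* **Time courses.**  Triphasic E(t)/M(t) segmented models for TGF-β
  induction experiments (breakpoints initialised at 2.5 and 10 days), bound
  models pinning the first breakpoint at its CI endpoints, and mapping of
  the modelled trajectory to mixture-state probabilities.
* **Gene subclusters.**  Semi-supervised subclustering of E/M genes from a
  TGF-β × ZEB1 perturbation panel: 10×10 self-organizing map, node labelling
  by annotated-gene majority, Ward + elbow subclustering, and subcluster
  scoring over time.
* **Group statistics.**  Welch's t with Benjamini–Hochberg adjustment, and
  chi-squared subtype-enrichment tests.
* **Synthetic data.**  Generators for cohorts on a five-state EMT path
  geometry, low–low outgroups, triphasic time courses and logic-gate
  perturbation panels, each emitting its generating truth — so the whole
  pipeline is testable without any cohort download.

## Worked example

```python
import numpy as np
from emtscape import synthetic_data as sd
from emtscape import (score_matrix, select_model, label_semantic,
                      assign_clusters, enumerate_min_paths, quadrant_census)

spec = sd.default_path_spec()                      # five-state EMT geometry
pts, truth = spec.sample_latent(1200, np.random.default_rng(0))
model, bic_table = select_model(pts, seed=0)
print(model.K, model.structure)                    # -> 5 EII
print(label_semantic(model))                       # component -> E/I0/I1/I2/M
print(enumerate_min_paths(model))
# -> [['E', 'I0', 'I2', 'M'], ['E', 'I1', 'I2', 'M']]
```

The two printed sequences are the *lower* path (through the characterless
low-E–low-M state I0) and the *upper* path (through the hybrid
high-E–high-M state I1); both route through the M-adjacent intermediate I2.
Fitting each path's deviation-vs-progression relationship with
`fit_emt_path` gives adjusted R² around 0.7 per path versus ≈0.14 for a
single model over all samples — splitting the cohort by path is what makes
the E–M relationship predictable.

Scoring an expression matrix end to end:

```python
matrix, truth = sd.generate_cohort(n_samples=400, seed=1)   # genes x samples
table = score_matrix(matrix, sd.signature_sets())           # E and M columns
print(quadrant_census(table).to_frame())
```

A command-line interface mirrors the library
(`emtscape score|cluster|paths|timecourse|subclusters|compare|simulate|run`);
`emtscape run --config cfg.yaml` executes the whole cohort pipeline and
writes a JSON run report with artifact checksums.

## Documentation

`docs/methods.md` describes the models, their assumptions, the synthetic
generators' scope, and the numerical choices (tolerances, tie-breaks,
initialisation) in detail.
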