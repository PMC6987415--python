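# Methods

This note documents the models implemented in `emtscape`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about behaviour on real cohorts.

## Single-sample enrichment scores

The E and M scores are the weighted Kolmogorov–Smirnov random-walk statistic
of gene set variation analysis, computed per sample against the rest of the
cohort:

1. Expression is log2(x+1)-transformed when flagged as linear-scale
   abundance (RSEM/FPKM); pre-transformed input passes `log_transform=False`.
2. For each gene a kernel cumulative density is estimated across samples
   with a Gaussian kernel of bandwidth `sd/4` (sample sd, ddof 1).  Genes
   with zero variance receive the constant statistic 0.5 and are logged;
   a rank-only mode (`kernel="none"`) substitutes the within-gene ECDF.
3. Within each sample genes are ranked by decreasing statistic — ties broken
   by input gene order so results are independent of storage order — and the
   rank r is folded to `|p/2 − r|`, then raised to τ (default 1).
4. The walk steps up by the normalised in-set weight and down by `1/(p−m)`;
   `es = max(0, max ν) + min(0, min ν)` (`max_diff` mode; `max_abs` is
   available).  The walk ends at 0 by construction and the score lies in
   [−1, 1].

Genes in a set but absent from the matrix are dropped with a logged count; a
set matching fewer than two genes is an error.  **Scores are
cohort-relative**: the kernel CDF uses all samples, so adding samples moves
every score.  Cohorts are therefore scored within the comparison of
interest (a time course on its own, a cancer cohort with or without its
outgroup, never pooled incidentally).

A consequence documented here because it shapes the tests: the score is, to
first order, a monotone function of each sample's *quantile* within the
cohort.  Crisp latent clusters are warped into heteroscedastic score-space
clusters (tight at the saturated poles, stretched mid-path), and a weak
transient in one program can be masked by rank competition from a strongly
moving opposite program.

## Mixture subpopulations

(E, M) pairs are clustered with diagonal Gaussian mixtures.  The six
covariance structures follow the volume/shape/orientation naming of
model-based clustering with orientation fixed to the axes: EII (one
spherical variance), VII (per-component spherical), EEI (shared diagonal),
VEI (shared shape, free volumes), EVI (shared volume, free shapes), VVI
(free diagonal).  M-step updates are the closed forms for each constraint
(VEI alternates its two closed-form updates to convergence).  Parameter
counts enter BIC = −2 log L + d log n; the minimum-BIC (K, structure) is
selected over K = 1..9.  The default selection set excludes the
unequal-volume shape models (VEI, VVI), which buy small BIC gains at the
cost of noticeably less certain assignments; all six remain available.

EM initialises from a Ward hierarchical partition cut at K (deterministic;
the tree is computed once per data set and shared across candidates), with
a seeded k-means fallback on degenerate restarts.  Convergence uses the
relative log-likelihood change (tolerance 1e-8) plus an Aitken-accelerated
stop: EM's gain sequence is asymptotically geometric, so iteration ends when
the projected remaining improvement falls below tolerance.  A component
variance below 1e-12 triggers one re-initialised restart, then the candidate
is recorded as missing (selection continues).  Our EII fits agree with R's
mclust to 1e-7 in log-likelihood on shared fixtures (mclust's BIC is ours
negated).

Semantic labels for K ∈ {4, 5}: E maximises μ_E − μ_M, M minimises it;
among the rest I0 has the lowest and I1 the highest μ_E + μ_M, and the
K = 5 leftover is the M-adjacent intermediate I2.

## Segmented regression and breakpoint inference

Broken-line models `y = β0 + β1 x + Σ δ_k (x−ψ_k)_+` are fitted by
iterative linearisation: gap regressors `−1(x>ψ_k)` measure the
discontinuity induced by the current guess and `ψ_k ← ψ_k + γ_k/δ_k`
drives it to zero.  The raw update can oscillate, so steps are halved until
the segmented RSS improves; convergence is declared when max|γ| <
1e-8·sd(y) or the breakpoints stop moving.  Breakpoints are clamped to the
2nd–98th data percentiles, coincident breakpoints are merged, and a
breakpoint whose slope change vanishes is dropped with a warning.  Adjusted
R² counts 2 + 2·(#breakpoints) parameters.  Model size (1–4 breakpoints,
quantile-spaced starts) is chosen by maximal adjusted R² with a parsimony
tie-break (fewest breakpoints within 1e-4).

Breakpoint existence tests treat ψ as a nuisance parameter absent under the
null, over k = 10 evenly spaced interior candidates:

* **Davies bound**: the slope-change t statistic is evaluated at each
  candidate; `p ≤ 2Φ(−M) + V·exp(−M²/2)/√(8π)` with M the maximal |t| and V
  the process's total variation.  Measured type-I error ≈ 0.05–0.07 at
  α = 0.05 on linear-null simulations.
* **Pseudo-score test**: the candidate hinges are averaged into fixed
  pseudo-covariates (one per hypothesised breakpoint) and tested with an
  exact F test — null p-values are exactly uniform.  Published variants of
  this statistic differ; equivalence with any specific one is not claimed.

Breakpoint confidence intervals invert a score-type statistic over a
100-point candidate grid: candidate ψ0 is retained when the gap
coefficient of the model pinned at ψ0 has |t| below the two-sided critical
value.  The interval is the connected acceptance run containing the
estimate (a hull over all accepted candidates over-covers via spurious
boundary pockets), with endpoints interpolated to the |t| = critical
crossings.  Empirical coverage on kink fixtures is ≈ 0.94 at the 0.95
level.

## EMT paths

Samples are rotated to u = (E−M)/√2 (progression, positive toward the E
pole) and v = (E+M)/√2 (deviation, positive toward the hybrid corner) — an
isometry.  The quadrant census uses a closed-left convention (a score of
exactly 0 is "low").

Cluster adjacency defaults to the **Gabriel graph** on component means: two
components are adjacent when no third mean lies inside the disc on their
connecting diameter.  This captures "neighbouring regions" without a tuning
constant and, on the five-state geometry, yields exactly the two expected
minimal paths (E–I0–I2–M and E–I1–I2–M).  A symmetrised k-NN graph is
available (`method="knn"`), but with k = 2 it adds a spurious M–I1 edge on
that geometry, shortcutting the hybrid path — the reason it is not the
default.  All shortest E→M paths are enumerated (no loops or backtracking
by construction); each path's members (mixture hard assignment) are fitted
with the segmented machinery and compared against the single all-sample
model.

## Time courses

E(t) and M(t) are fitted with two breakpoints initialised at 2.5 and
10 days; all replicate points enter individually.  One-breakpoint
comparison fits are recorded with adjusted R², and the "two breakpoints
supported" flag additionally requires the pseudo-score segmentation test at
p < 0.05 so that pure-noise scores are not flagged.  Bound models refit the
E curve with its first breakpoint pinned at each endpoint of the
score-inversion CI (endpoints clamped to the sampled range with a warning).
Trajectory state probabilities evaluate the fitted (Ê(t), M̂(t)) under a
cohort mixture model; extrapolation beyond the fitted range is refused by
default.

With the default sampling times (0–5 daily, then 8, 12, 16, 21 days) the
second breakpoint lies inside the 8–12 day gap, where the data constrain it
only weakly; recovery checks therefore use the median over five replicate
simulations.

## Gene subclusters

Perturbation-panel profiles are replicate-averaged per condition,
log2-transformed and z-scored per gene, then tiled onto a 10×10 batch SOM
(Gaussian neighbourhood, radius decaying linearly from half the grid width
to 0.5, 100 epochs, codebooks initialised from a seeded sample of genes;
deterministic under the seed).  Nodes are labelled E or M by majority of
their annotated member genes; annotation-free or tied nodes inherit the
majority of the nearest labelled nodes (1-NN in grid distance), with a
final tie going to the larger class.  Within each class, occupied-node
codebooks are Ward-clustered and k ≤ 8 is chosen by the elbow of the
occupancy-weighted within-cluster SSE measured on the log scale (relative
curvature) — the absolute second difference nearly always peaks at k = 2
because the first drop dominates the scree, merging true archetypes.
Subclusters are named E1../M1.. by earliest node index and scored over time
exactly like any gene set.

## Group statistics

Welch's t with Welch–Satterthwaite degrees of freedom, two-sided p, and a
95% CI for the mean difference; Benjamini–Hochberg adjustment is applied
across one analysis table at a time (the correction family is configurable,
since different analyses legitimately group different comparisons).
Subtype enrichment uses the chi-squared test against background frequencies
without continuity correction, flagging tables with any expected cell
below 5.  Expression values are compared as provided (normalised upstream).

## Synthetic data: what it emulates, and what it does not

The generators produce linear-scale matrices whose signature genes load
positively and linearly (log2 scale) on latent E/M activities, background
genes are latent-independent, and log-scale Gaussian noise (sd 0.3) is
added — the simplest model satisfying the scoring statistic's monotonicity
assumptions.  Defaults:

* **Cohorts**: five clusters at the E/I0/I1/I2/M geometry with spread 0.09
  (≈4σ separation at the closest pair) and weights 0.30/0.15/0.22/0.13/0.20;
  an outgroup generator places samples far below every cluster and shares
  gene parameters with the cohort under the same seed so the matrices pool.
* **Time courses**: triphasic trajectories with breakpoints at 2.5 and
  10 days, M slopes +0.10/+0.02/+0.05 per day, E slopes +0.02/−0.01/−0.08,
  latent noise sd 0.02, times 0–5 daily plus 8/12/16/21 days, 3 replicates.
* **Perturbation panels**: six subclusters wired as in the TGF-β/ZEB1
  logic-gate model — E1 (OR repression), E2 (incoherent feed-forward:
  TGF-β activates through a ZEB1-suppressible arm, ZEB1 represses), E3
  (AND repression, opposite-signed response to TGF-β alone), M1 (AND
  activation, reduced response to TGF-β alone), M2 (OR activation), M3
  (ZEB1 only).  A gate-driven time course ramps TGF-β by day 2.5 and ZEB1
  between days 5 and 12, producing the E2 pulse.

Because enrichment scores are cohort-relative quantile-like statistics, the
latent geometry does **not** survive the score transform undistorted:
score-space clusters are heteroscedastic, BIC on fully round-tripped
matrices overselects K, and weak latent transients can be masked by rank
competition.  Mixture/path recovery is therefore validated on samples drawn
in score space (where the mixture assumptions hold by construction), while
matrix round-trips are validated on what genuinely survives scoring: rank
preservation of latent activities (Spearman > 0.9), quadrant occupancy,
sign contrasts between clusters, outgroup positioning, phase patterns over
time, and subcluster recovery.  Passing these tests shows the machinery is
correct under its assumptions — not that real cohorts satisfy those
assumptions; real data bring library-size effects, count noise and
correlated gene modules that the generators deliberately omit.

## Problem sizes

The default validation sizes — 1200 score pairs for mixture selection, 100
replicates of n = 500 for the single-Gaussian control, 500 replicates for
test calibration, 200 for CI coverage, five replicate time courses, one
240-gene panel — run in a few minutes on one CPU and give binomial
uncertainties comfortably inside the asserted bands.
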