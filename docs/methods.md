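# Methods

This note documents the models and procedures implemented in `hubdyn`, the
parameters that matter, the numerical policies, and what the synthetic
cohorts do and do not establish about real data.

## Graph construction

Per subject, the Pearson correlation between every pair of parcel time
series is Fisher z-transformed (`z = atanh(r)`), z-matrices are averaged
elementwise over subjects, and the top fraction of upper-triangle values
becomes the weighted group graph.

Numerical policies:

- `|r|` is clamped at `1 − 1e−7` before `atanh`, so perfectly collinear
  parcels produce a large finite z (≈ 8.7) instead of infinity; downstream
  averages stay finite. Clamping events inside windows are logged.
- A constant parcel raises an explicit error naming the parcel; correlation
  with a zero-variance signal has no defined value worth silently imputing
  at the full-scan level. *Within a window*, a constant parcel yields r = 0
  with a logged warning — a window-level degeneracy should not abort a
  whole-cohort run.
- The retained edge count is `k = round(sparsity · P(P−1)/2)`. Both a
  sparsity fraction and an absolute edge count are exposed, because the two
  conventions genuinely differ (at P = 200 and 10%, `round` gives 1990
  while the commonly quoted figure is 2000); pipelines should state which
  they used.
- Ties at the threshold boundary are broken by lexicographic `(i, j)`
  order, making the edge set platform-independent.

## Link communities

Connections are clustered, not regions, so one region can sit in several
networks. Similarity is defined only for edge pairs sharing exactly one
(keystone) vertex:

- Jaccard: `S = |n(i) ∩ n(j)| / |n(i) ∪ n(j)|` over the **exclusive**
  first-order neighborhoods of the non-shared endpoints (a vertex is not
  its own neighbor). Exclusive neighborhoods are the reading under which
  the standard worked examples (S = 1/3 for a single shared keystone,
  S = 1 for identical neighborhoods) hold; note this differs from the
  inclusive-neighborhood variant of the original link-community
  formulation.
- Tanimoto: the weighted analog over weight vectors indexed by
  `n(i) ∪ n(j)`, zero where no connection exists and no self-weight
  diagonal term by default. The original formulation's self-weight term
  (a vertex's mean edge weight on its own coordinate) is available behind
  `self_weight=True`. On unit weights Tanimoto reduces exactly to Jaccard.

Clustering is agglomerative McQuitty/WPGMA linkage on `d = 1 − S`
(scipy's `weighted` method); non-adjacent edge pairs get the maximal
distance 1, the similarity being undefined for them. The dendrogram is cut
at the flat partition maximizing the global partition density `D`,
evaluated at the all-singleton level and after every distinct merge
height; ties go to the lower cut (more clusters), preserving resolution
deterministically. Single-edge clusters (`n_c = 2`) contribute `D_c = 0`,
resolving the 0/0 tree-equals-clique case by convention.

Vertex eligibility for the dynamics analysis requires at least two
networks at the vertex and at least `min_second = 2` connections in the
second-largest one, so per-network mean strengths are not single-edge
noise.

## Windowed dynamics and VNP

Windows are consecutive, non-overlapping blocks of `w` volumes (default
77; at TR = 0.645 s that is 49.7 s, matching a 0.01–0.1 Hz band-pass
regime); the trailing `T mod w` samples are discarded, and an 896-volume
scan yields exactly 11 windows. Window indexing is zero-based
(`[t·w, (t+1)·w − 1]`); a one-based upper index would overrun the scan.
Per-edge windowed z values are expressed as change scores relative to the
subject's full-scan z, removing between-subject baseline differences.

Within- vs between-network coherence of change is tested per region by a
one-sided paired Wilcoxon signed-rank over (subject, window) observations
of within-cluster vs pooled variance. Timepoints are not averaged over
subjects — subjects occupy different connectivity states. The signed-rank
null of the variance differences is only asymptotically symmetric; with
very small clusters (≲ 6 connections) p-values are approximate.

A hub's VNP for a pair of its networks is the MSE between the per-window
mean change of its connections in each network; with more than two
networks, the unweighted mean over all pairs (edge-count weighting is a
defensible alternative; unweighted keeps small networks visible). The
permutation null redraws two (or more) *disjoint* random connection sets
of the observed sizes from the hub, ignoring network labels — disjoint
because the real cluster assignments are disjoint — and the p-value uses
the add-one convention `(1 + #{null ≥ obs}) / (n_perm + 1)`, a valid
finite-sample p never exactly zero. Default `n_perm = 10000`; tests and
the synthetic examples use 500–1000, which resolves p = 0.05 comfortably.

This statistic responds to any departure from co-fluctuation of the two
networks' strengths — planted anti-phase switching, but also independent
per-network fluctuations. Significance against the random-cluster null
therefore means "these two connection sets vary more differentially than
random sets from the same hub", not specifically "states alternate".

## Reliability and associations

Split-half reliability fixes the connection set from the full group, then
recomputes edge weights and dendrograms on odd- and even-indexed subject
halves separately. Agreement is the Pearson correlation between the two
cophenetic-distance vectors; the Mantel null permutes the leaf labels of
one dendrogram's cophenetic matrix (rows and columns jointly, 999
permutations, one-sided for large observed correlation). Which matrix is
permuted is immaterial in distribution.

Partial Spearman correlation is computed as the Pearson correlation of
rank residuals: ranks of x and y regressed on covariate ranks (with
intercept) by least squares, with a t-distribution p-value at
`df = n − 2 − k`. With no covariates this is exactly Spearman's rho. The
default association battery mirrors a whole-brain analysis: whole-brain
VNP against each content/form factor (covariates: micro-movement, age,
gender, and the other factors of the same section; Bonferroni m = 8),
whole-brain VNP against age (covariate: micro-movement), and optionally
per-region VNP against all factors (m = 8 × regions). Gender enters as a
binary covariate column.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, with
independent standard-Gaussian latent series per community:

- non-hub parcel: `c_p · b · Σ_{communities of p} g_c(t) + ε`, with
  `b = base_coupling = 0.8`, `ε ~ N(0, noise_sd²)`, `noise_sd = 0.8`
  (within-community pairwise r ≈ 0.5, a realistic resting-state value);
- hub parcel: mixes its two communities' latents with state-dependent
  weights `(1 − a, a)` / `(a, 1 − a)`, `a = ½(1 − amplitude)`, rescaled so
  hub variance equals that of a static member of both communities at every
  amplitude (a fully switching hub still halves its time-averaged
  covariance with either community — an inherent signature, not a
  normalization artifact);
- states alternate in blocks of `state_block_length = 77` timepoints,
  aligned with the analysis windows so each window sees a pure state; 847
  timepoints give 11 windows;
- per-parcel coupling constants spread deterministically over
  `1 ± 0.25` (hubs maximal), emulating degree heterogeneity so that
  top-fraction thresholding keeps a stable, hub-containing edge set;
- behavioral scores: `positive = −amplitude + noise`,
  `past = +amplitude + noise` (slope `trait_coupling = 1`, noise SD 0.5),
  age negatively coupled to amplitude, all other factors, gender and
  micro-movement independent noise — so covariate adjustment can be
  validated against planted nulls.

The default cohort (50 subjects, 60 parcels, two communities sharing only
the hub parcel) is analyzed at sparsity 0.51 rather than the 10% typical
for a 200-parcel cortex-wide graph: with two communities covering 60
parcels, ~51% of all pairs are genuinely coupled, and the threshold should
sit at the boundary between structure and noise just as 10% does when
~10 networks tile 200 parcels. Retaining substantially more pairs than
genuinely coupled ones admits noise edges between the communities, which
are spuriously similar to the hub's connections (the hub's neighborhood is
the union of both communities) and can bridge its two connection sets into
one cluster.

What the generator does **not** emulate: hemodynamics and autocorrelated
BOLD noise, head motion and physiological artifacts, spatially varying
parcel sizes, more than a handful of networks, or graded/continuous state
changes. Passing tests therefore establish the pipeline's correctness and
power under its own model assumptions, not performance on real scans.

## Problem sizes in the test suite

Unit tests use toy graphs (≤ 14 edges) with exhaustive/brute-force
oracles. Cohort-level checks use 30-parcel cohorts (11 windows of 30
volumes) for speed, and the parameter-recovery checks use the full default
60-parcel, 50-subject cohort across 100 seeds with 1000 permutations per
test — enough to resolve the targeted error rates while keeping the whole
suite within a few minutes on one core.

## Known limitations

- WPGMA averages distances over *all* cross-pairs, including non-adjacent
  pairs at distance 1, so very large link clusters repel each other; with
  strongly homogeneous communities a high-degree hub's connections can
  form their own cluster rather than joining their networks' clusters.
  The analysis treats a hub's connection sets as "its networks" either
  way, but interpretation differs.
- The max-density cut is evaluated on merge heights only; a single global
  cut cannot represent nested resolution levels.
- The permutation null conditions on the observed cluster sizes; regions
  with nearly all connections in one network have low power by design
  (hence the eligibility rule).
- Partial Spearman p-values use the t approximation on rank residuals,
  standard but approximate in small samples with many covariates.
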