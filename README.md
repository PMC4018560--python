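# hubdyn

Dynamic network participation of functional connectivity hubs.

Resting-state fMRI networks overlap: many brain regions ("hubs") are
connected into several networks at once, and their degree of membership in
each network is not constant over a scan. `hubdyn` implements an analysis
pipeline that

1. builds a group connectivity graph from parcel time series
   (Pearson correlation → Fisher z → group mean → top-fraction threshold),
2. clusters the *connections* of that graph into overlapping networks
   (link communities), so a region can belong to several networks,
3. tracks each multi-network hub's per-network mean connection strength
   over non-overlapping sliding windows and scores its **variation of
   network participation (VNP)** — the mean squared error between the two
   networks' baseline-normalized strength timecourses — against a
   permutation null that redraws same-sized connection sets from the hub,
4. relates per-subject whole-brain VNP to behavioral reports
   (partial Spearman correlations with covariates, Bonferroni corrected),
   and checks clustering reliability by an odd/even split-half design
   (cophenetic correlation with a Mantel permutation test).

It is aimed at researchers analyzing parcellated resting-state time series
who want overlapping (edge-clustered) networks and per-region dynamics,
and it ships a synthetic-cohort generator with planted ground truth so the
whole pipeline is testable without any imaging data.

## The statistics at the core

**Connection similarity.** Two connections `e_ik`, `e_jk` sharing a
keystone vertex `k` are compared through the neighborhoods of their
non-shared endpoints: the Jaccard coefficient
`S = |n(i) ∩ n(j)| / |n(i) ∪ n(j)|` (with `n(·)` the exclusive first-order
neighborhood), or its weighted Tanimoto form
`S = w_i·w_j / (|w_i|² + |w_j|² − w_i·w_j)`.

**Partition density.** Agglomerative McQuitty (WPGMA) clustering on
`d = 1 − S` builds a dendrogram over the edges; the flat cut maximizes

```
D_c = (m_c − (n_c − 1)) / (n_c(n_c − 1)/2 − (n_c − 1)),   D = (1/M) Σ_c m_c D_c
```

— the number of connections of cluster `c` beyond a spanning tree,
normalized between tree (0) and clique (1), averaged with edge weights.

**VNP.** For a hub in networks A and B, with per-window, baseline-normalized
Fisher-z change scores averaged over the hub's connections in each network,
`VNP = (1/W) Σ_t (Ā_t − B̄_t)²`. Significance comes from random
re-partitions of the hub's own connections; a subject's whole-brain VNP is
the mean over all eligible regions (≥ 2 networks, second-largest with ≥ 2
connections).

## Worked example

```python
import hubdyn as hd
from scipy.stats import spearmanr

cfg = hd.SimulationConfig(seed=7)             # 50 subjects, 60 parcels,
subjects, truth, behavior = hd.simulate_cohort(cfg)  # 1 switching hub
res = hd.analyze_cohort(subjects, sparsity=0.51, n_perm=999, seed=7)

print(res.graph.n_edges, res.clustering.n_clusters_)
print(res.region_table)
rho, p = spearmanr(truth.switching_amplitude,
                   res.subject_table["whole_brain_vnp"])
print(f"amplitude recovery: Spearman r = {rho:.2f}, p = {p:.2e}")
```

prints

```
903 3
 region  degree  n_networks      vnp  p_perm
     28      59           2 0.239275   0.001
amplitude recovery: Spearman r = 0.97, p = 9.26e-32
```

The graph keeps 903 connections; link clustering finds the two planted
communities plus the hub's bridging connections as 3 networks. Parcel 28
(the planted switching hub) participates in two networks with 59
connections; its VNP of 0.24 is larger than every draw of the 999-draw
permutation null (p = 0.001), and per-subject whole-brain VNP recovers the
planted switching amplitudes almost perfectly (Spearman r = 0.97). Running
the association suite on the same cohort recovers the planted negative
coupling between VNP and positive thought reports
(partial Spearman r = −0.54, Bonferroni-corrected p = 0.0015) while the
uncoupled factors stay non-significant.

The same stages are available from the shell:

```bash
hubdyn simulate --out cohort/
hubdyn graph --manifest cohort/manifest.csv --sparsity 0.51 --out edges.tsv
hubdyn cluster --edges edges.tsv --out clust/
hubdyn vnp --manifest cohort/manifest.csv --edges edges.tsv \
    --partition clust/partition.tsv --out vnp/
hubdyn associate --vnp-table vnp/vnp_subjects.csv \
    --behavior cohort/behavior.csv --out associations.csv
hubdyn reliability --manifest cohort/manifest.csv --sparsity 0.51
```

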