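# Methods

`mstnetclass` classifies subjects by the topology of their functional
brain networks. The pipeline is: per-subject Pearson correlation network →
maximum-weight spanning tree (MST) → frequent connected-subnetwork mining →
discriminative selection by between-class frequency difference → network
rebuild → Weisfeiler–Lehman (WL) subtree kernel → kernel PCA → linear SVM
with repeated stratified 10-fold cross-validation. This note records the
model, the parameters that matter, and the design choices made where the
design was genuinely open.

## Network construction

The full network of a subject is the ROI×ROI matrix of Pearson correlations
between regional time courses. The MST backbone is extracted with Kruskal's
algorithm run on *descending* weights: links are taken strongest-first and a
link closing a cycle is skipped, yielding the spanning tree of maximal total
weight. The MST needs no threshold, keeps every region connected, and — a
useful robustness property — depends only on the rank order of the weights,
so any strictly increasing transform of the correlations leaves it
unchanged (tested).

*Negative correlations.* The default ranking is on signed correlations (the
strongest positive couplings win); an `absolute` mode ranks |r| instead, for
users who regard strong anticorrelations as strong connections. The choice
is exposed because resting-state literature is genuinely split here.

*Ties.* Equal weights are broken deterministically by (min node id, max
node id) ascending, in both Kruskal and the thresholding baseline. With
continuous correlations ties have measure zero; the rule only guarantees
reproducibility.

*Threshold baseline.* `threshold_network` keeps the `round(s·n(n−1)/2)`
strongest links as a binary graph (round-half-to-even), the conventional
fixed-sparsity construction the MST is meant to replace. It exists so the
two constructions can be compared under one evaluation harness.

## Frequent-subnetwork mining (gSpan)

Nodes carry labels (in this application, their own ROI index), so a
subnetwork is a connected node-labeled graph with at least one edge; a
single-node "pattern" carries no connectivity information and is excluded.
The frequency of a pattern in a graph set is the fraction of graphs that
contain it (transaction counting: one graph counts once however many
embeddings it has), and a pattern is frequent when that fraction is ≥ the
support threshold `s` (default 0.7).

Mining uses canonical minimum DFS codes with rightmost extension. A DFS
code is a sequence of tuples `(i, j, l_i, l_e, l_j)`; the lexicographic
minimum over all traversals is identical for isomorphic graphs and is
computed greedily by tracking every embedding that realizes the minimal
prefix. Candidate growth prunes any code that is not minimal (each
isomorphism class is expanded once) and any extension whose support falls
below threshold (anti-monotonicity). MST edges are unlabeled; a single
dummy edge label fills the code slot so the machinery generalizes.

Because MST node labels are unique within a graph, pattern containment
reduces to edge-set containment by label pairs, embeddings are unique, and
mining 90-node trees is cheap. The generic backtracking monomorphism search
handles duplicate labels and is cross-checked against exhaustive
enumeration in the tests.

*Per-class mining.* Patterns are mined separately within each class and the
candidate pool is the union (deduplicated by canonical code); a pattern
over-represented in either group is thereby a candidate even if its pooled
frequency is below `s`. Pooled mining is available as a flag.

## Discriminative selection and rebuild

A pattern's discriminability score is the absolute difference of its
occurrence frequencies in the two classes, |f_A − f_B| ∈ [0, 1]. The
absolute value keeps patterns enriched in *either* group. Selection keeps
the top-k scorers (default k = 50; ties prefer fewer edges, then canonical
code order) or, alternatively, all patterns above a score floor.

Each subject's network is then rebuilt by deleting every edge that appears
in no selected subnetwork. The default `embedded` rule keeps an edge only
when a selected pattern actually occurs in that subject's network and the
edge lies in the occurrence's image; the cheaper `union` rule keeps any
edge whose label pair appears in any selected pattern, whether or not the
pattern occurs. Rebuilding is idempotent and only removes edges (tested).
When no pattern reaches the support threshold the rebuilt networks are
edgeless and classification degrades to chance rather than failing — the
correct behavior under a true null.

The binary indicator features f_ij (1 iff pattern j occurs in subject i)
are provided as the baseline feature set that discards surrounding
topology; comparing them with the kernel features quantifies what the
kernel adds.

## WL subtree kernel

Round 0 counts original node labels. Each later round relabels every node
with a compression of (its current label, the sorted multiset of its
neighbors' labels); h rounds (default h = 5) produce a feature map of token
counts over all rounds, and the kernel is the plain inner product of two
maps. Compressed tokens come from one injective dictionary shared across
the dataset, filled in first-seen order, so identical signatures always
collide. For held-out graphs the training dictionary is reused; genuinely
novel signatures get fresh tokens and contribute nothing to cross products
— exactly the right behavior for out-of-sample projection. An optional
normalized variant k/√(k_GG·k_HH) is off by default. Symmetry, positive
semidefiniteness, isomorphism invariance and agreement with a naive
string-relabeling implementation are all tested.

## Kernel PCA

The eigenproblem is λα = Kα on the kernel matrix. Eigenpairs are sorted by
|λ| descending, eigenvectors kept at unit Euclidean norm, and a graph's
feature vector is its kernel row against the training graphs projected on
the top-m eigenvectors. The retained dimension m is the smallest count
whose cumulative |λ| mass *strictly* exceeds 0.9 of the total; a fixed m
can be forced.

*Centering.* By default K enters the eigenproblem as-is, matching the
plain eigenproblem formulation; conventional double-centering (removing the
feature-space mean, with the matching out-of-sample correction) is
available by flag. The distinction matters in practice: with uncentered
kernels over graphs that share a large constant component — e.g. 90
identically-labeled nodes — the leading eigenvector is nearly constant and
the 0.9-mass rule can retain only it. Inside the cross-validated pipeline
this is largely neutralized by per-fold feature standardization, and the
planted-effect benchmark reaches its accuracy ceiling under either setting.
The conventional 1/√λ eigenvector scaling is likewise a flag (off by
default; it rescales coordinates and is irrelevant to a subsequent
standardized SVM).

## Classification and evaluation

A linear SVM (C = 1, no class weighting) is trained on the kernel-PCA
features, standardized within training folds. Evaluation is stratified
10-fold cross-validation repeated (default 100 repetitions; tests and the
synthetic benchmark use 10 for runtime), reporting the arithmetic mean over
repetitions of ACC, SEN, SPE and rank-based AUC (ties count ½), plus a
pooled ROC sweep. The positive class is by convention the more-impaired
group, and the report records the convention.

Two leakage regimes are implemented. `fold_internal` (default) refits
mining, selection, the WL dictionary, KPCA and the scaler on the training
folds only — the methodologically sound generalization estimate.
`global_fit` fits all feature stages once on the full sample and
cross-validates only the SVM, mirroring pipelines that select features
globally; its estimates are optimistic, and the report labels which regime
produced it. Identical seed and configuration give byte-identical reports.

## Synthetic data: what it emulates and what it does not

`generate_tree_population` draws, per subject, a uniform random spanning
tree on the ROI set (random Prüfer sequence, so every labeled tree is
equally likely — a neutral null in which any specific edge occurs with
probability 2/n). Planted connected patterns are spliced in with per-class
inclusion probabilities; each spliced edge's cycle is repaired by removing
a deterministic, seeded choice among the non-pattern cycle edges, so every
subject remains a valid spanning tree. Defaults for the benchmark design:
20 ROIs, 30 subjects per class, one 3-edge planted path at inclusion
probabilities 0.9 (patients) / 0.1 (controls), matching a strong but not
deterministic group effect.

Under this design the best achievable accuracy is bounded by the
realization: patients who did not receive the pattern and controls who did
are information-theoretically indistinguishable, so the Bayes accuracy is
1 − (misses + contaminations)/N, with expectation 0.90 at the default
probabilities. The benchmark verifies the pipeline reaches that ceiling;
run-to-run variation in the reported accuracy reflects the binomial
variation of the realized inclusion counts, not classifier noise.

`generate_block_timeseries` emulates the upstream correlation stage:
ROIs within a block mix a shared latent signal so within-block correlation
≈ `within_r` and cross-block ≈ 0, and the MST preferentially keeps
within-block edges.

What the generator does not emulate: spatial autocorrelation and
distance-dependent connectivity, hemodynamics, scanner noise, site effects,
subject-level global signal differences, or realistic modular brain
topology. Passing the planted-recovery benchmark therefore shows the
pipeline recovers frequency-differentiated subnetwork structure from
tree-structured networks — not that any particular clinical accuracy will
be attained on real cohorts.

## Numerical choices and degenerate inputs

- Symmetry tolerance for input matrices and kernel matrices: 1e-8 (max
  absolute deviation); PSD tolerance: min eigenvalue ≥ −1e-8 × max.
- Eigen-sort ties break on original index; selection ties on (score, edge
  count, canonical code); Kruskal/threshold ties on node-id pairs.
- All randomness flows through `numpy.random.default_rng(seed)`; reports
  and artifacts are byte-stable given seed and config.
- Degenerate cases handled explicitly: zero-variance time series (error
  naming the ROI), single-class training folds (error), empty frequent
  pattern pools (warning + edgeless rebuild + chance-level output),
  all-zero spectra in `choose_m` (error).

## Problem sizes in tests

Unit and acceptance tests run the scales at which exhaustive oracles are
exact and fast: complete graphs with 4–7 nodes against full spanning-tree
enumeration, 5-graph datasets with ≤ 6 nodes against full connected-subset
enumeration, WL pairs with ≤ 12 nodes against the naive kernel, and the
20-ROI / 60-subject planted design with 10×10-fold CV for the end-to-end
benchmarks. The 90-ROI configuration is exercised for construction and
I/O; full-scale mining on 90-node trees is tractable (unique labels) but
not part of the default suite.

## Known limitations

- Mining with heavily duplicated labels can be exponential in pattern size;
  the `max_edges` cap is the safety valve. The brain-network case (unique
  labels) does not hit this.
- `global_fit` mode deliberately reproduces a leaky protocol; its numbers
  should never be reported as generalization estimates.
- The WL kernel ignores edge weights after network construction; the MST's
  correlation values influence which edges exist, not the kernel value.
- Multi-class classification is provided only as independent binary tasks.
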