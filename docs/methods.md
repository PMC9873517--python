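# Methods

## Model and procedure

The package analyzes two-group cohorts of ROI-level resting-state signals.
Each subject is a T × N matrix (time points × regions). The analysis chain
is:

1. **Low-order FC (LOFC).** Edge (i, j) is the Pearson correlation of the
   two regions' time series. The diagonal is fixed at 0 by convention.
2. **High-order FC (HOFC).** Edge (i, j) is the Pearson correlation of the
   two regions' LOFC profiles. Each profile is the region's row of the
   LOFC matrix restricted to the N − 2 columns that exclude both i and j:
   the self-entries and the mutual entry LOFC(i, j) would otherwise feed
   the quantity being measured into its own predictor and inflate the
   correlation. A switch for including the mutual entry is deliberately
   not provided; excluding it is the only construction we consider sound.
   A constant profile (degenerate input) yields 0 with a warning.
3. **Binarization.** Negative and zero weights are discarded; the
   strongest positive edges are kept down to a target sparsity s, with
   K = round(s·N(N−1)/2) edges (half-up rounding; ties at the cut broken
   by lexicographic (i, j) order so degenerate inputs remain
   deterministic). If fewer than K positive edges exist — common for HOFC
   at high sparsity, since HOFC matrices are roughly half negative — all
   positive edges are kept and the achieved sparsity is warned about.
   The default grid is 0.10–0.50 in steps of 0.01 (41 levels).
4. **Topology.** Per binary graph: clustering coefficient Cp (nodes of
   degree < 2 contribute 0 and stay in the mean), characteristic path
   length Lp (averaged over *connected* ordered pairs only, keeping Lp
   finite on disconnected low-sparsity graphs), global efficiency Eglob
   (mean 1/d with 1/∞ = 0), local efficiency Eloc (mean Eglob of each
   node's neighbor-induced subgraph), nodal degree/efficiency/betweenness
   (betweenness unnormalized, Brandes algorithm via networkx). γ and λ
   divide Cp and Lp by their means over degree-preserving double-edge-swap
   null graphs; σ = γ/λ. Defaults: 100 nulls, 10 × edge-count swap
   attempts per null. Metric-versus-sparsity curves are reduced to their
   trapezoidal AUC, the per-subject scalar entering group tests.
5. **Modular FC.** Mean *weighted* connectivity within each module and
   between each module pair of an a-priori five-module partition
   (SMN/DMN/FPN/VN/SN). Negative weights are retained here — the
   negative-weight removal belongs to binarization, and modular FC is a
   statement about the weighted matrix. A binarized-and-grid-averaged
   variant exists behind a flag for sensitivity analysis. The packaged
   AAL-90 partition is a constructed anatomical assignment (labelled
   synthetic); any two-column region→module file can replace it.
6. **Group inference.** Per-subject scalars are compared with an OLS
   model value ~ group + covariates (group coded 0/1, sex as a binary
   indicator); with no covariates this is exactly the pooled two-sample
   t test. Nodal-metric p-values get Benjamini–Hochberg FDR. NBS tests
   every edge with the same adjusted model, keeps edges with p below a
   primary alpha, forms connected components, and refers each component's
   extent (edge count; intensity optional) to the null distribution of
   the maximum component over group-label permutations, with the +1
   correction p = (1 + #{null ≥ obs}) / (n_perm + 1). Covariates are
   held fixed under permutation (label permutation only; Freedman–Lane
   residual schemes are out of scope). Brain–behavior associations use
   partial Spearman correlation: all variables rank-transformed,
   covariate ranks regressed out, residuals Pearson-correlated, p from
   the t approximation with df = n − 2 − #covariates.
7. **Classification.** Features are the N(N−1)/2 pairwise connection
   coefficients (the per-node-row aggregate reading is available as
   `vector_to_matrix` + row means, but the pairwise reading is the
   default). Inside each leave-one-out fold: standardize on the training
   subjects, screen with LASSO (linear model of the 0/1 label,
   penalty λ = 0.05), train a linear SVM (C = 1) on the selected
   features, score the held-out subject. Selection and scaling live
   inside the fold; a variant that selects once on all subjects is
   deliberately not offered because it leaks the held-out label.
   Accuracy/sensitivity/specificity come from held-out predictions
   (patient group positive); the ROC and AUC from the pooled held-out
   decision scores. A fold with an empty selection predicts the training
   majority class.

## Synthetic cohorts

`CohortDesign` draws each subject independently from a zero-mean
multivariate normal whose correlation matrix is block-structured: 1 on the
diagonal, `base_within_cov` (default 0.35) inside a module,
`base_between_cov` (default 0.10) between modules. Effects add a signed
delta to one block's correlations in group B only; the implied matrix is
eigen-checked and a non-positive-definite design fails loudly, naming the
offending block, rather than being projected to the nearest PD matrix.
Observation noise (sd 0.5) is added per sample; an optional AR(1)
coefficient (default 0) induces temporal autocorrelation while preserving
the stationary spatial covariance. The default design mirrors the
reference study's geometry: 60 + 51 subjects, 90 regions, 230 time
points.

What the generator emulates: two groups, modular covariance, group
differences confined to known blocks, subject-level sampling noise.
What it does not: hemodynamic convolution, scanner drift and motion
artifacts, spatially heterogeneous noise, non-Gaussian marginals, and
negative-correlation structure. Passing tests therefore demonstrate that
the *procedures* are correct and calibrated on data with known truth —
not that any particular clinical effect exists in real cohorts.
Note that with observation noise the sample correlation converges to an
attenuated version of the block correlation (factor 1/(1 + noise_sd²)),
uniformly across blocks; group contrasts keep their sign and approximate
magnitude ordering.

## Validation studies and problem sizes

`hofcnet.validation` fixes the package's standard verification
conditions, chosen so the full battery runs in minutes on one CPU while
leaving the statistical properties intact:

* **Calibration** (zero-effect designs, identical populations): NBS
  family-wise error over 200 cohorts of 30 + 30 subjects, 20 regions,
  T = 100, at n_perm = 500; and the rejection rate of the 7 global-AUC
  group tests over 100 cohorts of 30 regions on a thinned grid
  (0.10–0.50 step 0.05) with 3 rewired nulls per graph. Type-I error is
  insensitive to the null-ensemble depth and grid density, which only
  shift the metric values, not their exchangeability between groups. The
  30-region networks keep the lowest grid level dense enough that
  rewired nulls retain triangles (a 20-node graph at 10% sparsity often
  has none, making γ undefined).
* **Recovery**: 50 cohorts of 30 + 30 subjects, 20 regions, T = 200,
  with −0.25 added to the within-SMN correlations of group B — a 6-edge
  planted component. NBS runs at primary alpha 0.01: with block-
  structured data, edge statistics within a module co-vary, so a liberal
  primary threshold produces diffuse null components and a stricter one
  is the appropriate regime for a focal, strong effect (the classic
  extent/intensity trade-off of cluster-forming thresholds).
* **Small-world regime**: dense Erdős–Rényi graphs (30 nodes, p = 0.5)
  should give γ ≈ 1 and λ ≈ 1 — they are their own null model — and
  Watts–Strogatz ring lattices (30 nodes, k = 4, 5% shortcuts) should
  give σ > 1.
* **Classification sanity**: a +0.40 within-module effect at T = 200
  separates the groups by several subject-level standard errors on each
  of 6 edges, so LOOCV AUC must be 1.0; label-shuffled null cohorts must
  average AUC ≈ 0.5.

`scripts/acceptance.py` re-runs exactly these studies from a single seed.

## Numerical choices

* Correlations are used raw (no Fisher z) for matrix construction; the
  classification features may be z-transformed via a flag.
* Shortest paths on graphs of ≤ 256 nodes use a dense boolean-matmul BFS
  (one matrix product per distance level), which is much faster than
  sparse-graph machinery at connectome sizes; larger graphs fall back to
  scipy's BFS. Efficiency and path-length sums are accumulated level by
  level, so no distance matrix is materialized in the local-efficiency
  inner loop.
* Double-edge-swap rewiring draws its random numbers in batches; swap
  attempts are capped at 20 × the requested swap count. Graphs admitting
  no swap are returned unchanged with a warning.
* Mann–Whitney U uses full enumeration of group assignments (valid under
  ties) when n ≤ 20 and the tie-corrected normal approximation above.
* The pipeline derives per-stage seeds by SHA-256 hashing of
  (global seed, stage, key), so any stage can be reproduced in isolation
  and a rerun is byte-identical; every output table carries the resolved
  config hash.
* The NBS edge-wise tests are computed by Frisch–Waugh residualization
  (identical to the per-edge OLS group t, asserted in tests), making the
  permutation loop a handful of matrix products per permutation.

## Known limitations

* Static (whole-series) HOFC only; sliding-window dynamic variants are
  out of scope.
* Binary-graph metrics only; no weighted or directed variants.
* NBS permutes group labels only; exchangeability is assumed after
  covariate adjustment.
* The default AAL-90 five-module partition is a nominal anatomical
  assignment, not a published community structure; analyses that hinge on
  the partition should supply their own file.
* The generator's Gaussian, temporally-white default understates the
  autocorrelation of filtered BOLD; the AR(1) option narrows but does not
  close that gap (effective sample size per subject is smaller in real
  data, so real-data power will be lower at equal T).
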