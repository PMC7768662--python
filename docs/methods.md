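# Methods

## Model

The observed data are an `n × p` table of non-negative abundances `W`
(counts or proportions; only ratios are used).  Each row is mapped to a
composition `x = w / Σw`, an incidence vector `v = 1{x ≠ 0}`, and a
zero-preserving centred log-ratio vector `y`: for the `q` taxa present
in the sample, `y_j = ln x_j − (1/q) Σ_{present k} ln x_k`; absent taxa
stay exactly zero.  No pseudo-count is added at any point; an input zero
is treated as exact absence.  A sample with a single present taxon maps
to an all-zero `y` row with its information carried entirely by `v`.

The pair `(y, v)` is modelled with the multivariate Gaussian Hurdle
density, an exponential family on the support
`{(y, v) : y_j ≠ 0 ⇔ v_j = 1}` with unnormalised log-density

    v′ G v + v′ H y − ½ y′ K y

where `G` (symmetric) couples presences, `K` (symmetric, positive
diagonal; positive definite for simulation) couples abundances, and `H`
(general) couples the presence of one taxon with the abundance of
another.  The conditional-independence graph has an edge `(i, j)` iff
any of `g_ij, h_ij, h_ji, k_ij` is nonzero.

Collecting the `(v_i, y_i)` terms gives the exact univariate conditional
of node `i` given the rest: a hurdle law proportional to
`exp{v_i a + y_i b − (κ/2) y_i²}` with

    a = g_ii + 2 Σ_{j≠i} g_ij v_j + Σ_{j≠i} h_ij y_j
    b = h_ii + Σ_{j≠i} h_ji v_j − Σ_{j≠i} k_ij y_j
    κ = k_ii.

Its normaliser is available in closed form: the presence odds are
`m = exp(a + b²/2κ) √(2π/κ)`, presence probability `m/(1+m)`, and the
value given presence is Normal(`b/κ`, `1/κ`).  All such quantities are
evaluated in log space (`log1p`/`logaddexp`); κ is floored at 1e−8.
These conditionals power both the fitter and the Gibbs simulator, and
are verified in the tests against brute-force oracles (enumeration of
the binary configurations plus adaptive quadrature over the continuous
coordinate) at p ≤ 3.

## Estimation

Each node is fit by maximising its summed conditional log-likelihood
penalised by the group lasso `λ Σ_{j≠i} ‖θ_ij‖₂`,
`θ_ij = (g_ij, h_ij, h_ji, k_ij)`, so that whole groups are zeroed
exactly.  Implementation choices that matter:

* **Parameterisation.** Intercepts are `(α, β, log κ)`; the log
  reparameterisation keeps the precision positive (|log κ| capped at
  18).  The objective is concave in the natural parameters; the log-κ
  map makes it mildly non-convex in that one coordinate.
* **Standardisation.** Predictor columns are scaled to unit standard
  deviation inside each node regression (clr columns have spread ~2,
  incidence columns ~0.3–0.5; without scaling the group penalty's entry
  order is dominated by column scale and the binary/cross couplings are
  never ranked).  Fitted coefficients are mapped back to the natural
  scale; positive scalings leave the zero pattern unchanged.
* **Optimiser.** FISTA (accelerated proximal gradient) with backtracking
  line search, the group soft-threshold proximal map, and function-value
  restart; relative-objective tolerance 1e−7, at most 5000 iterations
  per λ, warm starts along the path.  Plain ISTA needs an order of
  magnitude more iterations in the small-λ regime.
* **Path.** 50 log-spaced λ values from the *global* λ_max (the largest
  per-node KKT bound: max group score norm at the intercept-only
  maximum likelihood, which is available in closed form) down to
  0.01·λ_max.  A single shared path keeps per-λ graphs comparable
  across nodes for ROC use; selection is still per node.  At λ ≥ λ_max
  every neighborhood is exactly empty (verified as a KKT boundary test).
* **Saturation guard.** The clr transform imposes a zero-sum over
  present entries, so once *all* of a node's groups are active its
  conditional becomes degenerate: `y_i` is an exact linear function of
  the other present taxa and the likelihood diverges as λ → 0.  The
  path fit stops at the first saturated point (the solution is carried
  forward), and saturated points are excluded from model selection.
* **Selection.** Per-node BIC, `−2·loglik + log(n)·df` with
  `df = 3 + 4·(#active groups)` (1 + #active in Ising mode), evaluated
  at the penalised path solution, ties to the sparser model.  The
  classical lasso-then-refit debiasing was evaluated and rejected: on
  clr data the unpenalised likelihood of a model with `k` of `p−1`
  groups active gains roughly `(n/2)·log(1/(1−k/(p−1)))` from the
  compositional constraint alone, which tracks the BIC penalty line and
  drives refit-based selection toward dense graphs.  The shrinkage of
  the penalised fit is what holds this artifact down.
* **Aggregation.** Union (OR) over the two node regressions per pair;
  per-edge flags record which of g/h_ij/h_ji/k fired in either
  regression.  The reported edge weight is the sign-preserving mean of
  the nonzero fitted components (up to 8 of them) — an
  implementation-defined summary for ranking and display, not a model
  parameter.
* **Degenerate columns.** A taxon present in every sample has an
  unidentifiable presence submodel: its α, g-row and h-row are frozen
  at zero (with a warning) and only the continuous parts are fit.
  All-absent taxa are rejected (prevalence screening removes them).
* **Parallelism.** Node fits are independent; with `n_jobs > 1` they run
  under joblib with results identical to the sequential order.

`mode="ising"` zeroes the continuous data and frees only the `g`
components (with κ pinned at 2π so the presence law is exactly
logistic), giving the classical Ising neighborhood selection as the
binary-only baseline.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions under which the estimator is evaluated.

* **Topologies.** `ar1`: the chain `0−1−…−(p−1)` (interior degree two);
  `ba1`: a Barabási–Albert preferential-attachment tree, one edge per
  new node (hubs arise).
* **Parameter settings.** `g_minimal` (G on all edges; H, K diagonal),
  `k_minimal` (K on all edges), `g_k` (G on all edges, K on the induced
  subgraph of nodes ⌊p/2⌋..p−1, H diagonal), `h_k` (H on all edges, K on
  the second-half subgraph, G diagonal — defined by mirroring `g_k`),
  and `g_h_k` (G and H on all edges, K on the second-half subgraph).
  Nonzero off-diagonals are i.i.d. Uniform(−0.1, 0.1); H's two
  directions are drawn independently.
* **Diagonals.** Each diagonal entry is the column sum of *absolute*
  off-diagonal values plus 0.1.  The absolute value matters: with signed
  Uniform(−0.1, 0.1) entries a signed column sum cannot guarantee
  positive definiteness, which is the rule's purpose; the absolute rule
  makes K strictly diagonally dominant (Gershgorin).
* **Sampling.** Systematic-scan Gibbs over the exact univariate
  conditionals; defaults are 1000 burn-in scans and 10-fold thinning
  ("2000 iterations after burn-in with 10% down-sampling" read as
  keep-every-10th-scan), so the default condition draws n=200 samples of
  p=60 taxa.  One uniform and one normal variate are pre-generated per
  coordinate update, making the chain a pure function of the seed.  The
  topology/parameter seed and the chain seed are separate fields, so
  datasets can share a ground truth.
* **Closure.** Present taxa get `w = exp(z)` and absent taxa `w = 0`
  (the literal `w = e^z` would map absent taxa to `w = 1` and destroy
  the zero pattern), then rows are normalised to proportions.  Rows with
  no present taxon cannot be normalised and are redrawn by continuing
  the chain (counted and logged; rare at default parameters).

What the generator does *not* emulate: sequencing-depth variation and
count discreteness (it emits proportions directly; an optional
multinomial resampling to integer counts is deliberately absent from
the defaults), taxonomic correlation of parameters, and overdispersed
library sizes.  Passing tests therefore certify the statistical
machinery under the model's own assumptions, not performance on any
particular real cohort.

## Evaluation, stability, assortativity

Structure recovery is scored over the `p(p−1)/2` unordered pairs:
confusion counts, TPR/FPR, Matthews correlation (zero-denominator
convention: MCC = 0), and ROC/AUC along the penalty path (curve anchored
at (0,0) and (1,1), FPR-sorted, staircase-monotone TPR, trapezoidal
area, no convex hull).

Bootstrap stability resamples the n samples with replacement B times
(default 100) and refits with the identical configuration, including
path construction and per-node re-selection of λ; an edge's stability is
the fraction of bootstrap networks containing it, reported over the
union of edges seen.

Assortativity is Newman's categorical coefficient
`r = (Σ_c e_cc − Σ_c a_c b_c)/(1 − Σ_c a_c b_c)` on the edge mixing
matrix of a taxonomy rank (each between-category edge contributes ½ to
each off-diagonal cell).  The permutation test shuffles the node labels
(default 100,000 permutations) and reports the strictly-greater
p-value `#{r_perm > r_obs}/n_perm`; an `--add-one` flag switches to the
conservative `(#{r_perm ≥ r_obs}+1)/(n_perm+1)` variant.  The
implementation is cross-checked in the tests against networkx's
attribute assortativity on random graphs.

## Problem sizes in the test suite

The test and acceptance computations run the pipeline at reduced scale,
chosen once as the smallest sizes at which the studied contrasts are
visible: recovery contrasts at p=20, n=400 over 10 seeds; consistency
at p=10 with n ∈ {200, 1000, 4000}; small-p oracles at p ≤ 3 with
20,000–50,000 Gibbs draws; bootstrap checks at p ≤ 10 with B ≤ 20.

## Known limitations

* **Compositional bias at small p.** After the clr map, every pair of
  taxa acquires a spurious conditional dependence of order 1/p.  At the
  default generator scale (p = 60) this is negligible next to real
  couplings, but in small-p benchmarks it forms a noise floor: path AUC plateaus below 1
  as n grows instead of converging to it, and the weakest
  binary/cross couplings cannot be ranked above the floor.
* **Saturated-fit degeneracy.** The fully-conditioned clr likelihood is
  singular by construction; everything past saturation on the path is
  reported but flagged, and never used for selection.
* **Weak-coupling regime.** With Uniform(−0.1, 0.1) effects, per-edge
  evidence at a few hundred samples is marginal; BIC (a consistent,
  conservative rule) then prefers very sparse graphs.  The path AUC is
  the better-powered summary at that scale; selected-network MCC
  reflects the conservative selection.
* **Ising near criticality.** Strong positive presence couplings push
  the chain toward an all-present phase (little binary variance) and
  slow Gibbs mixing; presence-balanced fields and heavier thinning are
  used in tests that need strong binary signal.
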