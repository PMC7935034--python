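# Methods

This note records the models, parameter defaults, numerical choices, and
limitations behind `connmap`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Graph construction

A subject's symmetric correlation matrix is reduced to a binary undirected
graph in two stages. First, Kruskal's algorithm on descending |r| builds a
**maximum-|r| spanning tree** (equivalently a minimum spanning tree on
1 − |r|), guaranteeing connectivity: nodal efficiencies of a disconnected
region would otherwise be dominated by the infinite-distance convention
rather than by topology. Second, the remaining edge budget is filled with
the largest |r| pairs not already in the tree until the graph holds exactly
`round(density · N(N−1)/2)` edges (round half-up; the convention is
declared because the edge budget at, say, 2.5 % density need not be an
integer). Requesting a budget below N−1 raises an error rather than
silently returning only the tree. Absolute correlation is used for ranking
throughout — strong negative coupling is as much a link as strong positive
coupling at this stage of the pipeline.

Ties in edge weight are broken by lexicographic (i, j) node order
everywhere, so the construction is deterministic; this matters for
reproducibility when synthetic matrices contain repeated values.

Fixing the edge count per density makes nodal metrics comparable across
subjects: every graph in a cohort has identical density, so differences in
degree or efficiency reflect reorganization, not sparsity.

## Nodal metrics

For a binary graph G on N nodes with hop distances L_ij:

- **degree** D_i = Σ_j G_ij;
- **global efficiency** Eglob_i = (1/(N−1)) Σ_{j≠i} 1/L_ij, with 1/∞ := 0
  so the value stays defined on disconnected graphs;
- **clustering** Clust_i = (1/(k(k−1))) Σ_{j≠l} 1/L_jl over the k neighbors
  of i, with path lengths computed **inside the neighbor-induced subgraph**
  (node i removed). This is the standard local-efficiency reading of
  neighborhood clustering; whether paths should instead be taken in the
  full graph is a genuinely open convention, and the subgraph-internal
  variant was chosen because it isolates the neighborhood's own wiring.
  Nodes with fewer than two neighbors score 0 — the quantity is otherwise
  undefined, and 0 (no neighborhood wiring) is the natural limit.

All three are cross-checked in the test suite against independent
networkx computations on random graphs.

## Scalar descriptors

**Hub disruption index κ.** For subject vector m and control reference
h̄ (node-wise control mean), κ is the OLS slope of (m − h̄) on h̄. The
defining regression is printed without an intercept, and its
interpretation assumes both groups share the same global mean; real
cohorts violate that assumption, so **an intercept is fitted by default**
(`fit_intercept=False` restores the through-origin form; both modes are
tested). κ = 0 means identical organization; κ = −1 means the subject's
profile is flat at the reference mean; κ < 0 generally means hub/non-hub
reversal.

**LDA.** With N nodes ≫ n subjects the within-class scatter S_w is
singular, so the Fisher direction uses shrinkage toward the diagonal,
S = (1 − λ) S_w + λ diag(S_w), default λ = 0.1 — enough to keep the solve
stable at N/n ratios around 5–10 without washing out covariance structure.
Scores are centered on the grand mean.

**FS.** Per-node pooled-variance two-sample t; the selected node is the
argmax of |t|, ties to the lowest node index, zero-variance nodes get
t = 0.

**Permutation test.** Two-sided test on the difference of group means.
Monte-Carlo shuffles are seeded and the p-value uses the add-one estimator
(b+1)/(B+1), so p is never 0 and the smallest attainable value is 1/(B+1).
When the number of distinct label assignments is ≤ B the test switches to
exhaustive enumeration (the identity split is then included, so
p = count/total is already bounded away from 0). Descriptor–descriptor
association uses the Pearson correlation.

## ISOMAP

The neighbor graph connects each subject to its k = 4 nearest neighbors in
Euclidean metric-vector distance (union symmetrization); k = 4 suits
cohorts of a few dozen subjects. Geodesic distances are Dijkstra shortest
paths over Euclidean edge lengths; classical MDS (double centering, top-d
eigenvectors scaled by √eigenvalue) gives the coordinates. Two
determinism/robustness choices the classical algorithm leaves open:

- **Disconnected neighbor graphs** are repaired by repeatedly adding the
  single shortest Euclidean edge between two components (an error mode is
  available via `bridge_components=False`).
- **Axis signs** are fixed by making the largest-|coordinate| entry of each
  axis positive.

With the neighbor graph complete, the procedure provably reduces to PCA;
the acceptance script verifies this equivalence to ~1e−14 and checks the
quarter-circle arc unrolling against the analytic arc length.

Covariate surfaces use thin-plate-spline RBF interpolation with zero
smoothing (reproduces affine covariates exactly; a Gaussian kernel with
width = median inter-point distance is available). Leave-one-out RMSE and
maximum error are computed by refitting without each subject in turn. The
class-probability map is L2-regularized logistic regression (C = 1).
Classification accuracy is leave-one-out CV of an RBF SVM with the median
heuristic γ = 1/(2·median²) and C = 1 — leave-one-out because cohorts of
~26–37 subjects leave no room for a held-out split, and the median
heuristic because no tuning set exists at these sizes.

## CCML

The reduced point is x̃_i = [α c_i ; x_i]. The constrained axis is **never
optimized or penalized** — it is stored as α·c structurally, so the
constraint holds to machine zero by construction. The cost is the raw
stress E = Σ_{i<j} (‖x̃_i − x̃_j‖ − ‖y_i − y_j‖)², the canonical
distance-matching objective; the squared-distance variant
(‖Δx̃‖² − ‖Δy‖²)² sits behind `squared_differences=True`. Original-space
distances ‖y_i − y_j‖ are Euclidean; geodesics are used only to order the
insertions and pick the initial landmark pair.

Optimization proceeds by farthest-point insertion: start from the two
subjects at maximal geodesic distance (placed so their reduced distance
matches their original distance, given α₀ = max pairwise data distance /
covariate range), then repeatedly insert the subject with the largest
minimum geodesic distance to the placed set (ties to the lowest index).
Each insertion runs three sub-optimizations — the new point's free
coordinates, α, then the previously placed free coordinates — one pass by
default (`inner_loops` configurable). New points start at the
inverse-distance-weighted barycenter of their three nearest placed
neighbors.

Numerical backend: the low-dimensional sub-problems (new point, α) use
Nelder–Mead (tolerance 1e−8, 500 iterations cap) — robust to the
non-smooth norm at coincident points; the joint re-optimization of placed
points and the final polish use L-BFGS-B with the analytic stress gradient,
which converges far better over the ~n coupled free coordinates. After all
insertions a **joint polish** over (α, all free coordinates) runs, followed
by a deterministic **reflection repair**: stress surfaces have mirror
basins in which a point settles on the wrong side of a free axis and no
gradient step can carry it across, so each point is re-optimized from a
small deterministic candidate set (current placement, reflection across
the other points' centroid, and the two triangulation solutions implied by
its distance to the nearest placed point), and the polish is repeated while
any point moves (at most three rounds). On planar instances this reliably
drives the relative stress below 1e−18 and recovers the planted scale
factor to well under 1 %.

`restarts=R` reruns the whole procedure from jittered seeded
initializations and reports the fraction of runs landing in the best cost
basin — the convergence-rate diagnostic for the optimization problem; its
value is data-specific.

The per-insertion cost trace is recorded (cost after initialization and
after each sub-optimization) and is non-increasing within each insertion
by construction (each optimizer returns its best-seen point).

## Generative model (MARS)

One degree-1 MARS regression per node maps reduced coordinates to that
node's metric value: prediction = intercept + Σ coef · max(0, ±(x_v − t)).
The forward pass greedily adds **mirrored hinge pairs** at observed data
values (a pair spans affine functions exactly, since
max(0,u) − max(0,−u) = u), stopping at `max_terms = min(21, n−1)` basis
functions or when the RSS stops improving. The backward pass greedily
deletes single terms, keeping the model minimizing
GCV = RSS/n / (1 − C/n)² with effective parameters
C = #terms + penalty · #knots, penalty c = 3 (the standard default for
additive models). Degree 1 (no interactions) suffices for the
locally-linear-globally-nonlinear behavior required here. Constant targets
degenerate cleanly to an intercept-only model. Predictions are continuous
piecewise-linear by construction.

Covariate traversal holds a subject's free coordinates fixed and sets the
constrained axis to α·value for each requested covariate value; movement
in the free coordinates is out of scope (the interpretable direction is
the covariate axis).

## Synthetic generators

All generators are pure functions of (parameters, seed).

- `simulate_metric_cohort`: reference profile h̄ = sorted lognormal(0, 1)
  draws — a realistic heavy-tailed hub hierarchy. Controls are h̄ + noise;
  patient j is m = h̄ + κ_j (h̄ − mean(h̄)) + noise. The disruption term is
  **mean-centered** rather than the literal κ·h̄, so the global node
  average is preserved (the interpretive assumption of the index) and the
  intercept-fitted regression recovers κ_j exactly at zero noise. Noise is
  node-wise Gaussian with σ expressed as a fraction of sd(h̄); σ = 0.1 is
  the default study condition.
- `simulate_graph_cohort`: node attractiveness w = sorted lognormal;
  graphs sample a weighted random spanning tree, then weighted edges
  without replacement to exactly n_edges. Patient attractiveness is
  (1−β) w + β reverse-ranked(w): β = 0 is exchangeable with controls,
  β = 1 swaps hubs and non-hubs in expectation, driving the degree-based
  κ negative.
- `make_two_factor_cohort`: two uniform latent factors mapped through
  orthonormal directions plus a curvature term ((f1² − f2²)/2, weight 0.5
  by default; 0 gives an exactly linear map), with noise at 5 % of the
  signal spread.

What the generators do **not** emulate: spatial autocorrelation between
brain regions, subject-level covariate structure (age, clinical scores),
inter-metric dependence, and measurement artifacts of fMRI preprocessing.
Passing tests therefore demonstrate correctness of the estimators and
optimizers under the stated models, not performance on real connectomes.

## Problem sizes

Tests and the acceptance script run at the scale of the motivating
studies: N = 90 nodes, cohorts of 20–37 subjects, κ ∈ [−1.5, 1.5],
B = 200–10⁴ permutations, 20–100 seeded replicates per Monte-Carlo check.
These sizes are the package's reference conditions for calibration
experiments.

## Known limitations

- CCML's stress surface is non-convex; the farthest-first insertion plus
  reflection repair empirically reaches the global basin on planar and
  two-factor instances, but no global-optimality guarantee exists (the
  `restarts` diagnostic quantifies basin stability per dataset).
- The MARS forward pass scans every observed value of every coordinate as
  a knot candidate; at the intended scale (n ≤ a few hundred, d = 2–3)
  this is inexpensive, but it is quadratic in n per added pair.
- Leave-one-out SVM and surface errors refit n models; both are O(n)
  refits and sized for cohorts of tens, not thousands.
- The permutation test shuffles group labels only; it does not model
  covariate-adjusted null hypotheses.
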