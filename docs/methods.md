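# Methods

This note documents the models and algorithms implemented by `topictree`,
the defaults and numerical choices, and what the synthetic benchmark does
and does not establish.

## Input pre-treatment

Expression values (genes x cells, any non-negative units) are transformed
to `log2(1 + x)` and genes whose post-transform standard deviation across
cells (ddof = 1) falls below `sd_threshold` (default 0.5) are removed. The
transformed values are then rounded half-up to integers, which become the
word counts of the topic model; a `scale` factor (default 1) is exposed for
sensitivity checks. Rationale for rounding the log scale: it keeps per-cell
token totals in a range where collapsed Gibbs sampling is cheap while
preserving the rank structure of expression. A cell whose discretised
column is all zero is an error, never silently dropped — losing samples
silently would corrupt downstream orderings. `pretreat` records itself in
the matrix provenance and refuses to run twice, since a second log
transform would silently change the scale.

## Topic model and inference

Cells are documents, discretised expression levels word counts. With M
cells, V genes and K topics:

    phi_k   ~ Dirichlet_V(beta),   theta_d ~ Dirichlet_K(alpha),

and inference is collapsed Gibbs sampling over token-topic assignments with
the standard conditional

    p(z = k | rest) ∝ (n_dk + alpha_k)(n_kw + beta_w) / (n_k + sum(beta)).

Defaults: symmetric `alpha = 50/K`, `beta = 0.1` (the usual collapsed-Gibbs
defaults; smaller values sharpen the model), 800 sweeps with 200 burn-in,
posterior means of theta and phi accumulated every 10th post-burn-in sweep.
All are exposed as arguments/flags. The complete-data log likelihood
log p(w, z) is recorded per sweep as a convergence trace.

Determinism and exchangeability: the sampler processes cells in
lexicographic cell-id order with tokens in lexicographic gene-id order, and
each cell draws from its own RNG substream seeded by (master seed,
canonical cell rank). Fits are therefore bit-identical under any
permutation of input rows or columns (tests assert this at 1e-12). The
inner sweep is compiled with numba; one core suffices for the shipped
problem sizes (a 60-cell x 500-gene fit with 1500 tokens/cell takes a few
seconds).

## Choosing the number of topics

`select_topic_count` scans K = k_min..k_max, warm-starting each fit from
the previous fit's assignments and seeding the fresh topic with the 5% of
tokens that had the lowest conditional probability under the previous model
(an iterative-residual scan). Each K is scored by a MAP-style penalised log
posterior: the multinomial *mixture* log likelihood at the posterior-mean
theta and phi,

    sum_{d,w} n_dw log(theta_d · phi_{:,w})  −  (df / 2) log N,

with df = K(V−1) + M(K−1) free parameters and N total tokens. The
z-conditional likelihood log p(w | z) is deliberately not used: it keeps
improving with K long past the true structure (every extra topic can absorb
multinomial noise through the assignments), whereas the mixture likelihood
at the posterior means plateaus at the data's true complexity, so the BIC
penalty can act. On generated data with three well-separated topics the
scan recovers K = 3 across seeds; on exchangeable (single-topic) data the
score is non-increasing beyond the smallest K.

## Cell distances, tree, rooting, ordering

Cells are compared by the chi-square distance between their topic
histograms; a component with `x_k + y_k = 0` contributes zero. The MST is
built with Kruskal on lexicographically pre-sorted edges, so ties resolve
identically on every platform. Two rooting modes:

* `diameter` — find the weighted diameter path (double Dijkstra sweep,
  exact on trees) and root at the endpoint with the smaller mean distance
  to the starting group. Suited to linear processes.
* `centrality` — root at the starting-group cell minimising the mean
  *squared* chi-square distance to the rest of the group. Suited to
  branching processes.

The starting group can be supplied or detected as the group with the
smallest mean pairwise intra-group distance (early stages are typically the
most homogeneous). Cells are ordered by weighted path distance from the
root — a pseudotime proxy; whether the original formulation orders by path
distance or traversal is ambiguous, and path distance was chosen because it
is invariant to child enumeration order. Ties break lexicographically.

Orderings are scored by pairwise agreement: the percentage of cell pairs,
comparable under the reference (ties excluded from the denominator), whose
relative order matches; the candidate is reversed when that raises the
score, because an ordering's direction carries no information. A
travelling-salesman baseline (nearest-neighbour construction from the
starting group's most central cell, then 2-opt to a local optimum,
deterministic) provides the naive comparison on euclidean log-expression
distances.

## Backbone trees

A backbone tree over cells V with width delta partitions V into backbone
vertices V_B (forming a subtree), vertebrae (each within delta of the
backbone and attached by a single edge to its *closest* backbone vertex)
and at most `outlier_fraction` (default 0.05) outliers. The objective is
the summed backbone edge weight; minimising it is NP-complete, so:

* **Heuristic** (`build_backbone`): start from the MST; repeatedly absorb
  the leaf with the heaviest incident edge, provided it stays within delta
  of a remaining vertex (or can be charged to the outlier budget; vertebra
  absorption preferred). Vertices stranded by later removals are restored.
  A steepest-descent local search over the backbone set (delete, swap, add
  moves, deletions first) then shrinks the backbone MST while coverage
  holds. The output always satisfies the four defining conditions, and its
  objective never exceeds the all-backbone MST weight.
* **Exact solver** (`brute_force_backbone`, <= 10 cells): enumerates every
  outlier set within budget and every backbone subset, taking the MST over
  V_B as the backbone subtree (whether the backbone may use non-MST edges
  is ambiguous; MST-over-V_B is used consistently in both solvers). Used as
  the test oracle: on random 8-point instances the heuristic stays within
  1.5x of the optimum (measured: ~1.00 on average) and is never below it.

Vertices farther than delta from every other vertex can never be
vertebrae; they fill the outlier budget first (most isolated first) and any
excess stays in the backbone, which the definition always permits — no
instance is infeasible and delta is never silently inflated.

`delta` defaults to the first mode of a Gaussian KDE (Silverman bandwidth)
of the pairwise distances, evaluated on a 512-point grid over [0, max]: the
smallest strict interior local maximum. If the density is monotone on the
grid (no interior mode), the 25th percentile is used and flagged in the
result metadata. Bandwidth rule, grid size and fallback are exposed.
Rooting maps the starting group's most central cell into the backbone (a
vertebra's attachment point stands in for it).

## Topic enrichment

Genes are ranked per topic by phi (descending, ties lexicographic) and each
term of a gene-set collection is tested with a one-sided two-sample
Kolmogorov–Smirnov test: member genes' per-topic probabilities
stochastically greater than non-members' (the direction follows from the
purpose of the ranking; the exact variant is otherwise a documented
choice). Terms with fewer than 3 member genes in the universe, or covering
more than half of it, are skipped; the universe is the set of genes that
survived pre-treatment, so p-values refer to the fitted model. Three modes:

* `classic` — independent test per term.
* `elim` — terms processed most-specific-first (by longest-path depth);
  a term significant at `sig_threshold` (default 0.01) has its genes
  removed from all ancestors before they are tested.
* `weight` — comparative variant: when an already-tested child has a
  smaller raw p-value than its parent, the child's genes are removed from
  the parent's member set and the parent re-tested. This is a simplified
  gene-claiming scheme rather than a reimplementation of any particular
  package's internals; it satisfies the defining properties (identical to
  classic on an edgeless DAG; never more significant terms than classic;
  planted signals recovered).

Annotations are made upward-closed on load (ancestors inherit descendants'
genes) after a cycle check. Bonferroni correction multiplies by the number
of terms tested for that topic (per topic, not across topics; a global
flag exists). A term significant (corrected p < alpha) in exactly one topic
is flagged `unique_to_topic`; `in_minority` marks terms significant in
strictly fewer than K/2 topics — exactly K/2 is excluded.

## Synthetic benchmark

`generate_trajectory` draws data from the LDA generative process itself:
phi rows are Dirichlet(0.1) with disjoint "anchor" gene blocks (V/(2K)
genes each) carrying 70% of the topic's mass — these blocks are the planted
gene sets; theta follows a piecewise-linear path through the simplex
corners e_1 → … → e_K as pseudotime advances (branches diverge at
pseudotime 0.5 toward distinct corners), perturbed toward a random simplex
point with a deterministic L1 magnitude `noise · (0.25 + 1.5 t)` — random
direction, fixed size — so intra-stage dispersion grows along the
trajectory by construction and automatic start-group detection has
something to detect. Exactly `tokens_per_cell` tokens are drawn per cell;
stage labels are pseudotime quartiles. Defaults (M=80, V=500, K=4,
1000 tokens/cell, noise=0.1, one branch) define the standard benchmark:
4 stages x 20 cells of desk-scale data. The generator asserts its own
documented structure (exact column sums, disjoint anchors, monotone jitter)
on every fixture. `generate_null` draws exchangeable cells from a single
gene distribution for type-I calibration.

What passing these tests does **not** show: the generator draws from the
model family being fitted, with no dropout, no library-size variation, no
ambient contamination and multinomial noise only, so results here bound
what clean, well-specified data allows; real scRNA-seq performance depends
on how far the data departs from those assumptions.

## Problem sizes and numerics

The shipped tests run at M <= 80, V <= 500, ~10^5 tokens — sizes chosen so
the full suite completes in about a minute while leaving recovery
non-trivial. Exact backbone enumeration is guarded at 10 cells (2^10
subsets x MST each). Tolerances: simplex rows are validated at 1e-9;
distance/oracle comparisons at 1e-12; all argmax/argmin ties break to the
lowest index or lexicographically smallest identifier. Degenerate inputs
fail loudly: all-zero distance matrices, singleton groups for start-group
detection, unrooted trees passed to ordering, K exceeding the number of
expressed genes.

## Known limitations

* The `weight` scheme is a simplified decorrelation, not byte-compatible
  with established ontology tools.
* Model selection's BIC-style df counts free parameters of the mixture; it
  is a pragmatic approximation to a marginal likelihood, adequate for
  well-separated topics, and can under-penalise at very small token counts.
* The backbone local search is a heuristic; optimality is only verified on
  small instances.
* The TSP baseline is nearest-neighbour + 2-opt, not an exact tour.
* No OBO parsing: term DAGs are supplied as a child/parent edge TSV.
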