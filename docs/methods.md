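# Methods

This note documents the statistical procedures implemented in
`symptomnet`, the choices made where the design was genuinely open, and
what the synthetic data generator does and does not emulate.

## Data model

An `ItemResponseMatrix` holds one dimension of an MSAS-style assessment:
occurrence ∈ {0,1}, severity ∈ {0..4}, distress ∈ {0..4}. Because the
instrument rates severity and distress only for symptoms that occurred,
a coding convention is unavoidable: by default a non-occurring symptom is
coded as category 0 on both rating scales (`absent_policy="zero"`), which
keeps every respondent in every pairwise estimate. The alternative
(`absent_policy="pairwise"`) treats category 0 as missing and estimates
each polychoric correlation from pairwise-complete observations; it is
exposed because the field is split on the question, and the two policies
can give visibly different severity/distress networks (the zero code
injects the occurrence pattern into the latent-scale estimates). Missing
cells are handled by listwise deletion at read time, with the dropped-row
count logged.

## Binary networks: eLasso

For node j, the ℓ1-penalized logistic path of Xⱼ on X₋ⱼ is computed by an
iteratively reweighted least squares / coordinate descent scheme (the
glmnet recipe): working response and weights from the current linear
predictor, coordinate updates on a cached weighted Gram matrix,
active-set sweeps, warm starts along the path, unpenalized intercept.
Convergence is declared at a maximum coefficient change of 1e-6
(recorded in the result metadata). The path uses 100 λ values log-spaced
from λ_max (the smallest λ with an all-zero solution, computed from the
score at the intercept-only fit) down to 0.01·λ_max.

The path serves as a candidate-set generator. Every distinct nonzero
pattern along the path — plus, always, the empty set — is refit by
unpenalized logistic regression, and the EBIC

    −2ℓ(refit) + |J| log n + 2γ|J| log(p−1)

is minimized over candidates, ties resolved toward the sparser
(larger-λ) set. Evaluating the EBIC on the ML refit rather than on the
shrunken path coefficients keeps the selection criterion about the
*support*, not about the amount of shrinkage: tests against an exhaustive
all-subsets EBIC search at p=3 agree seed-for-seed under this definition,
and the false-edge rate under a null model drops accordingly. With
γ = 0.25 (default) and the OR rule, a 6-node chain with couplings 1 at
n = 2000 is recovered with mean sensitivity 1.0 and specificity ≈ 0.99.

Directed neighborhoods are symmetrized by the AND or OR rule; the edge
weight is the arithmetic mean of the two directed (refitted)
coefficients, a selected zero contributing 0. Constant columns are
rejected by name, since the threshold of a never- or always-endorsed
symptom is unidentifiable.

## Ordinal networks: polychoric + graphical lasso

Polychoric correlations use the two-step estimator: thresholds are
standard-normal quantiles of the cumulative marginal proportions, then ρ
maximizes the contingency-table likelihood with thresholds fixed,
bounded to |ρ| ≤ 0.999 (perfectly concordant tables hit the bound).
Tables with an empty cell receive a 0.5 continuity correction on every
cell. Bivariate-normal rectangle probabilities come from the scipy
bivariate CDF at absolute tolerance 1e-7, and cell probabilities are
floored at 1e-12 before taking logs. The assembled p×p matrix is not
guaranteed positive-definite (each pair is estimated separately); if its
smallest eigenvalue falls below 1e-6 it is replaced by the nearest PD
correlation matrix (eigenvalue clipping, rescale to unit diagonal) and
the correction is flagged.

The graphical lasso is solved per λ with scikit-learn's coordinate
descent implementation; a tight inner (elastic-net) tolerance of 1e-9 is
what actually controls the stationarity residual of the returned
precision (verified ≤ 1e-4, typically ≤ 1e-7). The λ path mirrors the
binary side: 100 points from λ_max = max off-diagonal |S| down to
0.01·λ_max. As with eLasso, the EBIC for penalty selection,

    −2ℓ(Θ̂) + E log n + 4γE log p,  ℓ(Θ̂) = (n/2)(log det Θ̂ − tr(SΘ̂)),

is evaluated on the covariance-selection MLE for each path support
(computed by iterative proportional scaling: the inverse of the refit
precision matches S exactly on the support and diagonal), with E the
number of selected edges and constant terms dropped — selection is
invariant to additive constants. Evaluating on the refit rather than the
penalized solution prevents the tiny spurious edges that ride in with
shrinkage from surviving selection: on a p=10 chain-plus-shortcuts
design with partial correlations 0.3 at n=1000, edge recovery is
sensitivity 1.0 / specificity 1.0 versus specificity ≈ 0.81 under
penalized-loglik selection. The *returned* network is the penalized
glasso solution at the selected λ (so the KKT conditions of the glasso
objective hold exactly), reported as partial correlations.

## Centrality

Strength is the sum of absolute incident weights. Shortest paths are
computed on distances 1/|w| — stronger association, shorter path — the
convention of the weighted-network literature. Closeness is the inverse
of the summed distance to all *reachable* nodes, 0 for isolated nodes
(finite, and monotone in connectivity on disconnected graphs).
Betweenness counts shortest paths through a node with fractional credit
for ties (Brandes' algorithm via networkx, verified against a
Floyd–Warshall path-counting oracle and full simple-path enumeration).
Raw and z-standardized (population SD) columns are always emitted; a
constant raw column gets z = 0.

## Bootstrap accuracy and stability

Edge accuracy: B row resamples with replacement (default B = 1000,
refused below 50), full re-estimation per resample, per-edge quantile
CIs at α/2 and 1−α/2. Two edges are declared significantly different
when the α-level quantile interval of their bootstrapped difference
excludes zero; a zero-variance difference distribution (possible only
with a degenerate estimator) is treated as no evidence and never flags.
No multiple-testing correction is applied (per-comparison α, noted in
the output).

Subsetting stability: for each drop proportion q in the default grid
{0.1, …, 0.7} (with 250 iterations per proportion — both implementation
defaults, flagged as such in the report metadata), ⌊qn⌋ rows (case mode)
or ⌊qp⌋ nodes (node mode) are dropped, the network re-estimated, and
each centrality index Pearson-correlated with the full-sample values
over the retained nodes. A correlation with a zero-variance side is
recorded as 0 — a constant centrality profile cannot certify that the
ordering was retained (this also makes the CS of an empty noise network
0 rather than spuriously perfect). The CS coefficient per index is the
largest q whose correlations reach `cs_correlation` (0.7) in at least a
`cs_certainty` (0.95) fraction of iterations, 0 if none qualifies.

Split replication partitions respondents into k equal random groups
(default 4; remainder rows dropped and logged), estimates one network
per group, and reports the k×k Pearson correlation matrix of
node-strength vectors.

All bootstrap draws derive from the config seed; identical seeds give
identical CIs, CS values and split correlations.

## Communities

Walktrap (igraph implementation, walk length t = 4 by default) on
absolute edge weights — random walks need non-negative capacities, and
estimated symptom networks contain at most a handful of negative edges
(the count of sign-flipped edges is recorded per run). The dendrogram is
cut at maximum modularity; isolated nodes come out as singletons.
Weighted modularity Q = Σ_c(e_c/m − (d_c/2m)²) is implemented directly
and verified against hand values and exhaustive partition search on
small graphs. Merge costs are not exposed by the igraph dendrogram, so
merge history records the merge pairs with a NaN cost placeholder.

## Synthetic data generator

The generator plants a chain-of-communities graph: 5 near-equal blocks
(complete within a block, consecutive blocks joined by one bridge),
couplings 0.8 within / 0.1 between for the Ising truth, with thresholds
τⱼ = −½Σₖβⱼₖ to center marginals near 0.5. The ordinal truth shares the
planted zero pattern through a precision matrix Θ = I − A (within-block
partial correlation 0.12, bridges 0.03, rescaled if needed for positive
definiteness), discretized by fixed thresholds into 5 categories.
Severity and distress are then gated by occurrence: where a symptom did
not occur the rating is set to 0, so "rating > 0 ⇒ occurrence = 1" holds
by construction. Gating is applied after sampling — it reproduces the
instrument's skip logic, not a claim about any joint clinical process.

Ising sampling is exact (full 2^p enumeration) up to p = 20; beyond
that, n parallel Gibbs chains with a 1000-sweep burn-in produce one draw
each — approximate, flagged by the `method` argument. The fixture is
structural: it reproduces the dimensionality (n = 1328 × 38 symptoms,
with the standard MSAS symptom codes), the occurrence gating, and a
block structure in the plausible community-count range; it does not
match any real population's symptom prevalences, inter-dimension
dependence beyond gating, or marginal distributions, so passing tests
demonstrate correctness of the estimators under a known truth, not
clinical generalizability.

## Test and verification sizes

Oracle-equivalence checks run at the sizes where exhaustive search is
exact (p = 3 all-subsets EBIC at n = 5000; Bell-number partition
enumeration at p = 6; simple-path enumeration at p ≤ 7). Recovery
simulations use p = 6, n = 2000 (binary chain, 20 seeds) and p = 10,
n = 1000 (Gaussian chain, 20 seeds). Bootstrap-machinery tests use
pluggable estimator seams at B between 20 and 250 so that the resampling
logic, not estimator cost, is what is exercised. The end-to-end
determinism check runs the complete occurrence analysis twice at the
full fixture size (n = 1328, p = 38) and compares outputs byte for byte.

## Known limitations

- The severity/distress zero-coding default conflates "absent" with the
  lowest rating; the pairwise policy is the only alternative offered.
- Polychoric estimation is two-step, not full ML; thresholds are treated
  as known when ρ is optimized.
- Gibbs-mode samples are approximate; no convergence diagnostic beyond
  the fixed burn-in is computed.
- The edge-difference test inherits the per-comparison α convention and
  will over-flag when many pairs are compared.
- Node-dropping stability correlates centralities over retained nodes
  only, which favors optimism when few nodes remain.
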