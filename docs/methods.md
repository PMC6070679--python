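# Methods

This note records the models, conventions, and numerical choices behind
`riversem`, including the places where the design was genuinely open and a
choice had to be made.

## Causal diagrams and d-separation

A diagram is a DAG over named variables plus optional bidirected arrows.
A bidirected arrow `a <-> b` is shorthand for a latent common cause and is
handled everywhere by its explicit expansion (a fresh latent node with
arrows into `a` and `b`). d-separation is decided by
moralized-ancestral-graph reachability: restrict to the ancestors of
`{x, y} ∪ Z`, marry co-parents, drop directions, delete `Z`, and test
connectivity. This is O(V+E) per query and is checked in the test suite
against an independent path-enumeration oracle (every undirected simple
path, collider rules applied literally) on exhaustive enumerations of small
DAGs and on random 6-node DAGs, and against networkx's d-separation as a
third route.

**Basis set.** One statement per non-adjacent pair `{i, j}`, conditioning on
`pa(i) ∪ pa(j)`. Several constructions with the same count exist; this one
was chosen because each statement is testable with a single regression (the
conditioning set is exactly the parents of the two variables) and because
it reproduces the count law `V(V−1)/2 − A`. Pairs joined *only* by a
bidirected arrow get no statement: the latent common cause is precisely an
exemption from the independence claim. Consequently `A` in the count law
counts adjacent pairs of either kind. Statement enumeration is
lexicographic in declared node order, making reports deterministic.

## Ordination

Bray–Curtis dissimilarity is computed on square-root-transformed
abundances (scipy's `pdist`); a pair of all-zero rows is defined as
dissimilarity 0 with a warning rather than NaN. PCoA is the classical
Gower-centred eigendecomposition of `−½D²`. Bray–Curtis matrices are not
Euclidean-embeddable in general, so negative eigenvalues occur: they are
reported, but excluded from scores, proportion denominators, and inertia
decompositions. A Lingoes correction is available behind a flag and off by
default, matching the dominant convention of the ordination tools this
field uses. Eigenvector sign is arbitrary; each axis is oriented so its
largest-magnitude loading is positive.

**dbRDA.** The positive-axis PCO scores are (optionally) residualised on a
centred conditioning design, then projected onto the span of the
(equally residualised, centred) predictors. Inertia decomposes exactly as
conditional + constrained + residual = total positive inertia.
`pseudo-F = (constrained/q) / (residual/(n−q−c−1))` with `q` predictor and
`c` condition degrees of freedom. The permutation test permutes rows of the
conditioned response scores with the predictors fixed (reduced-model
permutation, 999 permutations by default) and reports
`p = (1 + #{F* ≥ F}) / (1 + B)`, so p can never be 0. Rank-deficient
designs raise an error naming the aliased columns (column-pivoted QR).
Interactions are first-class: design terms are either column names or
`a:b` products.

## Nontrivial-axis diagnostics

Four methods, all applied to positive eigenvalues only:

1. **Broken stick**: `b_k = (1/p) Σ_{i=k..p} 1/i`; an axis is flagged while
   its proportion of positive inertia strictly exceeds `b_k`, stopping at
   the first failure (leading-block reading — later ranks are noise by
   assumption once an axis fails).
2. **Bootstrap**: sites resampled with replacement, B = 1000 by default;
   95% percentile CIs per ranked eigenvalue; flags continue while
   successive CIs are disjoint and stop at the first overlap.
3. **Permutation null**: each taxon column permuted independently
   (destroying inter-taxon correlation, preserving each column's values),
   B = 999; observed eigenvalues above the 97.5% null bound are flagged.
4. **Relative percent**: `r_k = 100 λ_k / Σ_{i≥k} λ_i`, exported as scree
   data; the automated proxy flags axes above the equal-share line of the
   remaining ranks.

Percentile (2.5/97.5) intervals were chosen for both resampling methods as
the simplest definition of a 95% interval. Both routines canonicalise row
order (lexicographic) before drawing replicates, so results are invariant
to the caller's row ordering at a fixed seed. The consensus rule defaults
to `majority` (≥ 2 of 4 methods) and returns a leading contiguous block;
the four methods are usually inspected jointly and informally, so the
automated rule is user-overridable.

## Piecewise structural equations and the tests

Each child node's equation regresses it on design terms representing its
parents. Terms default to parent main effects but can be overridden per
node — the functional form (interactions, derived columns such as a
seasonal sinusoid or an exposure term) is part of the causal hypothesis.
Univariate equations use OLS (statsmodels) with a sequential ANOVA
decomposition and added-variable (partial regression) exports; the
community node is fitted by dbRDA.

**Local conditional-independence tests.** For two environmental variables,
a nested-model F test: the response is the variable later in the
topological order (declared order breaks ties; conditional independence is
symmetric but an F test needs a response), the conditioning design is the
response's own equation terms — retaining their functional form, as in
piecewise-SEM practice — plus main effects for any conditioning variables
not among the response's parents, and the other variable is added. If the
community is involved, the other variable is tested by dbRDA with the
conditioning design as `condition`. Degenerate cases (response constant
given the conditioning set, added variable aliased) return p = 1 with a
warning rather than failing: a variable that cannot add information cannot
reject an independence claim.

**Global test.** Fisher's C = −2 Σ ln pᵢ over the k testable statements,
compared to chi-square with 2k df. Statements referencing variables with no
data column are itemised as untestable and excluded from k, never silently
dropped. No multiple-testing correction is applied to the local tests; the
global C is the aggregation device. Analytic p-values are clamped at
1e-300 with a warning to keep C finite. α defaults to 0.05 everywhere.

**Intervention prediction.** `do(V = v)` fixes the intervened columns,
severs their incoming arrows by construction, and evaluates every fitted
downstream equation in topological order on the propagated parent values,
recomputing derived design columns at each step. The community response is
returned as the predicted shift in fitted PCO scores (difference of the
dbRDA linear predictor between intervened and observed designs). An empty
intervention reproduces the observational fitted values. Predicting from a
model the tests did not accept triggers a warning, not an error.

**Model revision** is user-driven: `diagram_diff` reports arrow changes
between versions, and a generic k-fold predictive-R² utility is provided
as one interpretation of cross-validated model checking; no automated
structure search is attempted, since arrow choices belong to domain
knowledge.

## Mantel correlogram

Pair distances along the stream are binned into equal-width classes
(Sturges' rule on the pair count by default). Per class, the Mantel
correlation between community dissimilarity and the binary within-class
indicator, with a two-sided permutation test of site labels. Classes with
fewer than two pairs are merged into a neighbour with a warning. A
progressive correction (class k's p multiplied by k, capped at 1,
monotonised) is reported alongside the raw p-values; whether to correct
across classes is left to the reader, so both are emitted.

## Biotic indices

Shannon uses natural log (the dominant ecological convention). EPT metrics
count Ephemeroptera/Plecoptera/Trichoptera taxa and individuals; taxa with
no annotation are treated as `other` with a warning. SIGNAL defaults to the
presence-based unweighted mean of grades over taxa present, with an
abundance-weighted option; grade tables vary by jurisdiction and are
user-supplied input, never bundled.

## The synthetic river

The generator emulates the target study design: `n_sites = 20` sites over a
20 km reach with a discharge point at 10 km, sampled on `n_times = 8`
occasions (160 rows), 20 taxa. Its causal diagram: `distance → effluent`
(upstream 1 / downstream 0); `time, distance, effluent, load1 → nutrient`;
`nutrient, distance → COMMUNITY`; `load1 <-> load2` via the latent plant
operation.

- Seasonality is a sinusoid over the time index (one cycle per series) —
  the simplest stand-in for seasonal forcing.
- The nutrient plume is `β · load1 · exp(−Δd/decay) ·` (downstream), with
  β = 0.8, decay length 5 km, against noise SD 0.3 — a discharge signal a
  field study would regard as strong but not caricatured.
- The latent plant operation loads on both discharge variables with
  loading 0.7 over noise SD 0.3 (load correlation ≈ 0.8).
- Taxa respond log-linearly to the z-scored nutrient and distance
  gradients (coefficient SDs 0.6 and 0.4), with Poisson counts by default
  and a negative-binomial option. The log-linear choice keeps the
  community–environment relation within the model family the pipeline
  fits, so recovery tests are fair tests of the machinery rather than of
  functional-form misspecification.
- Every row is treated as its own sampling moment: the latent and the
  loads are drawn per row, not per occasion. Sharing one realised load
  across all sites of an occasion would make load a within-dataset
  function of the time index (pseudo-replication) and invalidate the very
  independencies the generator declares.
- A single RNG keyed by `seed` draws, in order: latent plant operation,
  load noise (×2), nutrient noise, taxon baselines and gradient
  coefficients, counts. Same seed, bit-identical output.

The generated site table includes the derived columns `season` and
`exposure` with recipes for recomputing them, because the nutrient
equation is linear in *those* terms: local tests conditioning on
nutrient's parents through these terms are exactly specified, while the
community's conditioning design uses a second-order trend surface in
(nutrient, distance) to absorb the curvature that the
counts → Bray–Curtis → embedding map introduces.

What the generator does **not** emulate: hydrological realism, multiple
discharge points, species interactions, temporal autocorrelation of the
environment, and observation error on the environmental variables. Passing
recovery tests therefore demonstrate that the machinery is correct and
calibrated under its stated assumptions, not that those assumptions hold
in any particular river.

## Problem sizes and calibration outcomes checked

The verification suite (tests and `scripts/acceptance.py`) uses: exhaustive
DAG enumeration up to 5 nodes as edge subsets of the complete DAG in a
fixed topological order (every DAG is a relabelling of one of these), plus
200 random 6-node DAGs; 1000 replicates for the nested-F type-I-error
check (n = 100 per replicate, target 5%); 200 replicates at B = 199 for
the permutation-null eigenvalue calibration (target 2.5% per-rank
exceedance); and 100 synthetic-river replicates for structure recovery
(generating diagram accepted, effluent→nutrient-deleted diagram rejected).
These sizes give Monte-Carlo standard errors comfortably below the margins
asserted, and the suites compute every number they assert at run time.
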