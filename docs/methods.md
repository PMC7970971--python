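# Methods

## Model and assumptions

The package models a microbial community as a causal Bayesian network: a
DAG G over random variables X₁…X_n (relative abundances, optionally plus
an outcome variable), with the joint density factorizing as
P(V) = Π_i P(X_i | Pa(X_i)). Three assumptions do the heavy lifting:

* **Causal sufficiency** — no hidden confounders. Microbiome data almost
  certainly violate this (host diet, medication, environment); results
  should be read as candidates, with Y-structure legs the most defensible
  edges because their unconfoundedness is implied by the learned pattern
  itself.
* **Faithfulness** — every conditional independence in the data reflects
  d-separation in G. Near-canceling paths violate this in finite samples
  and are a real error source in dense networks (see limitations).
* **Linear-Gaussian mechanisms** — each variable is a linear function of
  its parents plus Gaussian noise. This licenses Fisher-z partial
  correlation as the conditional-independence test and makes every total
  causal effect a single regression coefficient. Relative abundances are
  used as-is; no compositional (log-ratio) correction is applied, and the
  induced compositional correlations are a known, uncorrected bias. A 0/1
  disease column is treated as numeric in the same machinery — effects on
  it are linear-probability-model slopes, which is why their scale in
  ranked tables is best read comparatively, not as probabilities.

## Structure learning

Skeleton search is PC-stable: at each conditioning-set size ℓ the
adjacency sets are frozen before any deletion, making the surviving
skeleton independent of the column order of the input. An edge {i, j} is
removed as soon as some S ⊆ adj(i)\{j} or adj(j)\{i}, |S| = ℓ, yields
p > α in the Fisher-z test z = √(n−|S|−3)·atanh(r); the first such S is
recorded. Pair sweeps and subset enumeration are ordered by variable
*name*, so the recorded separating sets — not just the skeleton — are
column-permutation invariant.

Collider orientation defaults to a **majority vote**: for each unshielded
triple i – j – k, all subsets of the skeleton neighborhoods of i and of k
are re-tested, and the triple becomes i → j ← k iff j appears in fewer
than half of the separating sets found. With a perfect independence
oracle the vote is unanimous in either direction, so the rule coincides
with the classical recorded-sepset rule (also provided, as
`v_structure_rule="sepset"`); on finite data it is substantially more
robust — in the synthetic benchmark it lifts directed-edge precision at
(9 nodes, 10 edges) from ≈0.73 to ≈0.87 at no recall cost. Orientation is
completed by the three Meek rules swept to a fixed point.

Finite-sample CI answers can be mutually inconsistent, so both
orientation stages refuse (deterministically, keeping earlier decisions)
any orientation that would close a directed cycle or reverse an existing
edge, preserving the acyclicity invariant of the graph type.

## Effects and influence

`adjustment_effect` regresses the effect variable on the cause plus the
cause's parents (intercept always included) and returns the cause's
coefficient; it returns exactly 0 when the effect is a parent of the
cause or when no directed path links them. On CPDAGs,
`causal_effect` enumerates every locally valid parent set — each subset T
of the cause's undirected neighbors such that T ∪ Pa(cause) introduces no
new collider at the cause — and summarizes the resulting multiset. The
default summary is the minimum absolute value (with its sign), a
conservative lower bound: note this means a lone undirected edge reports
effect 0, by construction. `mean` is available, and the full multiset can
be requested. The all-pairs matrix is computed with one least-squares
solve per (cause, parent set) against all columns simultaneously.

Causal influence is CI(B_i) = Σ_{j≠i} |C(B_i, B_j)| over **all** pairs,
so indirect effects count and opposite-signed effects cannot cancel.
Sinks therefore score exactly 0. Ranking ties break by the input column
order.

## Outcome analysis

Context embedding concatenates cohorts (variable intersection, duplicate
sample ids rejected) and appends the outcome column; binary outcomes must
be coded {0, 1}, ordinal/continuous severities pass through. Per-effect
bootstrap p-values are two-sided sign-stability:
p = 2·min(#{effect ≤ 0}, #{effect ≥ 0})/B over B row-resamples with
structure relearned each time, clipped to [1/B, 1]; replicates whose
structure lacks a directed cause→outcome path contribute 0. Y-structures
are searched among fully directed edges, but undirected edges count as
adjacency for the non-adjacency conditions — the conservative choice,
suppressing legs whose unconfoundedness the data leave ambiguous.

## Resampling validation

Bootstrap edge confidence is adjacency-based (direction-agnostic) because
orientations flip across replicates even when the adjacency is stable; a
per-edge directed-orientation frequency is reported separately. The
Gaussian network score is the decomposable ML log-likelihood (per-node
OLS, MLE residual variance floored at 1e−12); CPDAGs are scored through a
consistent extension, and all extensions of one CPDAG share the score.
The permutation test permutes each variable's values independently across
samples — destroying all inter-variable dependence while keeping
marginals — relearns and rescores N times; p is the fraction of null
networks scoring above the observed one. The sensitivity scan grows a
perturbation in `step`-percent increments (added synthetic samples drawn
per-sample-mean/sd and clipped at 0; deleted rows; or rows re-drawn from
column empirical distributions) until the relearned network first drops a
baseline edge with bootstrap confidence above 0.5.

## Synthetic generator

`random_dag` draws a uniform topological order, chooses the requested
number of forward edges uniformly, gives each a coefficient with
magnitude Uniform[0.1, 1] and random sign, and unit Gaussian node noise;
`sample_from_dag` is ancestral sampling in topological order. These
defaults are the benchmark's study conditions: the 0.1 floor keeps every
edge in principle detectable, unit noise puts typical edge signal-to-noise
near 1. The generator emulates none of the features that make real
abundance data hard — compositional closure, zero inflation,
non-Gaussianity, uneven sequencing depth — so green synthetic results
demonstrate correctness of the machinery under its own assumptions, not
performance on real microbiomes.

Ground-truth total effects are path-products summed over all directed
paths (computed by accumulating powers of the weighted adjacency matrix).
Recovery scoring defaults to correctly-directed-edge counts (undirected
inferred edges score as FN); because only compelled edges are directed in
a CPDAG, even a perfect learner's recall is capped at the compelled-edge
fraction (measured ≈0.63 for 9-node/10-edge graphs). `cpdag` scoring
(against the true equivalence-class representative, where a perfect
learner scores 1) and `adjacency` scoring are available. Accuracy is the
threat score TP/(TP+FP+FN), reported in percent; for any P, R it equals
P·R/(P+R−P·R) = F1/(2−F1).

## Numerical choices

* Partial correlations come from the inverse of the relevant correlation
  submatrix; near-singular submatrices fall back to a pseudo-inverse with
  rcond 1e−10, and |r| is clipped to 1−1e−12 before atanh (|r| = 1 yields
  p = 0, dependent, rather than an error).
* OLS uses `lstsq`; rank-deficient adjustment designs raise an error
  naming the collinear variables.
* Constant columns are dropped (with a warning) before learning; a
  degenerate bootstrap replicate that loses the cause or outcome column
  contributes a zero effect.
* All tie-breaks (orientation conflicts, extension choices, ranking ties)
  are deterministic; resampling uses a single seeded generator per call.

## Problem sizes used in tests

The test suite exercises exhaustive graph enumerations up to 4 nodes
(543 DAGs) with seeded random samples of 5–6-node DAGs standing in for
the larger spaces, benchmark runs at m = 1000 with 100 repetitions per
configuration, large-sample effect checks at m = 50,000, and permutation
calibration at N = 100 over 50 datasets. These sizes were chosen so the
full suite completes in a few minutes while keeping every statistical
check well-powered.

## Known limitations

* Compositionality is uncorrected by design; log-ratio or multinomial
  approaches are deliberately out of scope.
* No latent-confounder search (no FCI/PAG semantics) and no discrete or
  nonparametric CI tests.
* Dense networks with weak edges (|coef| near 0.1 at m = 1000) sit near
  the detection boundary of the Fisher-z test; skeleton recall degrades
  accordingly, and influence rankings inherit that error.
* The min-abs CPDAG summary is conservative: genuinely causal but
  orientation-ambiguous relationships can report effect 0.
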