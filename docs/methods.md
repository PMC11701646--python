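# Methods

This note records the models, the defaults and the design decisions behind
assocnet, in the package's own words.  It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Score model

A confidence score is the estimated probability that a postulated
association is real given the evidence.  Evidence is split into seven
channels assumed independent; the combined score is a noisy-OR of the
channel subscores after removing a prior *p* ∈ [0, 1) (the probability
that a random pair is associated) and restoring it afterwards:

    sᵢ′ = max(0, (sᵢ − p)/(1 − p));   S = p + (1 − p)(1 − ∏(1 − sᵢ′)).

Consequences used as invariants: S is permutation-invariant, monotone
non-decreasing in every channel, bounded by [p, 1], reduces to the plain
complement-product at p = 0 (hence S ≥ max sᵢ), and evidence at or below
the prior contributes nothing.  The prior defaults to 0.0 and is exposed as
configuration; no particular production value is asserted.  Recomputing
with a channel subset drops edges whose only evidence was disabled (their
recombined score equals the prior).

Three network modes exist: functional (the superset), physical and
regulatory.  The specific modes must be contained in the functional network
with equal-or-higher scores; `check_mode_consistency` reports every pair
violating that, comparing the best direction of a regulatory edge against
the undirected functional score with a 1e-12 float tolerance.

Regulatory edges are ordered pairs with an action type from a closed
taxonomy (regulation with positive/negative signed subtypes, regulation of
gene expression, regulation of degradation, catalysis of post-translational
modifications with six subtypes) and one confidence per direction.  A sign
is only legal on the signed-regulation subtypes.  One record per (ordered
pair, action type) is allowed; no merged symmetric score is invented.

Score dialects: unit floats in [0, 1] or "millipoint" integers 0–1000;
`auto` infers millipoint iff any value exceeds 1.  Unit-scale writing uses
shortest round-trip float repr (lossless); millipoint quantizes to 1/1000.
Self-edges are rejected at parse time; node identifiers are opaque.

## Overrepresentation analysis

The test statistic is the one-sided hypergeometric tail P(X ≥ k) for an
overlap of k between a query of size n and a term of effective size m
(members ∩ background) in a background of size N, computed through the
survival function of `scipy.stats.hypergeom`; the correction is
Benjamini–Hochberg, applied within each category over the *tested* terms
only.  Expected overlap is n·m/N; strength is log₁₀(observed/expected)
(undefined, reported as NaN, at zero overlap); signal is the weighted
harmonic mean of the observed/expected ratio and −log₁₀(max(FDR, floor)),
with defaults w_ratio = w_fdr = 1, log base 10 and floor 1e-15 — declared
as this package's defaults, not asserted as anyone's production values.
Signal is defined as 0 when either component carries no evidence.

### Viability filter

A term of effective size m is *viable* iff its best-case p-value,
p_min(m) = P(X ≥ min(m, n)), satisfies p_min(m) ≤ α — the loosest possible
BH rejection level.  Non-viable terms are not tested and do not count
toward the correction.  Because a BH q-value is never below its raw
p-value, an excluded term (p ≥ p_min > α) could never have been rejected:
the filter is safe.  p_min is decreasing in m up to m = n and increasing
beyond, so the viable sizes form a contiguous window [m_lo, m_hi]; a term
covering the whole background (m = N) has p_min = 1 and is never viable.

The power guarantee deserves precision.  For terms that are significant in
the unfiltered analysis, filtering can only shrink their q-values: all
excluded p-values exceed α, so ranks below the rejection threshold are
unchanged while the test count shrinks, scaling the minimizing candidate by
T′/T ≤ 1.  For *never-significant* terms the pointwise claim is false —
excluding a term whose p-value is smaller than a tested term's changes that
term's BH factor from T/rank to (T−1)/(rank−1), which is larger.  The test
suite and the acceptance script therefore check exactly the meaningful
property: no excluded term is significant unfiltered, and every
unfiltered-significant term's q-value does not increase.

A stricter α/T-style bound (`ViabilityBound.ALPHA_OVER_T`) is available as
a documented switch but is off by default, since a count-dependent bound
can exclude terms the step-up procedure would have rejected.

### Redundancy filtering and grouping

The redundancy filter walks rows in ascending p-value order (ties: larger
effective term, then lexicographic id, for determinism) and keeps a row iff
its Jaccard similarity to every already-kept row is ≤ the cutoff; it is
idempotent on its own kept set.  Similarity grouping is average-linkage
agglomerative clustering at distance 1 − Jaccard, cutting at distance
1 − cutoff; by induction over merges, every group's average pairwise
similarity is at least the cutoff.  Groups are ordered by their maximum
signal, terms within a group by individual signal; the dot-plot table
assigns y-ranks in that order, with FDR as the color key and observed count
as the size key.

## Clustering

"Most probable path" is formalized as the maximum product of edge
confidences, i.e. shortest paths under edge length −ln(score) (natural log;
any base is monotone-equivalent).  Score-1 edges get a 1e-15 floor length
so sparse shortest-path routines keep them.

k-medoids runs per connected component.  The budget k is spread by giving
every component one cluster and granting each extra to the component
maximizing size/granted (ties: larger component first, then smallest member
id) — the largest components are divided first; an allocation can never
exceed a component's size.  Within a component: seeded random first medoid,
deterministic farthest-point completion, then PAM-style alternation of
nearest-medoid assignment and exact medoid update until stable.  When
k < number of components (allowed but degenerate), the k−1 largest
components stand alone and the remainder share the last cluster; the
no-cluster-spans-components invariant is only promised for k ≥ component
count.

MCL: self-loop weight is the node's maximum incident score (1.0 for
isolated nodes), the matrix is column-normalized, and iterations alternate
expansion (matrix squaring) with inflation (elementwise power r > 1,
pruning entries < 1e-5, renormalization) until the matrix moves < 1e-8 in
max norm or 100 iterations (then flagged non-converged).  Clusters are the
connected components of the symmetrized support of the limit matrix.
Expansion power 2, the self-loop policy and the pruning threshold follow
common MCL practice; they are this package's defaults, not a reproduction
of any binary's internals.  Cluster ids are contiguous from 1, ordered by
size then smallest member, making outputs byte-reproducible.

Cluster naming runs enrichment of each cluster against the network's node
set as background; terms with FDR ≤ α are ranked by signal with the
category priority list (default: Gene Ontology Biological Process first) as
tie layer, and the top three distinct descriptions fill
primary/secondary/tertiary.  Single-gene clusters and clusters with no
significant term fall back to canonical gene names (comma-joined for
multi-gene sets).

## Calibration

Calibration maps a unitless raw evidence score to the probability that the
pair is a true interaction, per benchmark category.  Labelling: gold pairs
are positives; negatives are a seeded uniform sample of the *scored*
non-positive pairs at `negative_ratio` per positive (default 10).  Sampling
from scored pairs, rather than all universe pairs, is deliberate: an
unscored pair has no raw score and cannot contribute a precision point.
Unknown pairs are excluded from fitting but still receive calibrated
scores.  Directed pairs are benchmarked as ordered pairs.

Precision is estimated in sliding windows (default 100 wide, step 50) over
the label sequence sorted by raw score descending, each window contributing
(median raw, fraction positive); a window wider than the data collapses to
one whole-set point.  The curve is the isotonic least-squares fit of those
points (pool-adjacent-violators, implemented in-package; duplicate raw
knots merged by averaging), and application is linear interpolation clamped
to the end values — monotone by construction.  Precision itself, not a
likelihood-ratio transform, is the calibrated quantity: with well-mixed
windows it estimates exactly P(positive | raw), which is why the synthetic
Beta(5,2)/Beta(2,5) benchmark can compare the curve against the analytic
mixture posterior.

## Synthetic data

One seed drives everything through named substreams (network / terms /
query / gold), so each fixture is a pure function of its configuration and
fixtures drawn from one seed stay independent.

* **Planted-partition networks** (default 3 × 15 nodes, p_in = 0.6,
  p_out = 0.05; within-module scores ~ Beta(8,2), between ~ Beta(2,8); the
  cluster-recovery benchmark uses fixed scores 0.9/0.6): a drawn combined
  score is decomposed onto two random channels by inverting the zero-prior
  noisy-OR with a random mixing fraction u ∈ (0.2, 0.8), and the stored
  combined score is recomputed from the channels so recombination matches
  bit-for-bit.
* **Term collections**: planted terms are module memberships (or any
  designated sets); noise terms (default 200–500) draw sizes from a
  geometric distribution (floor 1), deliberately rich in single-gene terms
  to exercise the viability filter.
* **Queries**: (1 − c) of a planted term's size from its members, c from
  the rest of the universe (c = 0.2 in the recovery benchmark), rounded
  deterministically.
* **Gold standards**: distinct ordered non-self pairs; positives' raw
  scores ~ Beta(5, 2), negatives ~ Beta(2, 5) — overlapping but separable —
  with the implied analytic posterior returned for recovery tests; action
  types uniform over the taxonomy, signs tied to the signed subtypes.

What the generators do *not* emulate: real score distributions and their
channel correlations, literature co-mention statistics, hub-dominated
degree distributions, ontology hierarchies (parent–child term nesting), or
identifier namespaces.  Passing recovery tests therefore demonstrates the
correctness and power of the machinery under clean, well-separated
conditions, not performance on real proteome-scale data.

## Problem sizes and numerical choices

The standard study conditions, used by both the test suite and the
acceptance script: exact-oracle enumeration of the hypergeometric tail over
every parameter combination with N ≤ 12; 1,000 random p-vectors (lengths
1–200) against a quadratic-time BH reference; 200 random collections
(N = 100, n ≤ 20) for filter safety/power; 100 seeds of the planted-term
fixture (1 planted 20-gene term, 500 noise terms, contamination 0.2);
50 seeds of the 3 × 15 planted-partition MCL benchmark; 100 disconnected
k-medoids fixtures; one 10,000-prediction calibration benchmark (window
100, step 50); 10,000 random score-combination property trials; 50
calibrate-then-check consistency fixtures.

Tolerances: 1e-12 for oracle agreement, 1e-9 for round-trips and path
distances, 1e-8 MCL convergence, 1e-15 anti-flicker epsilon in PAV pooling.
Ties are broken deterministically everywhere (documented per routine), so
identical inputs, options and seeds give byte-identical outputs.

## Known limitations

* BH is applied within each category independently; no cross-category
  correction is attempted.
* Only overrepresentation analysis is implemented; ranked-list enrichment,
  ontology-aware corrections and GO slimming are out of scope, as is
  computing channel subscores from primary data.
* The MCL attractor interpretation (connected components of the limit
  support) can, in principle, attach a node to one cluster where overlap
  interpretations would allow several; overlapping clusters are not
  produced.
* Calibration assumes the sliding-window precision is a consistent local
  estimate of P(positive | raw); with very few labelled predictions the
  curve degenerates to a single overall-precision point.
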