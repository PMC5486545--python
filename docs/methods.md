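# Methods

## The model

A study is a carrier-by-feature matrix `C = (c_ij)`: `n` carriers
(species or higher taxa) in rows, `m` features in columns.  Entries
live in one of three fields, declared by a `field_tag` because the
central quantity — rank — depends on the field:

| tag       | entries              | rank arithmetic                          |
|-----------|----------------------|------------------------------------------|
| `real`    | measurements         | singular values over a relative tolerance |
| `integer` | counts / state codes | exact elimination over the rationals      |
| `gf2`     | presence/absence     | exact elimination modulo 2                |

The rank `r` is the minimal number of terms in `C = Σ a^ν ⊗ b^ν`.
Each `b^ν` is an independent feature combination (a character
cluster); each `a^ν` the per-carrier factors.  For 0/1 data the GF(2)
rank can be strictly below the rational rank (the suite ships a 3×3
witness), which is why the field is an explicit input and every report
names it.

### Numerical rank and ε-rank

Real-field rank counts singular values above `tol · σ_max` with
`tol = 1e-8` by default — machine-precision safe for desk-scale
matrices; the tolerance is a parameter everywhere it matters.  The
ε-rank is the minimal rank among matrices strictly within Frobenius
distance ε; by Eckart–Young this is the smallest `r` whose trailing
singular values satisfy `Σ_{k>r} σ_k² < ε²`.  The inequality is
strict: a tail exactly at the boundary keeps the higher rank.

### Canonical decompositions

Minimal decompositions are not unique, so outputs are canonicalized
for reproducibility.  Real field: the SVD form `a^ν = σ_ν u_ν`,
`b^ν = v_ν` in descending `σ`, sign fixed so each `b^ν`'s dominant
entry is positive.  Exact fields: when the nonzero columns partition
into proportionality classes and the class count equals the rank, one
term per class is emitted (the representative column, leading
coefficient normalized to 1, against the vector of per-column
multipliers).  This feature-disjoint form is the one in which overlay
matrices are naturally written — e.g. the 6×4 two-syndrome example
decomposes exactly into `(1,1,1,2,2,2) ⊗ (1,1,0,0) +
(1,2,3,1,2,3) ⊗ (0,0,1,1)` — and it degenerates gracefully: for a
fully proportional matrix it gives the single printed term, for a
diagonal matrix the singleton terms.  When the classes do not reach
minimality (a column that is a non-trivial combination of others),
the fallback is column-pivoted outer-product peeling with first-pivot
tie-breaking, which always terminates in exactly `rank` steps with
echelon-structured (hence independent) factor families.  Cluster
lists are ordered by decreasing carrier-factor norm, ties by first
loaded feature.

Representative features of a cluster are those with nonzero loading
(exact fields) or loading at least `rep_frac = 0.1` of the dominant
magnitude (real field); the fraction is a parameter.

### Missing data

The algebraic operations refuse incomplete matrices and name the
offending cells; `complete_column_subset()` is the sanctioned
restriction to fully observed features.  No imputation — the
geometric view is the home for partial observations: a missing entry
simply leaves the taxon's section undefined at that feature.

## Frequencies and independence

For binary features, three normalization conventions are implemented
because the natural definitions disagree and the package takes no side:

- `carrier_fraction` (default): `p_{j1…js}` = fraction of carriers
  possessing all the listed features.  This is the convention under
  which the standard worked examples (identical vs disjoint carriers)
  come out as printed, and the one the independence test reads most
  naturally.
- `total_normalized`: counts divided by the total number of feature
  occurrences `Σ_ℓ r_ℓ`, the textbook marginal formula.  Its order-1
  vector sums to one; higher-order tables are counts over the same
  denominator.
- `distributional`: each order-`s` table normalized to unit mass; the
  marginals are *defined* as the row sums of the pairwise table, so
  the row-sum consistency property holds by construction.  This is
  the only reading under which a symmetric joint table can have its
  row sums equal to the marginals.

All tables are exact `Fraction`s; the independence test
(`p_{j1…js} = Π p_{jk}` entrywise within `tol`, default exact) and
its reported maximum deviation are therefore free of float noise.

The co-occurrence matrix `P = C·Cᵀ/Z` with `Z` the total mass of
`C·Cᵀ` is formed over the rationals (or floats for real input) — the
normalization by `Z` leaves GF(2) — and its rank preservation
(`rank P = rank C`) is a statement over the rationals/reals.  The
property test draws entry palettes per field (floats, small integers,
bits) and compares rational/real ranks on both sides.  `Z = 0` is an
explicit error, never a NaN.

## Tensor rank

Order-`s` frequency tensors can hide dependencies invisible at order
2, so a rank oracle for small tensors is included.  Tensor rank is
NP-hard and the border rank (the infimum over neighbourhoods) can be
strictly smaller than the rank, so the module is split into two
honest regimes:

- `exact_small` (≤ 16 entries, rank ≤ 4): over GF(2) the set of
  rank-one tensors is finite and the search is exhaustive.  Over the
  rationals, "rank ≤ r" is decided algebraically: the scaling freedom
  of each term is spent by normalizing leading entries, the finitely
  many leading-zero patterns are enumerated, and sympy decides each
  polynomial system — a trivial Gröbner basis is a Nullstellensatz
  certificate that no decomposition exists even over ℂ, while an
  explicit solution is a witness.  A tensor whose nonzero-entry count
  reaches the candidate rank gets a constructive single-entry-term
  witness without touching the solver.  A branch with provably
  complex-only solutions raises rather than guessing (rank over ℝ
  and ℂ can differ); none of the shipped fixtures hits this.
- `als_upper_bound`: alternating least squares CP fits with seeded
  restarts; reports the smallest `r ≤ max_rank` whose relative
  residual falls below tolerance.  Documented and flagged as an upper
  bound only; border rank is never computed exactly (residual-vs-rank
  curves are the only diagnostic).

The entry and rank caps exist because the branch count is
combinatorial; they keep the oracle honest and fast rather than
pretending to scale.

## The section model

`FeatureSpace` holds the base (ordered feature ids), finite fibers
(ordered value tuples — order fixes the lexicographic enumeration of
completions), and optionally an explicit finite list of admissible
global sections.  Constraints-as-enumeration was a deliberate choice:
the spaces of interest are finite and small, figures and fixtures
enumerate their sections, and predicate-based constraints would buy
generality the rest of the package cannot yet consume.  A "range" of
values is represented as an explicit finite subset of the fiber.

Sections compare by domain and values; the label (taxon name) is
metadata.  `extensions` returns admissible completions in admissible
order (or all combinatorial completions, lexicographically, when
unconstrained), so outputs are deterministic.  `apomorphies` reports,
for a section with at least two extensions, the outside features
attaining at least two values — the distinctions available below that
taxon.

Innovations: `extend_fiber` never invalidates existing sections and
carries constraints over unchanged.  `add_feature` makes old
constraints non-global; with a caller-supplied default each
admissible section is completed explicitly, otherwise the constraint
set is dropped with a logged warning — old constraints are never
silently broadcast over the new fiber, since nothing says every new
value is admissible.  `amalgamate` replaces two features by one via a
value map; the new fiber is exactly the image of the map, value pairs
outside its domain lose the feature on transport (reported), and for
a total injective map the transport is a bijection on sections
defined at both features.

Group actions are per-(element, feature) value bijections with an
explicit composition table; elements absent from the action table act
trivially, which covers the common case of a group fixing most
fibers.  `verify_action` checks the table axioms (closure, identity,
inverses, associativity), identity triviality, bijectivity, and the
action law `(g∘h)(x) = g(h(x))`, returning violations as data.  Orbit
equivalence requires equal domains — cross-domain gestalt comparison
is deliberately out of scope, as there is no canonical way to compare
a value at a feature one pattern lacks.  The shipped
finite-chain-translation action is intentionally broken: a shift on
an ordered fiber with ends clamps at the last value, so bijectivity
and the claimed involution law fail — everywhere except at the
clamped end itself, which is the boundary effect the fixture exists
to exhibit.

## Cladistic vs functional structure

`is_cladistic` uses rooted character compatibility with state 0
ancestral: every pair of feature support sets nested or disjoint
(laminar).  The strict staircase is the special case where supports
form a chain; when the check passes, carrier order (by number of
possessed features) and feature order (by decreasing support) exhibit
the staircase for ladder-shaped inputs, and the laminar family is
exportable as a rooted Newick tree.  Violating pairs are reported as
data.  The criterion is invariant under row/column permutation by
construction.

`functional_clusters` is label-free on principle: state codes are
mere labels, so two features are grouped iff they induce the same
partition of the carriers.  Searching relabelings to minimize numeric
rank would be combinatorial; instead the matrix is canonically
relabeled (codes 1, 2, … by first appearance down each column, which
makes co-clustered columns identical) and the real rank of that
relabeled matrix is reported alongside.  On a full-factorial design
with `k` clusters this rank equals `k` exactly.

`rank_signature`'s verdict (full rank → "cladistic-like", at or below
half of `min(n, m)` → "functional-like", else "mixed") is a reporting
convention, not a theorem; the threshold is a parameter and the
report carries the raw numbers.  Pairwise analysis can miss
higher-order dependence — the tensor-rank oracle is the
cross-reference for that.

## Synthetic generators

The generators are pure functions of (spec, seed) and exist so every
behaviour is testable without external data:

- `gen_cladistic(n)`: the n×n staircase (carrier `i` possesses
  features `1..i`) — nested synapomorphies, maximal rank, the ladder
  tree.
- `gen_functional`: overlay of perfectly correlated feature blocks;
  full factorial of cluster states by default (every syndrome
  combination realized, matching the printed 6×4 example), or a
  seeded sampled design.
- `gen_noisy`: entrywise Gaussian jitter (real) or independent bit
  flips (gf2) — the minimal standard noise models; the magnitude
  actually applied is returned with the matrix.
- `gen_space`: seeded random admissible subsets, constructed so both
  canonical extension behaviours (a section with ≥ 2 extensions, a
  section with none) are guaranteed whenever `2 ≤ admissible < all`,
  and refused with an explanation otherwise.

What the generators emulate is correlation *structure*: nesting,
block correlation, noise.  They do not emulate homoplasy
(convergence/reversal), rate variation, or missing-data patterns of
real morphological datasets, so green tests certify the algebra and
combinatorics, not robustness to conflicting characters — conflict
handling beyond reporting laminarity violations is out of scope.

## Problem sizes and determinism

Everything here is desk-scale by design: the worked examples are at
most 6×5, property checks run on hundreds of seeded random matrices
up to 8×8, the adjunction check enumerates all fiber profiles with
≤ 4 features and ≤ 3 values, and the exact tensor oracle is capped at
16 entries.  Every stochastic routine takes an explicit seed; writers
emit stable key order and fixed formatting, so reports are
byte-reproducible.

## Known limitations

- Exact tensor rank over ℚ relies on sympy's solver finding explicit
  real witnesses; systems whose solutions exist only over ℂ (or whose
  realness sympy cannot decide) raise instead of answering.
- NEXUS support covers `DATATYPE=STANDARD` with single-character
  symbols and codes 0–9 on output; PHYLIP/TNT dialects are not
  implemented.
- Constraint sets are explicit enumerations; predicate constraints
  and interval ("range") fibers are future work.
- No statistical phylogenetic inference, no parsimony search, no
  genotype–phenotype modeling: the package quantifies dependence
  structure, it does not infer trees from conflicting data.
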