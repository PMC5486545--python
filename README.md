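# morphospace

Algebraic and geometric analysis of dependencies between morphological
characters.

In biological classification a character is a feature of a taxon whose
state distinguishes it from other taxa — but characters are not
independent: structural constraints, developmental pathways and
functional syndromes correlate them. `morphospace` makes those
dependencies computable for the people who work with character
matrices (systematists, paleontologists, morphometricians), in two
complementary pictures:

**Algebraic.** A study is a carrier-by-feature matrix
`C = (c_ij)` — `n` carriers (species or higher taxa) in the rows, `m`
features in the columns, with real measurements, integer codes, or 0/1
presence–absence.  The minimal representation

    C = Σ_{ν=1..r} a^ν ⊗ b^ν

as a sum of outer products defines the rank `r`: the number of
independent feature combinations.  Each `b^ν` is a **character
cluster** (one character per cluster suffices for classification) and
`a^ν` its vector of per-carrier factors.  Since measurement error
typically fills the rank to `min(n, m)`, the **ε-rank** asks for the
minimal rank among all matrices within Frobenius distance ε.  On the
frequency side, binary features have marginal frequencies `p_j`, joint
frequencies `p_{jk}` (and order-`s` tensors), and the co-occurrence
matrix `P = C·Cᵀ/Z`, whose rank provably equals the rank of `C`;
independence of feature frequencies is exactly the rank-one condition
`p_{j1…js} = p_{j1}·…·p_{js}`.

**Geometric.** The features form a base space `B`; over each feature
`j` sits a finite fiber `F_j` of admissible values.  A taxon is a
partial section `s_i` with `s_i(j) = f_j(i)`; a species is a maximally
extended section.  Restriction moves up the taxonomy, extension moves
down, multiple extensions reveal apomorphies, and constraints (the
admissible feature combinations) decide which sections exist at all.
Innovations are moves on the space itself: enlarging a fiber, adding a
feature, or **amalgamating** two features into one (feathers +
extended forelimbs → wing).  A transformation group acting fiberwise
partitions sections into orbits — **gestalts**, patterns identified up
to the group.

The two pictures meet in classification: a **cladistic** matrix of
nested synapomorphies (its feature support sets form a laminar family)
has maximal rank, while a **functional** matrix of correlated
character blocks has rank equal to its number of syndromes, with the
blocks recoverable label-freely from the induced carrier partitions.

## A worked example

```python
from morphospace import CharacterMatrix, character_clusters, matrix_rank, rank_decompose

overlay = CharacterMatrix(
    [[1, 1, 1, 1], [1, 1, 2, 2], [1, 1, 3, 3],
     [2, 2, 1, 1], [2, 2, 2, 2], [2, 2, 3, 3]],
    feature_ids=["teeth", "feet", "fur", "color"],
    field_tag="integer",
)
print(matrix_rank(overlay))
for a, b in rank_decompose(overlay).terms:
    print([int(x) for x in a], [int(x) for x in b])
for c in character_clusters(overlay):
    print(c.representative_features)
```

prints

```
2
[1, 2, 3, 1, 2, 3] [0, 0, 1, 1]
[1, 1, 1, 2, 2, 2] [1, 1, 0, 0]
['fur', 'color']
['teeth', 'feet']
```

Six taxa (two feeding types crossed with three climate zones) and four
characters carry only **two** independent distinctions.  The exact
decomposition recovers the overlay of the two syndromes — teeth and
feet track the feeding type, fur and color the climate — so one
character per cluster is enough to classify.

More narrative scripts live in `examples/` (frequencies and
independence, ε-rank under measurement noise, taxa as sections with
innovation and amalgamation, cladistic vs functional structure,
gestalt orbits).  A thin CLI mirrors the library:

```sh
morphospace synth cladistic --n 5 | morphospace rank - --field gf2
morphospace freq matrix.csv --pair 1 4
```

## File formats

CSV/TSV (first column carrier id, header row feature ids, `?` for
missing), NEXUS `CHARACTERS`/`DATA` blocks with `DATATYPE=STANDARD`
(symbols map positionally to integer codes, `?` and gaps become
missing), JSON reports under the versioned `morphospace-v1` schema,
and Newick export of the tree implied by a compatible binary matrix.

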