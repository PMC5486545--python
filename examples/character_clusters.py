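"""Find character clusters: independent feature combinations in a matrix.

Builds the 6x4 overlay matrix in which teeth/feet follow the feeding
type (2 states) and fur/color follow the climate zone (3 states), and
recovers the two clusters from the minimal rank decomposition.
"""

from morphospace import CharacterMatrix, character_clusters, matrix_rank, rank_decompose

overlay = CharacterMatrix(
    [
        [1, 1, 1, 1],
        [1, 1, 2, 2],
        [1, 1, 3, 3],
        [2, 2, 1, 1],
        [2, 2, 2, 2],
        [2, 2, 3, 3],
    ],
    carrier_ids=[
        "arctic_carnivore", "temperate_carnivore", "tropical_carnivore",
        "arctic_herbivore", "temperate_herbivore", "tropical_herbivore",
    ],
    feature_ids=["teeth", "feet", "fur", "color"],
    field_tag="integer",
)

print(f"rank = {matrix_rank(overlay)} (of a possible {min(overlay.shape)})")
for term in rank_decompose(overlay).terms:
    a, b = term
    print(f"  carrier factors {[int(x) for x in a]}  x  feature combination {[int(x) for x in b]}")
for cluster in character_clusters(overlay):
    print(f"cluster: {cluster.representative_features}")

# The rank 2 says the four characters carry only two independent
# distinctions; each cluster is one functional syndrome (feeding type,
# climate adaptation), and one character per cluster suffices.
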