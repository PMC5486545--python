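"""Cladistic versus functional matrices: two opposite rank regimes.

The 5x5 staircase of nested synapomorphies has maximal rank and passes
the rooted-compatibility check; the functional overlay has low rank
and splits into perfectly correlated feature blocks.
"""

from morphospace import (
    SynthSpec, cladistic_newick, functional_clusters, gen_cladistic,
    gen_functional, is_cladistic, rank_signature,
)

ladder = gen_cladistic(5)
report = is_cladistic(ladder)
sig = rank_signature(ladder)
print(f"staircase: cladistic={report.is_cladistic}, rank {sig.rank}/{sig.min_dim} -> {sig.verdict}")
print(f"  clade of character_4: {sorted(report.synapomorphies['character_4'])}")
print(f"  tree: {cladistic_newick(report)}")

overlay = gen_functional(SynthSpec(
    kind="functional",
    clusters=[(("teeth", "feet"), 2), (("fur", "color"), 3)],
))
fc = functional_clusters(overlay)
sig = rank_signature(overlay)
print(f"overlay: clusters {fc.clusters}, rank {sig.rank}/{sig.min_dim} -> {sig.verdict}")

# Every nested synapomorphy adds an independent distinction, so the
# cladistic matrix is full rank and implies a ladder tree; the
# functional matrix's rank equals its number of syndromes.
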