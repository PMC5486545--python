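"""Gestalts: patterns identified up to a fiberwise transformation group.

A cyclic relabeling group acts on every fiber; sections that differ
only by a uniform relabeling fall into one orbit (one gestalt).  A
"translation" on a finite vertebral chain, in contrast, fails the
group axioms at the chain's end.
"""

from morphospace import (
    FeatureSpace, Section, chain_translation_action,
    cyclic_relabeling_action, orbit_classes, verify_action,
)

space = FeatureSpace(("a", "b"), {"a": (0, 1), "b": (0, 1)})
G = cyclic_relabeling_action(space)
sections = [
    Section({"a": 0, "b": 0}, label="s1"),
    Section({"a": 1, "b": 1}, label="s2"),
    Section({"a": 0, "b": 1}, label="s3"),
]
for k, cls in enumerate(orbit_classes(sections, G, space), 1):
    print(f"gestalt {k}: {[s.label for s in cls]}")

vertebral = FeatureSpace(("segment",), {"segment": ("v1", "v2", "v3", "v4")})
report = verify_action(chain_translation_action(vertebral), vertebral)
print(f"finite-chain translation valid: {report.ok}")
for v in report.violations:
    print(f"  violation: {v}")

# s1 and s2 are one pattern up to relabeling (one gestalt); s3 is not.
# The vertebral shift clamps at v4, so it is not a bijection and the
# composition law breaks — a translation group needs an infinite chain
# or a closed loop.
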