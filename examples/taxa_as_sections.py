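"""Taxa as partial sections: extension, apomorphies, innovation, amalgamation.

A three-feature space with four admissible feature combinations.  A
higher taxon (partial section) extends to the species compatible with
it; the features on which those species differ are its apomorphies.
Then two features are amalgamated into a new one (feathers + extended
forelimbs -> wing).
"""

from morphospace import (
    ConstraintSet, FeatureSpace, Section,
    amalgamate, apomorphies, extensions,
)

base = ("feathers", "forelimb", "size")
fibers = {
    "feathers": ("absent", "present"),
    "forelimb": ("short", "extended"),
    "size": ("small", "large"),
}
admissible = ConstraintSet([
    Section({"feathers": "absent", "forelimb": "short", "size": "small"}, label="g1"),
    Section({"feathers": "present", "forelimb": "short", "size": "small"}, label="g2"),
    Section({"feathers": "present", "forelimb": "extended", "size": "small"}, label="g3"),
    Section({"feathers": "present", "forelimb": "extended", "size": "large"}, label="g4"),
])
space = FeatureSpace(base, fibers, admissible)

feathered = Section({"feathers": "present"}, label="feathered_taxon")
exts = extensions(feathered, space)
print(f"extensions of the feathered taxon: {[t.label for t in exts]}")
print(f"apomorphies: {apomorphies(feathered, space)}")

bald = Section({"feathers": "absent", "forelimb": "extended"})
print(f"extensions of an impossible combination: {len(extensions(bald, space))}")

am = amalgamate(space, "feathers", "forelimb", "flight_apparatus",
                {("present", "extended"): "wing"})
flyer = am.transport(Section({"feathers": "present", "forelimb": "extended",
                              "size": "large"}, label="proto-bird"))
print(f"transported proto-bird: {flyer.as_dict()}")

# Three species extend the feathered taxon; forelimb and size are the
# features that can distinguish them (apomorphies).  The absent+extended
# combination violates every constraint: no species realizes it.  After
# amalgamation the compatible pair becomes the single feature "wing".
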