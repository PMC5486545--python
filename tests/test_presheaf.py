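import itertools
import logging

import numpy as np
import pytest

from morphospace import (
    CharacterMatrix,
    ConstraintSet,
    FeatureSpace,
    MorphospaceError,
    Section,
    amalgamate,
    apomorphies,
    chain_translation_action,
    cyclic_relabeling_action,
    extensions,
    identity_action,
    innovate,
    orbit_classes,
    restrict,
    sections_from_matrix,
    verify_action,
)


class TestRestrict:
    def test_identity_restriction(self, binary_space):
        s = Section({"a": 0, "b": 1, "c": 0})
        assert restrict(s, s.domain, binary_space) == s

    def test_empty_restriction_is_top_taxon(self):
        s = Section({"a": 0, "b": 1})
        assert restrict(s, set()).domain == frozenset()

    def test_unknown_feature_rejected(self, binary_space):
        with pytest.raises(MorphospaceError, match="unknown"):
            restrict(Section({"a": 0}), {"z"}, binary_space)

    def test_roundtrip_with_every_extension(self, binary_space):
        for dom_size in range(3):
            for dom in itertools.combinations(binary_space.base, dom_size):
                for vals in itertools.product((0, 1), repeat=dom_size):
                    s = Section(dict(zip(dom, vals)))
                    for t in extensions(s, binary_space):
                        assert restrict(t, s.domain) == s


class TestExtensions:
    def test_unconstrained_count_is_fiber_product(self, binary_space):
        s = Section({"a": 0})
        assert len(extensions(s, binary_space)) == 4  # 2 * 2 completions

    def test_constrained_agreeing_sections(self, constrained_space):
        # three of the four admissible sections carry a=0
        exts = extensions(Section({"a": 0}), constrained_space)
        assert len(exts) == 3
        assert [t.label for t in exts] == ["g1", "g2", "g3"]

    def test_conflicting_section_has_no_extension(self, constrained_space):
        exts = extensions(Section({"a": 1, "b": 1}), constrained_space)
        assert exts == []

    def test_monotone_in_admissible_set(self, constrained_space):
        """Enlarging the admissible set never loses extensions."""
        bigger = FeatureSpace(
            constrained_space.base,
            constrained_space.fibers,
            ConstraintSet(
                list(constrained_space.constraints)
                + [Section({"a": 1, "b": 1, "c": 1}, label="g5")]
            ),
        )
        for dom_size in range(3):
            for dom in itertools.combinations(constrained_space.base, dom_size):
                for vals in itertools.product((0, 1), repeat=dom_size):
                    s = Section(dict(zip(dom, vals)))
                    assert set(extensions(s, constrained_space)) <= set(
                        extensions(s, bigger)
                    )

    def test_restricting_widens_extensions(self, constrained_space):
        """A higher taxon (smaller domain) admits at least the extensions
        of any more specific taxon below it."""
        s = Section({"a": 0, "b": 1})
        higher = restrict(s, {"a"})
        assert set(extensions(s, constrained_space)) <= set(
            extensions(higher, constrained_space)
        )


class TestApomorphies:
    def test_single_extension_gives_nothing(self, constrained_space):
        s = Section({"a": 1})  # only g4 extends it
        assert apomorphies(s, constrained_space) == {}

    def test_distinguishing_features_listed(self, constrained_space):
        apo = apomorphies(Section({"a": 0}), constrained_space)
        assert apo == {"b": {0, 1}, "c": {0, 1}}

    def test_unconstrained_binary_feature(self, binary_space):
        apo = apomorphies(Section({"a": 0, "b": 0}), binary_space)
        assert apo == {"c": {0, 1}}


class TestInnovate:
    def test_extend_fiber_multiplies_completions(self, binary_space):
        grown = innovate(binary_space, "extend_fiber", ("c", (2,)))
        s = Section({"a": 0})
        assert len(extensions(s, grown)) == 2 * 3
        assert grown.fibers["c"] == (0, 1, 2)

    def test_extend_fiber_rejects_duplicates(self, binary_space):
        with pytest.raises(MorphospaceError, match="disjoint"):
            innovate(binary_space, "extend_fiber", ("c", (1,)))

    def test_add_feature_with_default_completes_constraints(self, constrained_space):
        grown = innovate(constrained_space, "add_feature", ("d", (0, 1)), default=0)
        assert len(grown.constraints) == len(constrained_space.constraints)
        for t in grown.constraints:
            assert t("d") == 0
        # forced completion: extension counts unchanged
        s = Section({"a": 0})
        assert len(extensions(s, grown)) == len(extensions(s, constrained_space))

    def test_add_feature_without_default_drops_constraints(self, constrained_space, caplog):
        with caplog.at_level(logging.WARNING, logger="morphospace.presheaf"):
            grown = innovate(constrained_space, "add_feature", ("d", (0, 1)))
        assert grown.constraints is None
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_add_existing_feature_rejected(self, binary_space):
        with pytest.raises(MorphospaceError, match="already exists"):
            innovate(binary_space, "add_feature", ("a", (0, 1)))

    def test_unextendable_section_gains_extension(self):
        """A new fiber value plus a new admissible section rescues a
        previously unextendable partial section."""
        space = FeatureSpace(
            ("wing", "size"),
            {"wing": (0, 1), "size": (0, 1)},
            ConstraintSet([Section({"wing": 0, "size": 0})]),
        )
        stuck = Section({"size": 1})
        assert extensions(stuck, space) == []
        grown = innovate(space, "extend_fiber", ("wing", (2,)))
        rescued = FeatureSpace(
            grown.base,
            grown.fibers,
            ConstraintSet(
                list(grown.constraints) + [Section({"wing": 2, "size": 1})]
            ),
        )
        assert len(extensions(stuck, rescued)) >= 1


class TestAmalgamate:
    def test_wing_example(self, wing_space):
        am = amalgamate(
            wing_space,
            "feathers",
            "forelimb",
            "flight_apparatus",
            {("present", "extended"): "wing"},
        )
        assert am.space.fibers["flight_apparatus"] == ("wing",)
        flyer = am.transport(
            Section({"feathers": "present", "forelimb": "extended", "size": "large"})
        )
        assert flyer("flight_apparatus") == "wing"
        walker = am.transport(Section({"feathers": "absent", "forelimb": "short"}))
        assert "flight_apparatus" not in walker.domain

    def test_total_injective_map_is_bijective_on_sections(self, wing_space):
        pairs = list(
            itertools.product(wing_space.fibers["feathers"], wing_space.fibers["forelimb"])
        )
        vmap = {p: f"v{i}" for i, p in enumerate(pairs)}  # total and injective
        am = amalgamate(wing_space, "feathers", "forelimb", "combo", vmap)
        sections = [
            Section({"feathers": f, "forelimb": l, "size": s})
            for f, l, s in itertools.product(
                wing_space.fibers["feathers"],
                wing_space.fibers["forelimb"],
                wing_space.fibers["size"],
            )
        ]
        images = [am.transport(s) for s in sections]
        assert len(set(images)) == len(sections)

    def test_commutes_with_restriction_to_untouched_features(self, wing_space):
        am = amalgamate(
            wing_space,
            "feathers",
            "forelimb",
            "combo",
            {("present", "extended"): "wing", ("absent", "short"): "plain"},
        )
        for f, l, s in itertools.product(
            wing_space.fibers["feathers"],
            wing_space.fibers["forelimb"],
            wing_space.fibers["size"],
        ):
            sec = Section({"feathers": f, "forelimb": l, "size": s})
            via_transport = restrict(am.transport(sec), {"size"})
            via_restrict = restrict(sec, {"size"})
            assert via_transport == via_restrict

    def test_rejects_bad_input(self, wing_space):
        with pytest.raises(MorphospaceError):
            amalgamate(wing_space, "feathers", "feathers", "x", {("a", "b"): 1})
        with pytest.raises(MorphospaceError, match="non-empty"):
            amalgamate(wing_space, "feathers", "forelimb", "x", {})


class TestSectionsFromMatrix:
    def test_disjoint_carriers_give_disjoint_global_sections(self, m19):
        space, secs = sections_from_matrix(m19)
        assert all(s.domain == frozenset(space.base) for s in secs)
        assert secs[0] != secs[1]

    def test_identical_carriers_give_identical_sections(self, m18):
        _, secs = sections_from_matrix(m18)
        assert secs[0] == secs[1]
        assert secs[0].label != secs[1].label  # labels stay distinct

    def test_missing_entry_gives_partial_section(self):
        M = CharacterMatrix([[1, np.nan, 0]], field_tag="real")
        _, secs = sections_from_matrix(M)
        assert len(secs[0].domain) == 2


class TestGroupActions:
    def test_cyclic_relabeling_is_valid(self, binary_space):
        report = verify_action(cyclic_relabeling_action(binary_space), binary_space)
        assert report.ok

    def test_identity_only_group_is_valid(self, binary_space):
        assert verify_action(identity_action(binary_space), binary_space).ok

    def test_chain_translation_fails_at_the_boundary(self):
        """Shifting along a finite ordered fiber clamps at the last value:
        not a bijection, and t o t misbehaves exactly at the chain's end."""
        vertebral = FeatureSpace(("segment",), {"segment": ("v1", "v2", "v3")})
        report = verify_action(chain_translation_action(vertebral), vertebral)
        assert not report.ok
        kinds = {v[0] for v in report.violations}
        assert "not_bijective" in kinds
        assert "composition_law" in kinds
        boundary = [v for v in report.violations if v[0] == "composition_law"]
        assert any("v2" in v or "v3" in v for v in boundary)

    def test_broken_table_reported(self, binary_space):
        G = identity_action(binary_space)
        G.table = {}
        report = verify_action(G, binary_space)
        assert not report.ok


class TestOrbitClasses:
    def test_identity_group_gives_discrete_partition(self, binary_space):
        secs = [Section({"a": 0}), Section({"a": 1}), Section({"b": 0})]
        classes = orbit_classes(secs, identity_action(binary_space), binary_space)
        assert len(classes) == 3

    def test_cyclic_orbit_merges_related_sections(self):
        sp = FeatureSpace(("a", "b"), {"a": (0, 1), "b": (0, 1)})
        secs = [
            Section({"a": 0, "b": 0}),
            Section({"a": 1, "b": 1}),
            Section({"a": 0, "b": 1}),
        ]
        classes = orbit_classes(secs, cyclic_relabeling_action(sp), sp)
        sizes = sorted(len(c) for c in classes)
        assert sizes == [1, 2]

    def test_output_is_a_partition(self, binary_space):
        secs = [
            Section(dict(zip(binary_space.base, vals)))
            for vals in itertools.product((0, 1), repeat=3)
        ]
        classes = orbit_classes(secs, cyclic_relabeling_action(binary_space), binary_space)
        flattened = [s for cls in classes for s in cls]
        assert sorted(flattened, key=repr) == sorted(secs, key=repr)
        seen = set()
        for cls in classes:
            assert not (set(cls) & seen)
            seen |= set(cls)

    def test_invalid_action_rejected(self, binary_space):
        G = identity_action(binary_space)
        G.table = {}
        with pytest.raises(MorphospaceError, match="valid group action"):
            orbit_classes([Section({"a": 0})], G, binary_space)

    def test_different_domains_never_merge(self, binary_space):
        secs = [Section({"a": 0}), Section({"b": 0})]
        classes = orbit_classes(secs, cyclic_relabeling_action(binary_space), binary_space)
        assert len(classes) == 2
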