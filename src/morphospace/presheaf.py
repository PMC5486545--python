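"""Taxa as partial sections over a base of features.

The geometric picture: the set of features under consideration is the
*base* ``B``; over each feature ``j`` sits a finite *fiber* ``F_j`` of
admissible values.  A taxon is a *partial section* — an assignment of a
fiber value to each feature it possesses — and a species is a section
extended as far as possible.  Restricting a section to a smaller base
moves up the taxonomy; extending it moves down.  Not every combination
of fiber values corresponds to a real organism, so a space may carry an
explicit :class:`ConstraintSet` of admissible global sections encoding
structural, functional, developmental or environmental constraints.

Evolutionary novelty has three moves here: enlarging a fiber with new
values, adding a new feature to the base, and *amalgamation* — fusing
two features into one (feathers + extended forelimbs -> wing).

Finally, a transformation group acting fiberwise (scaling, reflection,
relabeling ...) partitions sections into orbits; each orbit is a
*gestalt*, a pattern identified up to the group's transformations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .errors import MorphospaceError
from .matrix import CharacterMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpace",
    "Section",
    "ConstraintSet",
    "GroupAction",
    "ActionReport",
    "AmalgamationResult",
    "restrict",
    "extensions",
    "apomorphies",
    "innovate",
    "amalgamate",
    "sections_from_matrix",
    "verify_action",
    "orbit_classes",
    "identity_action",
    "cyclic_relabeling_action",
    "chain_translation_action",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Section:
    """A (partial) assignment ``j -> value in F_j`` over a subset of the base.

    Two sections are equal when they assign the same values on the same
    domain; the label is metadata (the taxon's name), not identity.
    """

    assignment: tuple[tuple[str, object], ...]
    label: str = ""

    def __init__(self, assignment, label: str = ""):
        if isinstance(assignment, dict):
            items = tuple(sorted(assignment.items(), key=lambda kv: kv[0]))
        else:
            items = tuple(sorted(assignment, key=lambda kv: kv[0]))
        object.__setattr__(self, "assignment", items)
        object.__setattr__(self, "label", label)

    @property
    def domain(self) -> frozenset[str]:
        return frozenset(j for j, _ in self.assignment)

    def as_dict(self) -> dict:
        return dict(self.assignment)

    def __call__(self, j: str):
        d = dict(self.assignment)
        if j not in d:
            raise KeyError(f"section {self.label!r} is not defined at feature {j!r}")
        return d[j]

    def __eq__(self, other):
        return isinstance(other, Section) and self.assignment == other.assignment

    def __hash__(self):
        return hash(self.assignment)

    def __repr__(self):  # pragma: no cover - cosmetic
        vals = ", ".join(f"{j}={v!r}" for j, v in self.assignment)
        name = f" {self.label!r}" if self.label else ""
        return f"Section({vals}){name}"


@dataclass(frozen=True)
class ConstraintSet:
    """Explicit finite list of admissible global sections."""

    admissible: tuple[Section, ...]

    def __init__(self, admissible):
        adm = tuple(admissible)
        if len(set(adm)) != len(adm):
            raise MorphospaceError("ConstraintSet contains duplicate sections")
        object.__setattr__(self, "admissible", adm)

    def __iter__(self):
        return iter(self.admissible)

    def __len__(self):
        return len(self.admissible)


@dataclass
class FeatureSpace:
    """Base of features, finite fibers of values, optional constraints."""

    base: tuple[str, ...]
    fibers: dict[str, tuple]
    constraints: ConstraintSet | None = None

    def __post_init__(self):
        self.base = tuple(str(j) for j in self.base)
        if len(set(self.base)) != len(self.base):
            raise MorphospaceError("base feature ids must be unique")
        self.fibers = {str(j): tuple(v) for j, v in self.fibers.items()}
        for j in self.base:
            if j not in self.fibers or len(self.fibers[j]) == 0:
                raise MorphospaceError(f"feature {j!r} needs a non-empty fiber")
        if self.constraints is not None:
            for s in self.constraints:
                self.validate_section(s, require_global=True)

    def validate_section(self, s: Section, require_global: bool = False) -> None:
        d = s.as_dict()
        for j, v in d.items():
            if j not in self.fibers:
                raise MorphospaceError(f"section {s.label!r} uses unknown feature {j!r}")
            if v not in self.fibers[j]:
                raise MorphospaceError(
                    f"section {s.label!r} assigns {v!r} outside the fiber of {j!r}"
                )
        if require_global and s.domain != frozenset(self.base):
            raise MorphospaceError(f"section {s.label!r} is not global")

    def global_sections(self):
        """All combinatorially possible global sections (ignoring constraints)."""
        for combo in itertools.product(*(self.fibers[j] for j in self.base)):
            yield Section(dict(zip(self.base, combo)))


# ---------------------------------------------------------------------------
# restriction / extension
# ---------------------------------------------------------------------------

def restrict(s: Section, subbase, space: FeatureSpace | None = None) -> Section:
    """Forget the values outside ``subbase`` (pass to a higher taxon)."""
    subbase = set(subbase)
    if space is not None:
        unknown = subbase - set(space.base)
        if unknown:
            raise MorphospaceError(f"unknown features in subbase: {sorted(unknown)}")
    return Section(
        {j: v for j, v in s.assignment if j in subbase}, label=s.label
    )


def extensions(s: Section, space: FeatureSpace) -> list[Section]:
    """All global sections extending ``s`` (pass to more specific taxa).

    With constraints: the admissible sections agreeing with ``s`` on
    its domain, in admissible order.  Without: every combinatorial
    completion, missing features filled in lexicographic fiber order.
    An empty list means the partial section cannot be completed at all.
    """
    space.validate_section(s)
    if space.constraints is not None:
        return [
            t for t in space.constraints if restrict(t, s.domain) == s
        ]
    missing = [j for j in space.base if j not in s.domain]
    out = []
    for combo in itertools.product(*(space.fibers[j] for j in missing)):
        full = s.as_dict()
        full.update(zip(missing, combo))
        out.append(Section(full, label=s.label))
    return out


def apomorphies(s: Section, space: FeatureSpace) -> dict:
    """Features whose value differs among the extensions of ``s``.

    Maps each feature outside ``domain(s)`` that attains at least two
    distinct values across ``extensions(s, space)`` to the set of
    values attained — the feature values that can distinguish sister
    taxa below ``s``.  Empty when there is at most one extension.
    """
    exts = extensions(s, space)
    if len(exts) <= 1:
        return {}
    out: dict = {}
    for j in space.base:
        if j in s.domain:
            continue
        vals = {t(j) for t in exts}
        if len(vals) >= 2:
            out[j] = vals
    return out


# ---------------------------------------------------------------------------
# innovations
# ---------------------------------------------------------------------------

def innovate(space: FeatureSpace, kind: str, payload, default=None) -> FeatureSpace:
    """Evolutionary novelty as a change of the feature space.

    ``extend_fiber``: payload ``(feature_id, new_values)`` appends new
    values to an existing fiber; every old section stays valid, and
    previously unextendable sections may gain extensions once new
    admissible sections using the values are supplied.

    ``add_feature``: payload ``(feature_id, fiber_values)`` appends a
    fresh feature.  An existing constraint set no longer consists of
    global sections; with ``default`` given, every admissible section
    is completed by it, otherwise the constraints are dropped with a
    logged warning (old constraints are not silently broadcast).
    """
    if kind == "extend_fiber":
        j, new_values = payload
        if j not in space.fibers:
            raise MorphospaceError(f"unknown feature {j!r}")
        new_values = tuple(new_values)
        if not new_values:
            raise MorphospaceError("extend_fiber needs at least one new value")
        if set(new_values) & set(space.fibers[j]):
            raise MorphospaceError("new values must be disjoint from the existing fiber")
        fibers = dict(space.fibers)
        fibers[j] = space.fibers[j] + new_values
        return FeatureSpace(space.base, fibers, constraints=space.constraints)

    if kind == "add_feature":
        j_new, fiber = payload
        fiber = tuple(fiber)
        if j_new in space.fibers or j_new in space.base:
            raise MorphospaceError(f"feature {j_new!r} already exists")
        if not fiber:
            raise MorphospaceError("new feature needs a non-empty fiber")
        fibers = dict(space.fibers)
        fibers[j_new] = fiber
        base = space.base + (j_new,)
        constraints = None
        if space.constraints is not None:
            if default is not None:
                if default not in fiber:
                    raise MorphospaceError("default value must lie in the new fiber")
                constraints = ConstraintSet(
                    Section({**s.as_dict(), j_new: default}, label=s.label)
                    for s in space.constraints
                )
            else:
                logger.warning(
                    "add_feature(%r): constraint set dropped; supply a default "
                    "value to complete the admissible sections", j_new,
                )
        return FeatureSpace(base, fibers, constraints=constraints)

    raise ValueError(f"unknown innovation kind {kind!r}")


@dataclass
class AmalgamationResult:
    space: FeatureSpace
    j1: str
    j2: str
    j_new: str
    value_map: dict

    def transport(self, s: Section) -> Section:
        """Carry a section into the amalgamated space.

        A section defined on both fused features with a mapped value
        pair gains the new feature; otherwise the fused features are
        simply lost (the pair was incompatible with the new structure).
        """
        d = s.as_dict()
        new = {j: v for j, v in d.items() if j not in (self.j1, self.j2)}
        if self.j1 in d and self.j2 in d and (d[self.j1], d[self.j2]) in self.value_map:
            new[self.j_new] = self.value_map[(d[self.j1], d[self.j2])]
        return Section(new, label=s.label)

    def transport_all(self, sections) -> tuple[list[Section], list[str]]:
        """Transport many sections; also report labels that lost the pair."""
        out, dropped = [], []
        for s in sections:
            t = self.transport(s)
            d = s.as_dict()
            if (self.j1 in d or self.j2 in d) and self.j_new not in t.domain:
                dropped.append(s.label)
            out.append(t)
        return out, dropped


def amalgamate(
    space: FeatureSpace, j1: str, j2: str, j_new: str, value_map: dict
) -> AmalgamationResult:
    """Fuse features ``j1`` and ``j2`` into ``j_new`` via ``value_map``.

    The new fiber is the image of ``value_map``; value pairs outside
    its domain have no counterpart in the fused structure, so sections
    carrying them lose the feature on transport.  Constraints are
    transported likewise; admissible sections whose pair is unmapped
    are dropped with a logged warning.
    """
    if j1 == j2 or j1 not in space.fibers or j2 not in space.fibers:
        raise MorphospaceError(f"amalgamate needs two distinct existing features, got {j1!r}, {j2!r}")
    if j_new in space.fibers:
        raise MorphospaceError(f"feature {j_new!r} already exists")
    if not value_map:
        raise MorphospaceError("value_map must be non-empty")
    for (v1, v2) in value_map:
        if v1 not in space.fibers[j1] or v2 not in space.fibers[j2]:
            raise MorphospaceError(f"value pair ({v1!r}, {v2!r}) outside the fibers of {j1!r}, {j2!r}")
    new_fiber = tuple(dict.fromkeys(value_map.values()))
    base = tuple(j for j in space.base if j not in (j1, j2)) + (j_new,)
    fibers = {j: f for j, f in space.fibers.items() if j not in (j1, j2)}
    fibers[j_new] = new_fiber
    result = AmalgamationResult(
        FeatureSpace(base, fibers, constraints=None), j1, j2, j_new, dict(value_map)
    )
    if space.constraints is not None:
        transported, dropped = [], []
        for s in space.constraints:
            t = result.transport(s)
            if t.domain == frozenset(base):
                transported.append(t)
            else:
                dropped.append(s.label or str(s))
        if dropped:
            logger.warning(
                "amalgamate(%r, %r -> %r): %d admissible sections dropped "
                "(value pair not in the map)", j1, j2, j_new, len(dropped),
            )
        seen: list[Section] = []
        for t in transported:
            if t not in seen:
                seen.append(t)
        result.space = FeatureSpace(base, fibers, constraints=ConstraintSet(seen))
    return result


# ---------------------------------------------------------------------------
# bridge from the algebraic view
# ---------------------------------------------------------------------------

def sections_from_matrix(M: CharacterMatrix) -> tuple[FeatureSpace, list[Section]]:
    """Read each carrier row as a partial section (``s_i(j) = c_ij``).

    The base is the feature list; each fiber is the set of observed
    values in that column; missing entries simply leave the section
    undefined at that feature.
    """
    def cell(i, j):
        v = M.values[i, j]
        return int(round(v)) if M.field_tag in ("integer", "gf2") else float(v)

    fibers = {}
    for j, fid in enumerate(M.feature_ids):
        observed = sorted(
            {cell(i, j) for i in range(M.n_carriers) if not M.missing[i, j]}
        )
        fibers[fid] = tuple(observed) if observed else (0,)
    space = FeatureSpace(tuple(M.feature_ids), fibers)
    sections = []
    for i, cid in enumerate(M.carrier_ids):
        assignment = {
            M.feature_ids[j]: cell(i, j)
            for j in range(M.n_features)
            if not M.missing[i, j]
        }
        sections.append(Section(assignment, label=cid))
    return space, sections


# ---------------------------------------------------------------------------
# group actions and gestalts
# ---------------------------------------------------------------------------

@dataclass
class GroupAction:
    """A finite group acting fiberwise on a feature space.

    ``table[(g, h)]`` is the product ``g o h``; ``action[(g, j)]`` the
    map on fiber ``F_j`` as a value dict.  Elements absent from
    ``action`` for a feature act trivially (the group may well fix
    some fibers pointwise).
    """

    elements: tuple[str, ...]
    identity: str
    table: dict
    action: dict

    def apply(self, g: str, j: str, x):
        amap = self.action.get((g, j))
        if amap is None:
            return x
        return amap.get(x, x)

    def apply_section(self, g: str, s: Section) -> Section:
        return Section({j: self.apply(g, j, v) for j, v in s.assignment}, label=s.label)


@dataclass
class ActionReport:
    ok: bool
    violations: list

    def __bool__(self):
        return self.ok


def verify_action(G: GroupAction, space: FeatureSpace) -> ActionReport:
    """Check the group axioms and the fiberwise action law.

    Verifies that the composition table is a group (closure, identity,
    associativity, inverses), that the identity acts trivially, that
    every action map is a bijection of its fiber, and that
    ``(g o h)(x) = g(h(x))`` for all elements and all fiber values.
    Failures are collected as data, not raised.
    """
    V: list = []
    els = G.elements
    for g in els:
        for h in els:
            if (g, h) not in G.table or G.table[(g, h)] not in els:
                V.append(("closure", g, h))
    if G.identity not in els:
        V.append(("identity_missing", G.identity))
    else:
        for g in els:
            if G.table.get((G.identity, g)) != g or G.table.get((g, G.identity)) != g:
                V.append(("identity_law", g))
    for g in els:
        if not any(
            G.table.get((g, h)) == G.identity and G.table.get((h, g)) == G.identity
            for h in els
        ):
            V.append(("inverse_missing", g))
    for g in els:
        for h in els:
            for k in els:
                gh, hk = G.table.get((g, h)), G.table.get((h, k))
                if gh in els and hk in els and G.table.get((gh, k)) != G.table.get((g, hk)):
                    V.append(("associativity", g, h, k))
    for j in space.base:
        fiber = set(space.fibers[j])
        for g in els:
            image = [G.apply(g, j, x) for x in space.fibers[j]]
            if set(image) != fiber or len(set(image)) != len(image):
                V.append(("not_bijective", g, j))
        for x in space.fibers[j]:
            if G.apply(G.identity, j, x) != x:
                V.append(("identity_not_trivial", j, x))
        for g in els:
            for h in els:
                gh = G.table.get((g, h))
                if gh not in els:
                    continue
                for x in space.fibers[j]:
                    if G.apply(gh, j, x) != G.apply(g, j, G.apply(h, j, x)):
                        V.append(("composition_law", g, h, j, x))
    return ActionReport(not V, V)


def orbit_classes(sections, G: GroupAction, space: FeatureSpace) -> list[list[Section]]:
    """Partition sections into gestalts (orbits of the group action).

    Two sections are equivalent when their domains coincide and some
    group element carries one onto the other fiber by fiber.  Each
    class lists its members with the lexicographically least first.
    """
    report = verify_action(G, space)
    if not report.ok:
        raise MorphospaceError(
            f"orbit_classes requires a valid group action; {len(report.violations)} violations"
        )
    sections = list(sections)
    n = len(sections)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, k):
        ri, rk = find(i), find(k)
        if ri != rk:
            parent[rk] = ri

    for i in range(n):
        for k in range(i + 1, n):
            s, t = sections[i], sections[k]
            if s.domain != t.domain:
                continue
            if any(G.apply_section(g, s) == t for g in G.elements):
                union(i, k)

    groups: dict[int, list[Section]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(sections[i])

    def sec_key(s: Section):
        return tuple((j, repr(v)) for j, v in s.assignment)

    classes = [sorted(members, key=sec_key) for members in groups.values()]
    classes.sort(key=lambda cls: sec_key(cls[0]))
    return classes


# ---------------------------------------------------------------------------
# shipped example actions
# ---------------------------------------------------------------------------

def identity_action(space: FeatureSpace) -> GroupAction:
    """The trivial group: every fiber fixed pointwise."""
    return GroupAction(("e",), "e", {("e", "e"): "e"}, {})


def cyclic_relabeling_action(space: FeatureSpace, order: int | None = None) -> GroupAction:
    """Cyclic relabeling: shift every fiber's values cyclically.

    A stand-in for a scaling-type symmetry on categorical data; the
    group is Z/k with k the least common multiple-friendly choice of
    ``order`` (default: max fiber size).
    """
    if order is None:
        order = max(len(f) for f in space.fibers.values())
    els = tuple(f"g{i}" for i in range(order))
    table = {
        (els[i], els[j]): els[(i + j) % order] for i in range(order) for j in range(order)
    }
    action = {}
    for j in space.base:
        fiber = space.fibers[j]
        k = len(fiber)
        for i in range(order):
            action[(els[i], j)] = {fiber[t]: fiber[(t + i) % k] for t in range(k)}
    return GroupAction(els, els[0], table, action)


def chain_translation_action(space: FeatureSpace) -> GroupAction:
    """'Translation' along a finite ordered fiber — deliberately broken.

    Serial homologies (e.g. along the vertebral column) look like
    translations, but a finite chain has ends: the shift clamps at the
    last value, so it is not a bijection and the group law fails at the
    boundary.  :func:`verify_action` reports exactly those violations.
    """
    els = ("e", "t")
    table = {("e", "e"): "e", ("e", "t"): "t", ("t", "e"): "t", ("t", "t"): "e"}
    action = {}
    for j in space.base:
        fiber = space.fibers[j]
        k = len(fiber)
        action[("t", j)] = {
            fiber[t]: fiber[min(t + 1, k - 1)] for t in range(k)
        }
    return GroupAction(els, "e", table, action)
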