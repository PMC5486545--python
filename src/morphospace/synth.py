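"""Seeded generators for cladistic, functional, noisy and constrained fixtures.

Every generator is a pure function of its arguments (including the
seed), so any downstream analysis is reproducible bit for bit.  The
cladistic generator emits the staircase matrix of nested
synapomorphies; the functional generator overlays perfectly correlated
feature blocks (full factorial by default, so every combination of
syndrome states is realized); the noise models are the minimal
standard ones — entrywise Gaussian jitter for measurements,
independent bit flips for presence/absence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import FieldError, MorphospaceError
from .matrix import CharacterMatrix
from .presheaf import ConstraintSet, FeatureSpace, Section

__all__ = [
    "SynthSpec",
    "NoisyResult",
    "gen_cladistic",
    "gen_functional",
    "gen_noisy",
    "gen_space",
]


@dataclass
class SynthSpec:
    """Recipe for a synthetic fixture.

    ``clusters`` lists ``(feature_ids, n_states)`` blocks for the
    functional generator; ``complete`` selects the full-factorial
    carrier design.  ``noise`` is ``(model, magnitude)`` with model
    ``gaussian_sd`` (real) or ``flip_rate`` (gf2).  The seed is
    mandatory for any stochastic kind.
    """

    kind: str
    n_carriers: int = 0
    n_features: int = 0
    clusters: list | None = None
    complete: bool = True
    noise: tuple | None = None
    seed: int | None = None
    n_values: int = 2
    n_admissible: int | None = None

    def __post_init__(self):
        if self.kind not in ("cladistic", "functional", "noisy", "space"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("noisy", "space") or (self.kind == "functional" and not self.complete):
            if self.seed is None:
                raise ValueError(f"kind {self.kind!r} is stochastic: a seed is required")


@dataclass
class NoisyResult:
    matrix: CharacterMatrix
    model: str
    magnitude: float
    n_changed: int


def gen_cladistic(n: int) -> CharacterMatrix:
    """The n x n staircase of nested synapomorphies.

    Carrier ``i`` possesses characters ``1..i``; the last species
    possesses all characters, character ``n`` is its apomorphy, and
    character ``k`` is a synapomorphy of species ``k..n``.  The matrix
    is binary, lower-triangular and of maximal rank ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = np.tril(np.ones((n, n)))
    return CharacterMatrix(
        X,
        carrier_ids=[f"species_{i + 1}" for i in range(n)],
        feature_ids=[f"character_{j + 1}" for j in range(n)],
        field_tag="gf2",
    )


def gen_functional(spec: SynthSpec) -> CharacterMatrix:
    """Overlay of perfectly correlated feature blocks.

    Each cluster ``(features, k)`` assigns one of ``k`` state labels
    (1..k) per carrier, identically across all its features.  With
    ``complete=True`` the carriers are the full factorial of cluster
    states, in product order (first cluster outermost); otherwise
    ``n_carriers`` random state combinations are drawn with the spec's
    seed.
    """
    if spec.kind != "functional":
        raise ValueError("spec.kind must be 'functional'")
    if not spec.clusters:
        raise MorphospaceError("functional spec needs clusters")
    feature_ids: list[str] = []
    for feats, k in spec.clusters:
        if k < 1:
            raise MorphospaceError("each cluster needs at least one state")
        for f in feats:
            if f in feature_ids:
                raise MorphospaceError(f"feature {f!r} assigned to two clusters")
            feature_ids.append(str(f))
    state_counts = [k for _, k in spec.clusters]

    if spec.complete:
        combos = list(itertools.product(*(range(k) for k in state_counts)))
    else:
        if spec.n_carriers < 1:
            raise MorphospaceError("sampled design needs n_carriers >= 1")
        rng = np.random.default_rng(spec.seed)
        combos = [
            tuple(int(rng.integers(0, k)) for k in state_counts)
            for _ in range(spec.n_carriers)
        ]

    rows = []
    for combo in combos:
        row = []
        for (feats, _k), state in zip(spec.clusters, combo):
            row.extend([state + 1] * len(feats))
        rows.append(row)
    return CharacterMatrix(
        np.array(rows, dtype=float),
        carrier_ids=[f"taxon_{i + 1}" for i in range(len(combos))],
        feature_ids=feature_ids,
        field_tag="integer",
    )


def gen_noisy(M: CharacterMatrix, noise: tuple, seed: int) -> NoisyResult:
    """Seeded perturbation of a matrix.

    ``("gaussian_sd", sd)`` adds iid N(0, sd^2) to every entry of a
    real matrix; ``("flip_rate", p)`` flips each bit of a gf2 matrix
    independently with probability ``p``.  Missing entries are left
    untouched.
    """
    model, magnitude = noise
    rng = np.random.default_rng(seed)
    out = M.copy()
    if model == "gaussian_sd":
        if M.field_tag != "real":
            raise FieldError("gaussian_sd noise applies to real matrices")
        if magnitude < 0:
            raise ValueError("sd must be nonnegative")
        delta = rng.normal(0.0, magnitude, size=M.shape) if magnitude > 0 else np.zeros(M.shape)
        delta[M.missing] = 0.0
        out.values = M.values + delta
        changed = int(np.sum(delta != 0))
    elif model == "flip_rate":
        if M.field_tag != "gf2":
            raise FieldError("flip_rate noise applies to gf2 matrices")
        if not 0 <= magnitude <= 1:
            raise ValueError("flip rate must lie in [0, 1]")
        flips = rng.random(M.shape) < magnitude
        flips &= ~M.missing
        out.values = np.where(flips, 1.0 - np.round(M.values), M.values)
        changed = int(flips.sum())
    else:
        raise ValueError(f"unknown noise model {model!r}")
    return NoisyResult(out, model, float(magnitude), changed)


def gen_space(spec: SynthSpec) -> FeatureSpace:
    """A random constrained feature space with both extension behaviours.

    Draws ``n_features`` fibers of ``n_values`` values each and a
    seeded random admissible set of ``n_admissible`` global sections.
    The construction guarantees (when the requested sizes permit, i.e.
    ``2 <= n_admissible < total``) that some partial section has at
    least two extensions and some global section has none — the two
    canonical behaviours of constrained extension.
    """
    if spec.kind != "space":
        raise ValueError("spec.kind must be 'space'")
    m, k = spec.n_features, spec.n_values
    if m < 1 or k < 1:
        raise MorphospaceError("need n_features >= 1 and n_values >= 1")
    total = k ** m
    n_adm = spec.n_admissible if spec.n_admissible is not None else min(max(2, total // 2), total - 1)
    if not 1 <= n_adm <= total:
        raise MorphospaceError(f"n_admissible must be in 1..{total}")
    if not (2 <= n_adm < total):
        raise MorphospaceError(
            f"cannot guarantee both >=2-extension and 0-extension behaviour with "
            f"{n_adm} admissible of {total} global sections"
        )
    base = tuple(f"f{j + 1}" for j in range(m))
    fibers = {j: tuple(range(k)) for j in base}
    rng = np.random.default_rng(spec.seed)
    all_sections = [
        Section(dict(zip(base, combo)))
        for combo in itertools.product(*(fibers[j] for j in base))
    ]
    idx = rng.choice(total, size=n_adm, replace=False)
    admissible = [all_sections[i] for i in sorted(idx)]
    return FeatureSpace(base, fibers, constraints=ConstraintSet(admissible))
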