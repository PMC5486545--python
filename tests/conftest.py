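import numpy as np
import pytest

from morphospace import CharacterMatrix, ConstraintSet, FeatureSpace, Section


@pytest.fixture
def eq7():
    """3x3 permutation-like matrix of full rank 3."""
    return CharacterMatrix([[0, 1, 0], [1, 0, 0], [0, 0, 1]], field_tag="real")


@pytest.fixture
def eq8():
    """Rank-1 matrix (1,2) (x) (1,2,5)."""
    return CharacterMatrix([[1, 2, 5], [2, 4, 10]], field_tag="integer")


@pytest.fixture
def eq8_real():
    return CharacterMatrix([[1, 2, 5], [2, 4, 10]], field_tag="real")


@pytest.fixture
def m18():
    """Two identical carriers: features dependent on carriers."""
    return CharacterMatrix([[1, 0, 0, 1], [1, 0, 0, 1]], field_tag="gf2")


@pytest.fixture
def m19():
    """Disjoint carriers: dependencies between the features themselves."""
    return CharacterMatrix([[1, 0, 0, 1], [0, 1, 1, 0]], field_tag="gf2")


@pytest.fixture
def eq21():
    """5x5 cladistic staircase: nested synapomorphies, maximal rank."""
    X = np.tril(np.ones((5, 5)))
    return CharacterMatrix(
        X,
        carrier_ids=[f"species_{i}" for i in range(1, 6)],
        feature_ids=[f"character_{j}" for j in range(1, 6)],
        field_tag="gf2",
    )


@pytest.fixture
def eq23():
    """Functional matrix after canonical labeling: all columns identical."""
    return CharacterMatrix(
        [[1, 1, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3]],
        carrier_ids=["carnivore", "herbivore", "insectivore"],
        feature_ids=["teeth", "feet", "stomach", "claws"],
        field_tag="integer",
    )


@pytest.fixture
def eq24():
    """Overlay of a 2-state feeding cluster and a 3-state climate cluster."""
    return CharacterMatrix(
        [
            [1, 1, 1, 1],
            [1, 1, 2, 2],
            [1, 1, 3, 3],
            [2, 2, 1, 1],
            [2, 2, 2, 2],
            [2, 2, 3, 3],
        ],
        carrier_ids=[
            "arctic_carnivore",
            "temperate_carnivore",
            "tropical_carnivore",
            "arctic_herbivore",
            "temperate_herbivore",
            "tropical_herbivore",
        ],
        feature_ids=["teeth", "feet", "fur", "color"],
        field_tag="integer",
    )


@pytest.fixture
def binary_space():
    """Three binary features, unconstrained."""
    return FeatureSpace(
        ("a", "b", "c"), {"a": (0, 1), "b": (0, 1), "c": (0, 1)}
    )


@pytest.fixture
def constrained_space(binary_space):
    """Four admissible sections; the partial section a=0 has exactly three
    extensions (the multi-extension picture) while a conflicting section
    has none (the unextendable picture)."""
    adm = [
        Section({"a": 0, "b": 0, "c": 0}, label="g1"),
        Section({"a": 0, "b": 1, "c": 0}, label="g2"),
        Section({"a": 0, "b": 1, "c": 1}, label="g3"),
        Section({"a": 1, "b": 0, "c": 0}, label="g4"),
    ]
    return FeatureSpace(
        binary_space.base, binary_space.fibers, ConstraintSet(adm)
    )


@pytest.fixture
def wing_space():
    return FeatureSpace(
        ("feathers", "forelimb", "size"),
        {
            "feathers": ("absent", "present"),
            "forelimb": ("short", "extended"),
            "size": ("small", "large"),
        },
    )
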