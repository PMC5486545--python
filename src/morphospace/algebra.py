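"""Rank and frequency algebra on carrier-feature matrices.

The number of independent feature combinations in a character matrix
``C`` is its tensor-product rank: the minimal ``r`` in

    C = sum_{nu=1..r} a^nu (x) b^nu,

where each ``b^nu`` (an *independent feature combination*) defines a
character cluster and ``a^nu`` holds the per-carrier factors.  Over the
reals the rank is computed from singular values with a relative
tolerance; over the integers (rationals) and GF(2) it is exact.

The module also carries the frequency side of the theory for binary
features: marginal and joint occurrence frequencies, the normalized
co-occurrence matrix ``P = C C^T / Z``, and the independence test
``p_{j1..js} = p_{j1} * ... * p_{js}``.  Dependence between features
drives the matrix rank down, while *independence* of the feature
frequencies drives the rank of the frequency tensors down to one — the
two notions pull in opposite directions and both are exposed here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import DegenerateMatrixError, FieldError
from .matrix import CharacterMatrix

DEFAULT_TOL = 1e-8

__all__ = [
    "RankDecomposition",
    "CharacterCluster",
    "FrequencyModel",
    "IndependenceResult",
    "matrix_rank",
    "rank_decompose",
    "epsilon_rank",
    "character_clusters",
    "cooccurrence_matrix",
    "feature_frequencies",
    "independence_test",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class RankDecomposition:
    """A minimal outer-product representation of a matrix.

    ``terms`` is an ordered list of ``(a, b)`` pairs — carrier-factor
    vector and feature-combination vector — whose outer products sum to
    the matrix.  For exact fields the entries are :class:`~fractions.Fraction`
    and the reconstruction is exact; for the real field they are floats
    from the SVD canonical form.
    """

    terms: list[tuple[np.ndarray, np.ndarray]]
    rank: int
    field_tag: str
    reconstruction_error: float
    shape: tuple[int, int] = (0, 0)

    def reconstruct(self) -> np.ndarray:
        n, m = self.shape
        total = np.zeros((n, m), dtype=object if self.field_tag != "real" else float)
        for a, b in self.terms:
            total = total + np.outer(a, b)
        if self.field_tag == "gf2":  # addition in the field is mod 2
            total = np.array(
                [[Fraction(int(x) % 2) for x in row] for row in total], dtype=object
            )
        return total


@dataclass
class CharacterCluster:
    """One independent feature combination and its carrier factors."""

    feature_combination: np.ndarray
    carrier_factors: np.ndarray
    representative_features: list[str]


@dataclass
class FrequencyModel:
    """Marginal/joint feature frequencies and the co-occurrence matrix.

    Which tables are populated depends on the producing operation:
    :func:`feature_frequencies` fills ``marginals``, ``pairwise`` and
    ``joint_tensors`` under the chosen convention, while
    :func:`cooccurrence_matrix` fills ``cooccurrence`` and its
    normalizer ``Z``.
    """

    convention: str | None = None
    feature_ids: list[str] = field(default_factory=list)
    marginals: np.ndarray | None = None
    pairwise: np.ndarray | None = None
    joint_tensors: dict[int, np.ndarray] = field(default_factory=dict)
    cooccurrence: np.ndarray | None = None
    Z: Fraction | float | None = None


@dataclass
class IndependenceResult:
    independent: bool
    max_deviation: float
    argmax: tuple[int, ...] | None

    def __iter__(self):  # allow ``ok, dev = independence_test(...)``
        yield self.independent
        yield self.max_deviation


# ---------------------------------------------------------------------------
# exact elimination over Q and GF(2)
# ---------------------------------------------------------------------------

def _exact_entries(M: CharacterMatrix) -> list[list[Fraction]]:
    rows = M.exact_rows()
    if M.field_tag == "gf2":
        return [[Fraction(int(v) % 2) for v in row] for row in rows]
    return rows


def _reduce_gf2(x: Fraction) -> Fraction:
    return Fraction(int(x) % 2)


def _peel_decompose(rows: list[list[Fraction]], gf2: bool):
    """Column-pivoted outer-product peeling.

    Scans columns left to right, rows top to bottom for the first
    nonzero pivot; peels ``a (x) b`` with the leading coefficient of
    ``a`` normalized to 1.  The resulting ``a`` (resp. ``b``) vectors
    have an echelon pattern and are therefore linearly independent, so
    the number of terms equals the rank.
    """
    n, m = len(rows), len(rows[0])
    R = [row[:] for row in rows]
    terms: list[tuple[list[Fraction], list[Fraction]]] = []
    while True:
        pivot = None
        for j in range(m):
            for i in range(n):
                if R[i][j] != 0:
                    pivot = (i, j)
                    break
            if pivot:
                break
        if pivot is None:
            break
        pi, pj = pivot
        v = R[pi][pj]
        a = [R[i][pj] / v for i in range(n)]
        b = [R[pi][j] for j in range(m)]
        if gf2:
            a = [_reduce_gf2(x) for x in a]
            b = [_reduce_gf2(x) for x in b]
        for i in range(n):
            if a[i] == 0:
                continue
            for j in range(m):
                R[i][j] -= a[i] * b[j]
                if gf2:
                    R[i][j] = _reduce_gf2(R[i][j])
        terms.append((a, b))
    return terms


def _column_class_decompose(rows: list[list[Fraction]], gf2: bool):
    """Group proportional columns into classes; one term per class.

    Returns ``None`` when the classes do not directly yield a minimal
    decomposition (i.e. class count exceeds the rank).  When it
    succeeds, the terms have feature-disjoint supports — the form in
    which overlay matrices such as a feeding-type cluster plus a
    climate cluster are naturally written.
    """
    n, m = len(rows), len(rows[0])
    cols = [[rows[i][j] for i in range(n)] for j in range(m)]

    def first_nonzero(v):
        for x in v:
            if x != 0:
                return x
        return None

    classes: list[dict] = []  # {"rep": normalized column, "coeffs": {j: mu}}
    for j, col in enumerate(cols):
        lead = first_nonzero(col)
        if lead is None:
            continue  # zero column: contributes nothing
        unit = [x / lead for x in col]
        if gf2:
            unit = [_reduce_gf2(x) for x in unit]
        placed = False
        for cls in classes:
            if cls["rep"] == unit:
                cls["coeffs"][j] = lead
                placed = True
                break
        if not placed:
            classes.append({"rep": unit, "coeffs": {j: lead}})
    rank = len(_peel_decompose(rows, gf2))
    if len(classes) != rank:
        return None
    terms = []
    for cls in classes:
        a = list(cls["rep"])
        b = [Fraction(0)] * m
        for j, mu in cls["coeffs"].items():
            b[j] = _reduce_gf2(mu) if gf2 else mu
        terms.append((a, b))
    return terms


def _gf2_rank(rows: list[list[Fraction]]) -> int:
    return len(_peel_decompose(rows, gf2=True))


# ---------------------------------------------------------------------------
# rank operations
# ---------------------------------------------------------------------------

def matrix_rank(M: CharacterMatrix, tol: float = DEFAULT_TOL) -> int:
    """Minimal number of outer-product terms representing ``M``.

    Exact elimination for ``integer``/``gf2``; for ``real``, the count
    of singular values above ``tol`` times the largest.
    """
    M.require_complete()
    if M.field_tag == "real":
        if tol < 0:
            raise ValueError("tol must be nonnegative")
        s = np.linalg.svd(M.values, compute_uv=False)
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > tol * s[0]))
    rows = _exact_entries(M)
    return len(_peel_decompose(rows, gf2=M.field_tag == "gf2"))


def rank_decompose(M: CharacterMatrix, tol: float = DEFAULT_TOL) -> RankDecomposition:
    """A canonical minimal decomposition ``C = sum a^nu (x) b^nu``.

    Real matrices use the SVD canonical form ``a = sigma u``, ``b = v``
    (descending sigma, sign fixed so the dominant entry of each ``b`` is
    positive).  Exact fields prefer the feature-disjoint column-class
    form when it is minimal, falling back to pivoted elimination.
    """
    M.require_complete()
    if M.field_tag == "real":
        u, s, vt = np.linalg.svd(M.values, full_matrices=False)
        r = 0 if (s.size == 0 or s[0] == 0) else int(np.sum(s > tol * s[0]))
        terms = []
        for nu in range(r):
            a = s[nu] * u[:, nu]
            b = vt[nu, :].copy()
            k = int(np.argmax(np.abs(b)))
            if b[k] < 0:
                a, b = -a, -b
            terms.append((a, b))
        approx = sum((np.outer(a, b) for a, b in terms), np.zeros(M.shape))
        err = float(np.linalg.norm(M.values - approx))
        return RankDecomposition(terms, r, "real", err, shape=M.shape)

    rows = _exact_entries(M)
    gf2 = M.field_tag == "gf2"
    terms = _column_class_decompose(rows, gf2)
    if terms is None:
        terms = _peel_decompose(rows, gf2)
    # order by decreasing carrier-factor norm, then first loaded feature
    def sort_key(term):
        a, b = term
        norm2 = float(sum(Fraction(x) * Fraction(x) for x in a))
        first = next((j for j, x in enumerate(b) if x != 0), len(b))
        return (-norm2, first)

    terms = sorted(terms, key=sort_key)
    arr_terms = [
        (np.array(a, dtype=object), np.array(b, dtype=object)) for a, b in terms
    ]
    return RankDecomposition(arr_terms, len(arr_terms), M.field_tag, 0.0, shape=M.shape)


def epsilon_rank(M: CharacterMatrix, eps: float, norm_tag: str = "frobenius") -> int:
    """Minimal rank among matrices within Frobenius distance ``eps`` (strict).

    By Eckart-Young the minimizer truncates the SVD, so this is the
    smallest ``r`` whose trailing singular values satisfy
    ``sum_{k>r} sigma_k^2 < eps^2``.  A tail exactly at the boundary
    keeps the higher rank (the distance bound is strict).
    """
    if M.field_tag != "real":
        raise FieldError("epsilon_rank applies to the real field; use matrix_rank for exact fields")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if norm_tag != "frobenius":
        raise ValueError(f"unsupported norm {norm_tag!r}")
    M.require_complete()
    s = np.linalg.svd(M.values, compute_uv=False).astype(float)
    for r in range(s.size + 1):
        tail = float(np.sum(s[r:] ** 2))
        if tail < eps * eps:
            return r
    return s.size


def character_clusters(
    M: CharacterMatrix, eps: float = 0.0, rep_frac: float = 0.1, tol: float = DEFAULT_TOL
) -> list[CharacterCluster]:
    """Character clusters: one per term of the minimal decomposition.

    With ``eps > 0`` (real field) the matrix is first replaced by its
    closest lower-rank neighbour within ``eps`` (the epsilon-rank
    truncation).  Representative features carry a nonzero loading
    (exact fields) or a loading of at least ``rep_frac`` times the
    dominant one (real field).
    """
    M.require_complete()
    work = M
    if eps > 0:
        if M.field_tag != "real":
            raise FieldError("eps > 0 requires the real field")
        r = epsilon_rank(M, eps)
        u, s, vt = np.linalg.svd(M.values, full_matrices=False)
        truncated = (u[:, :r] * s[:r]) @ vt[:r, :]
        work = CharacterMatrix(
            truncated,
            carrier_ids=list(M.carrier_ids),
            feature_ids=list(M.feature_ids),
            field_tag="real",
        )
    dec = rank_decompose(work, tol=tol)
    clusters = []
    for a, b in dec.terms:
        if dec.field_tag == "real":
            mags = np.abs(np.asarray(b, dtype=float))
            top = mags.max() if mags.size else 0.0
            reps = [
                M.feature_ids[j]
                for j in range(len(b))
                if top > 0 and mags[j] >= rep_frac * top
            ]
        else:
            reps = [M.feature_ids[j] for j in range(len(b)) if b[j] != 0]
        clusters.append(
            CharacterCluster(
                feature_combination=np.asarray(b),
                carrier_factors=np.asarray(a),
                representative_features=reps,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def cooccurrence_matrix(M: CharacterMatrix) -> FrequencyModel:
    """The normalized carrier co-occurrence matrix ``P = C C^T / Z``.

    ``p_ij = (1/Z) sum_k c_ik c_jk`` with ``Z`` the total mass of
    ``C C^T``.  P is symmetric, its entries sum to one, and its rank
    (over the rationals/reals — the normalization leaves GF(2)) equals
    the rank of ``C``.
    """
    M.require_complete()
    if M.field_tag == "real":
        G = M.values @ M.values.T
        Z = float(G.sum())
        if Z == 0.0:
            raise DegenerateMatrixError("degenerate matrix: all co-occurrence mass is zero")
        P = G / Z
    else:
        rows = M.exact_rows()
        n = len(rows)
        G = [
            [sum(rows[i][k] * rows[j][k] for k in range(len(rows[0]))) for j in range(n)]
            for i in range(n)
        ]
        Z = sum(sum(row) for row in G)
        if Z == 0:
            raise DegenerateMatrixError("degenerate matrix: all co-occurrence mass is zero")
        P = np.array([[g / Z for g in row] for row in G], dtype=object)
    return FrequencyModel(
        convention=None,
        feature_ids=list(M.carrier_ids),  # P is indexed by carriers
        cooccurrence=np.asarray(P),
        Z=Z,
    )


def cooccurrence_rank(F: FrequencyModel, tol: float = DEFAULT_TOL) -> int:
    """Rank of the co-occurrence matrix over the rationals/reals."""
    P = F.cooccurrence
    if P is None:
        raise ValueError("FrequencyModel has no cooccurrence matrix")
    if P.dtype == object:
        rows = [[Fraction(x) for x in row] for row in P]
        return len(_peel_decompose(rows, gf2=False))
    s = np.linalg.svd(np.asarray(P, dtype=float), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > tol * s[0]))


def feature_frequencies(
    M: CharacterMatrix, convention: str = "carrier_fraction", max_order: int = 2
) -> FrequencyModel:
    """Marginal and joint occurrence frequencies of binary features.

    Conventions (the printed formula and the worked examples in the
    source theory disagree; all three readings are provided):

    ``carrier_fraction`` (default)
        ``p_{j1..js}`` = fraction of carriers possessing all of
        ``j1..js``.  Matches every worked example.
    ``total_normalized``
        counts normalized by the total number of feature occurrences
        ``sum_l r_l`` (the printed marginal formula).
    ``distributional``
        each order-``s`` table normalized to total mass one; the
        marginals are the row sums of the pairwise table, so the
        row-sum property holds by construction.

    All tables are exact rationals.
    """
    M.require_complete()
    if M.field_tag != "gf2":
        raise FieldError("feature_frequencies requires a gf2 (presence/absence) matrix")
    if convention not in ("carrier_fraction", "total_normalized", "distributional"):
        raise ValueError(f"unknown convention {convention!r}")
    n, m = M.shape
    if not 1 <= max_order <= m:
        raise ValueError(f"max_order must be in 1..{m}")
    X = [[int(round(v)) for v in row] for row in M.values]
    r = [sum(X[i][j] for i in range(n)) for j in range(m)]  # occurrence counts
    total = sum(r)

    def joint_count(js: tuple[int, ...]) -> int:
        return sum(1 for i in range(n) if all(X[i][j] for j in js))

    tensors: dict[int, np.ndarray] = {}
    for s in range(1, max_order + 1):
        T = np.empty((m,) * s, dtype=object)
        for idx in itertools.product(range(m), repeat=s):
            T[idx] = Fraction(joint_count(idx))
        tensors[s] = T

    if convention == "carrier_fraction":
        for s in tensors:
            tensors[s] = tensors[s] / Fraction(n)
        marginals = np.array([Fraction(rj, n) for rj in r], dtype=object)
    elif convention == "total_normalized":
        if total == 0:
            raise DegenerateMatrixError("no feature occurrences to normalize by")
        for s in tensors:
            tensors[s] = tensors[s] / Fraction(total)
        marginals = np.array([Fraction(rj, total) for rj in r], dtype=object)
    else:  # distributional
        for s in tensors:
            mass = sum(tensors[s].flat)
            if mass == 0:
                raise DegenerateMatrixError("no feature occurrences to normalize by")
            tensors[s] = tensors[s] / mass
        if 2 not in tensors:
            T = np.empty((m, m), dtype=object)
            for idx in itertools.product(range(m), repeat=2):
                T[idx] = Fraction(joint_count(idx))
            tensors[2] = T / sum(T.flat)
        marginals = np.array(
            [sum(tensors[2][j, k] for k in range(m)) for j in range(m)], dtype=object
        )

    pairwise = tensors.get(2)
    return FrequencyModel(
        convention=convention,
        feature_ids=list(M.feature_ids),
        marginals=marginals,
        pairwise=pairwise,
        joint_tensors=tensors,
        Z=None,
    )


def independence_test(
    F: FrequencyModel, order: int = 2, tol: float = 0.0
) -> IndependenceResult:
    """Does the order-``s`` joint tensor factor as ``p (x) ... (x) p``?

    Returns whether every entry matches the product of marginals within
    ``tol``, together with the largest absolute deviation
    ``|p_{j1..js} - p_{j1} ... p_{js}|`` and where it occurs.
    """
    if order not in F.joint_tensors:
        raise ValueError(f"FrequencyModel has no joint tensor of order {order}")
    if F.marginals is None:
        raise ValueError("FrequencyModel has no marginals")
    T = F.joint_tensors[order]
    p = F.marginals
    m = len(p)
    best = Fraction(0)
    arg = None
    for idx in itertools.product(range(m), repeat=order):
        prod = Fraction(1)
        for j in idx:
            prod *= Fraction(p[j])
        dev = abs(Fraction(T[idx]) - prod)
        if dev > best:
            best, arg = dev, idx
    return IndependenceResult(float(best) <= tol, float(best), arg)


def pair_frequencies(F: FrequencyModel, j: int, k: int) -> dict:
    """Joint frequency of features ``j``, ``k`` (0-based) vs the marginal product."""
    if F.pairwise is None or F.marginals is None:
        raise ValueError("FrequencyModel lacks pairwise table or marginals")
    joint = Fraction(F.pairwise[j, k])
    prod = Fraction(F.marginals[j]) * Fraction(F.marginals[k])
    return {
        "features": (F.feature_ids[j], F.feature_ids[k]),
        "joint": joint,
        "product": prod,
        "deviation": abs(joint - prod),
        "independent_pair": joint == prod,
    }
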