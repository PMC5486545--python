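"""Tensor rank for the higher-order frequency tensors.

Matrix rank captures pairwise dependence; the rank of an order-``s``
joint-frequency tensor captures dependence among ``s`` features at
once.  Tensor rank beyond order two is NP-hard in general, so this
module offers two honest regimes:

``exact_small``
    A genuine decision procedure for tiny tensors.  Over GF(2) the
    search is exhaustive (the finite field makes the set of rank-one
    tensors finite).  Over the rationals, a claimed rank ``r`` is
    decided algebraically: the polynomial system ``T = sum of r
    rank-one terms`` is branched over vector normalization patterns and
    handed to sympy — a Groebner basis equal to {1} proves there is no
    solution even over the complex numbers, hence rank > r; an explicit
    solution is a witness.

``als_upper_bound``
    Alternating least squares CP fits with seeded restarts; reports the
    smallest ``r`` whose relative residual falls below tolerance.  This
    is an upper bound on the rank (and says nothing about border rank,
    which can be strictly smaller).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import sympy as sp

__all__ = ["TensorRankResult", "tensor_rank", "cp_als"]

EXACT_ENTRY_CAP = 16
EXACT_MAX_RANK = 4


@dataclass
class TensorRankResult:
    rank: int | None            # None when the search was exhausted at max_rank
    mode: str
    is_upper_bound: bool
    max_rank: int
    decomposition: list[tuple] | None = None
    residual: float | None = None

    @property
    def exceeded(self) -> bool:
        return self.rank is None


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def _flattening_rank_lb(T: np.ndarray, gf2: bool) -> int:
    """max over modes of the unfolding rank — a lower bound on tensor rank."""
    lb = 0
    for mode in range(T.ndim):
        unf = np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)
        M = sp.Matrix([[sp.Rational(x) for x in row] for row in unf.tolist()])
        if gf2:
            r = _gf2_matrix_rank(np.asarray(unf, dtype=int) % 2)
        else:
            r = M.rank()
        lb = max(lb, r)
    return lb


def _gf2_matrix_rank(A: np.ndarray) -> int:
    A = (A.copy() % 2).astype(np.uint8)
    rank = 0
    rows, cols = A.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if A[r, c]:
                piv = r
                break
        if piv is None:
            continue
        A[[rank, piv]] = A[[piv, rank]]
        for r in range(rows):
            if r != rank and A[r, c]:
                A[r] ^= A[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def _gf2_rank_one_tensors(shape: tuple[int, ...]):
    """All distinct nonzero rank-one 0/1 tensors of the given shape."""
    seen = {}
    axes_vectors = [
        [v for v in itertools.product((0, 1), repeat=d) if any(v)] for d in shape
    ]
    for vecs in itertools.product(*axes_vectors):
        t = np.ones(shape, dtype=np.uint8)
        for axis, v in enumerate(vecs):
            sl = [None] * len(shape)
            sl[axis] = slice(None)
            t = t * np.asarray(v, dtype=np.uint8)[tuple(sl)]
        seen.setdefault(t.tobytes(), (t, vecs))
    return list(seen.values())


def _exact_rank_gf2(T: np.ndarray, max_rank: int) -> TensorRankResult:
    T = (np.asarray(T, dtype=int) % 2).astype(np.uint8)
    if not T.any():
        return TensorRankResult(0, "exact_small", False, max_rank, decomposition=[])
    lb = _flattening_rank_lb(T, gf2=True)
    rank1 = _gf2_rank_one_tensors(T.shape)
    for r in range(max(1, lb), max_rank + 1):
        for combo in itertools.combinations(rank1, r):
            total = np.zeros_like(T)
            for t, _ in combo:
                total ^= t
            if np.array_equal(total, T):
                return TensorRankResult(
                    r, "exact_small", False, max_rank,
                    decomposition=[vecs for _, vecs in combo],
                )
    return TensorRankResult(None, "exact_small", False, max_rank)


def _normalized_vector_patterns(d: int, prefix: str):
    """All rank-one factor vectors up to scale: zeros, then 1, then symbols."""
    pats = []
    for lead in range(d):
        v = [sp.Integer(0)] * lead + [sp.Integer(1)]
        v += [sp.Symbol(f"{prefix}_{k}") for k in range(lead + 1, d)]
        pats.append(v)
    return pats


def _rational_rank_le(T: np.ndarray, r: int) -> list[tuple] | None:
    """Decide whether T admits a rank-r decomposition; witness or None.

    The scaling freedom of each term is spent by normalizing the first
    nonzero entry of every factor except the last-mode one to 1; the
    finitely many leading-zero patterns are enumerated.  For each
    branch sympy decides the polynomial system; a Groebner basis {1}
    on every branch refutes rank <= r over the complex numbers.
    """
    shape = T.shape
    if r == 0:
        return [] if not np.any(T) else None
    entries = {
        idx: sp.Rational(T[idx]) for idx in itertools.product(*map(range, shape))
    }
    per_term_patterns = []
    for t in range(r):
        mode_choices = [
            _normalized_vector_patterns(shape[mode], f"x{t}m{mode}")
            for mode in range(len(shape) - 1)
        ]
        free = [sp.Symbol(f"x{t}m{len(shape)-1}_{k}") for k in range(shape[-1])]
        per_term_patterns.append((mode_choices, free))

    branch_sets = [
        itertools.product(*mode_choices) for mode_choices, _ in per_term_patterns
    ]
    inconclusive = False
    for branches in itertools.product(*branch_sets):
        eqs = []
        for idx in entries:
            total = sp.Integer(0)
            for t in range(r):
                factors = branches[t]
                free = per_term_patterns[t][1]
                term = sp.Integer(1)
                for mode in range(len(shape) - 1):
                    term *= factors[mode][idx[mode]]
                term *= free[idx[-1]]
                total += term
            eqs.append(sp.expand(total - entries[idx]))
        syms = sorted(set().union(*[e.free_symbols for e in eqs]), key=str)
        if not syms:
            if all(e == 0 for e in eqs):
                return [tuple(branches)]
            continue
        sols = sp.solve(eqs, syms, dict=True)
        real_sols = [
            sol for sol in sols
            if all(v.is_real is not False for v in sol.values() if v.is_number)
        ]
        for sol in real_sols:
            witness = []
            for t in range(r):
                vecs = [
                    tuple(sp.nsimplify(c.subs(sol)) for c in branches[t][mode])
                    for mode in range(len(shape) - 1)
                ]
                vecs.append(
                    tuple(sp.nsimplify(c.subs(sol)) for c in per_term_patterns[t][1])
                )
                witness.append(tuple(vecs))
            return witness
        if not sols:
            # no solution found: certify with a Nullstellensatz check; a
            # trivial Groebner basis proves the branch empty over C
            gb = sp.groebner(eqs, *syms, order="grevlex")
            if list(gb.exprs) != [sp.Integer(1)]:
                inconclusive = True
        else:
            # complex-only solutions: rank r is attained over C but no
            # real witness surfaced on this branch
            inconclusive = True
    if inconclusive:
        raise RuntimeError(
            f"exact_small could not certify rank <= {r}: a branch admits "
            "solutions that are not provably real; use als_upper_bound"
        )
    return None


def _exact_rank_rational(T: np.ndarray, max_rank: int) -> TensorRankResult:
    if not np.any(T):
        return TensorRankResult(0, "exact_small", False, max_rank, decomposition=[])
    lb = _flattening_rank_lb(T, gf2=False)
    # order-2 tensors are matrices: rank equals the flattening rank
    if T.ndim <= 2:
        return TensorRankResult(lb, "exact_small", False, max_rank)
    nnz_idx = [tuple(idx) for idx in np.argwhere(T != 0)]
    for r in range(max(1, lb), max_rank + 1):
        if len(nnz_idx) <= r:
            # constructive witness: one single-entry term per nonzero cell
            witness = []
            for idx in nnz_idx:
                vecs = []
                for mode, d in enumerate(T.shape):
                    v = [sp.Integer(0)] * d
                    v[idx[mode]] = sp.Rational(T[idx]) if mode == 0 else sp.Integer(1)
                    vecs.append(tuple(v))
                witness.append(tuple(vecs))
            return TensorRankResult(
                r, "exact_small", False, max_rank, decomposition=witness
            )
        witness = _rational_rank_le(T, r)
        if witness is not None:
            return TensorRankResult(
                r, "exact_small", False, max_rank, decomposition=witness
            )
    return TensorRankResult(None, "exact_small", False, max_rank)


# ---------------------------------------------------------------------------
# ALS upper bound
# ---------------------------------------------------------------------------

def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for M in mats[1:]:
        out = (out[:, None, :] * M[None, :, :]).reshape(-1, out.shape[1])
    return out


def cp_als(
    T: np.ndarray,
    rank: int,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-12,
) -> tuple[list[np.ndarray], float]:
    """CP decomposition by alternating least squares.

    Returns the factor matrices of the best restart and the relative
    Frobenius residual ``||T - T_hat|| / ||T||``.
    """
    T = np.asarray(T, dtype=float)
    norm_T = np.linalg.norm(T)
    if norm_T == 0 or rank == 0:
        return [np.zeros((d, rank)) for d in T.shape], 0.0
    rng = np.random.default_rng(seed)
    best_factors, best_res = None, np.inf
    unfoldings = [np.moveaxis(T, m, 0).reshape(T.shape[m], -1) for m in range(T.ndim)]
    for _ in range(n_restarts):
        factors = [rng.standard_normal((d, rank)) for d in T.shape]
        prev = np.inf
        for _ in range(max_iter):
            for mode in range(T.ndim):
                others = [factors[m] for m in range(T.ndim) if m != mode]
                kr = _khatri_rao(others)
                sol, *_ = np.linalg.lstsq(kr, unfoldings[mode].T, rcond=None)
                factors[mode] = sol.T
            approx = _khatri_rao([factors[m] for m in range(1, T.ndim)]) @ factors[0].T
            res = np.linalg.norm(unfoldings[0].T - approx) / norm_T
            if abs(prev - res) < tol * max(1.0, prev):
                break
            prev = res
        if res < best_res:
            best_res, best_factors = res, [f.copy() for f in factors]
        if best_res < tol:
            break
    return best_factors, float(best_res)


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def tensor_rank(
    T,
    mode: str = "exact_small",
    max_rank: int = EXACT_MAX_RANK,
    field: str = "rational",
    seed: int = 0,
    residual_tol: float = 1e-8,
    entry_cap: int = EXACT_ENTRY_CAP,
) -> TensorRankResult:
    """Rank of a small tensor, exactly or as an ALS upper bound.

    ``exact_small`` demands ``T.size <= entry_cap`` and
    ``max_rank <= 4`` (the algebraic search is combinatorial) and
    entries that are whole or small rationals; ``field`` selects GF(2)
    or rational arithmetic.  ``als_upper_bound`` accepts any real
    tensor and reports the smallest ``r <= max_rank`` whose CP fit
    residual drops below ``residual_tol`` — an upper bound only.
    """
    T = np.asarray(T)
    if mode == "exact_small":
        if T.size > entry_cap:
            raise ValueError(
                f"exact_small caps total entries at {entry_cap} (got {T.size}); "
                "use mode='als_upper_bound'"
            )
        if max_rank > EXACT_MAX_RANK:
            raise ValueError(f"exact_small caps max_rank at {EXACT_MAX_RANK}")
        if field == "gf2":
            return _exact_rank_gf2(T, max_rank)
        if field == "rational":
            return _exact_rank_rational(T, max_rank)
        raise ValueError(f"unknown field {field!r}")
    if mode == "als_upper_bound":
        Tf = np.asarray(T, dtype=float)
        if not np.any(Tf):
            return TensorRankResult(0, mode, True, max_rank, residual=0.0)
        for r in range(1, max_rank + 1):
            factors, res = cp_als(Tf, r, seed=seed)
            if res < residual_tol:
                return TensorRankResult(
                    r, mode, True, max_rank, decomposition=factors, residual=res
                )
        return TensorRankResult(None, mode, True, max_rank, residual=res)
    raise ValueError(f"unknown mode {mode!r}")
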