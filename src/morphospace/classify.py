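"""Cladistic versus functional correlation structure.

Two extreme shapes of a character matrix:

* A *cladistic* matrix records nested synapomorphies.  Its feature
  support sets (which carriers show state 1) form a laminar family —
  any two are nested or disjoint — which is the rooted-compatibility
  criterion for a perfect phylogeny with 0 ancestral.  Such a matrix
  has maximal rank: every character adds an independent distinction.

* A *functional* matrix records syndromes: blocks of features that are
  perfectly correlated because they serve one function (feeding type,
  climate ...).  Its rank is the number of blocks, far below maximal,
  and the blocks are recoverable from the empirical correlations alone.

State labels on categorical characters are arbitrary, so functional
clustering is defined label-freely: two features belong together iff
they induce the same partition of the carriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import algebra
from .errors import FieldError
from .matrix import CharacterMatrix

__all__ = [
    "CladisticReport",
    "FunctionalClustering",
    "RankSignature",
    "is_cladistic",
    "functional_clusters",
    "rank_signature",
    "cladistic_newick",
]


@dataclass
class CladisticReport:
    is_cladistic: bool
    carrier_order: list[str]
    feature_order: list[str]
    synapomorphies: dict            # feature id -> frozenset of carrier ids
    violations: list                # (feature, feature) pairs breaking laminarity


@dataclass
class FunctionalClustering:
    clusters: list[list[str]]                 # partition of the feature ids
    carrier_partitions: dict                  # cluster key -> partition of carriers
    numeric_rank_after_labeling: int
    relabeled: CharacterMatrix | None = None


@dataclass
class RankSignature:
    rank: int
    min_dim: int
    ratio: float
    verdict: str
    field_tag: str
    degenerate: bool = False


# ---------------------------------------------------------------------------

def is_cladistic(M: CharacterMatrix) -> CladisticReport:
    """Rooted perfect-phylogeny compatibility of a binary matrix.

    True iff every pair of feature supports is nested or disjoint.
    When true, carrier and feature orders exhibiting the staircase
    pattern are reported (for a strict ladder matrix, exactly the
    printed staircase), plus each feature's clade — the carrier set its
    derived state unites.
    """
    if M.field_tag != "gf2":
        raise FieldError("is_cladistic requires a gf2 matrix")
    M.require_complete()
    X = np.round(M.values).astype(int)
    n, m = X.shape
    supports = {
        M.feature_ids[j]: frozenset(M.carrier_ids[i] for i in range(n) if X[i, j])
        for j in range(m)
    }
    violations = []
    fids = M.feature_ids
    for a in range(m):
        for b in range(a + 1, m):
            A, B = supports[fids[a]], supports[fids[b]]
            if (A & B) and not (A <= B or B <= A):
                violations.append((fids[a], fids[b]))
    ok = not violations

    # staircase-exhibiting orders: features by decreasing support size,
    # carriers by increasing number of possessed features (ladder shape)
    feature_order = sorted(fids, key=lambda f: (-len(supports[f]), fids.index(f)))
    counts = X.sum(axis=1)
    carrier_order = sorted(
        M.carrier_ids, key=lambda c: (counts[M.carrier_ids.index(c)], M.carrier_ids.index(c))
    )
    return CladisticReport(
        is_cladistic=ok,
        carrier_order=carrier_order if ok else list(M.carrier_ids),
        feature_order=feature_order if ok else list(M.feature_ids),
        synapomorphies=supports,
        violations=violations,
    )


def cladistic_newick(report: CladisticReport) -> str:
    """Rooted tree implied by a laminar support family, as Newick.

    Each non-empty support set is a clade; parents are the minimal
    strict supersets; carriers hang below their smallest containing
    clade.
    """
    if not report.is_cladistic:
        raise ValueError("matrix is not cladistic; no tree is implied")
    clades = sorted(
        {s for s in report.synapomorphies.values() if s},
        key=lambda s: (-len(s), sorted(s)),
    )
    all_carriers = frozenset(report.carrier_order)
    if all_carriers not in clades:
        clades.insert(0, all_carriers)

    def children(clade):
        subs = [c for c in clades if c < clade]
        maximal = [
            c for c in subs if not any(c < d for d in subs)
        ]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        leaves = sorted(clade - covered)
        return maximal, leaves

    def render(clade):
        subs, leaves = children(clade)
        if not subs and len(leaves) == 1:
            return leaves[0]
        parts = [render(c) for c in sorted(subs, key=lambda s: sorted(s))] + leaves
        return "(" + ",".join(parts) + ")"

    return render(all_carriers) + ";"


# ---------------------------------------------------------------------------

def _column_partition(column, carrier_ids) -> frozenset:
    blocks: dict = {}
    for cid, v in zip(carrier_ids, column):
        blocks.setdefault(v, []).append(cid)
    return frozenset(frozenset(b) for b in blocks.values())


def functional_clusters(M: CharacterMatrix) -> FunctionalClustering:
    """Group features by the carrier partition they induce.

    Two categorical features are perfectly correlated — members of one
    functional syndrome — exactly when they split the carriers into the
    same blocks, regardless of how their states are labeled.  The
    matrix relabeled with canonical codes 1, 2, ... (order of first
    appearance down each column) makes correlated columns identical;
    its real rank is reported for comparison with the raw rank.
    """
    if M.field_tag not in ("integer", "gf2"):
        raise FieldError("functional_clusters requires categorical integer data")
    M.require_complete()
    X = np.round(M.values).astype(int)
    n, m = X.shape

    partitions = [
        _column_partition(X[:, j], M.carrier_ids) for j in range(m)
    ]
    clusters: list[list[str]] = []
    cluster_parts: list[frozenset] = []
    for j in range(m):
        for c, p in zip(clusters, cluster_parts):
            if partitions[j] == p:
                c.append(M.feature_ids[j])
                break
        else:
            clusters.append([M.feature_ids[j]])
            cluster_parts.append(partitions[j])

    carrier_partitions = {
        tuple(c): sorted(sorted(block) for block in p)
        for c, p in zip(clusters, cluster_parts)
    }

    # canonical relabeling: code by order of first appearance per column
    relabeled = np.zeros_like(X)
    for j in range(m):
        codes: dict = {}
        for i in range(n):
            v = X[i, j]
            if v not in codes:
                codes[v] = len(codes) + 1
            relabeled[i, j] = codes[v]
    relabeled_M = CharacterMatrix(
        relabeled.astype(float),
        carrier_ids=list(M.carrier_ids),
        feature_ids=list(M.feature_ids),
        field_tag="integer",
    )
    rank = algebra.matrix_rank(relabeled_M)
    return FunctionalClustering(
        clusters=clusters,
        carrier_partitions=carrier_partitions,
        numeric_rank_after_labeling=rank,
        relabeled=relabeled_M,
    )


# ---------------------------------------------------------------------------

def rank_signature(
    M: CharacterMatrix,
    tol: float = algebra.DEFAULT_TOL,
    functional_frac: float = 0.5,
) -> RankSignature:
    """Rank relative to the maximal possible, with a reporting verdict.

    ``cladistic-like`` at full rank, ``functional-like`` at or below
    ``functional_frac`` of ``min(n, m)`` (a configurable reporting
    convention, not a theorem), ``mixed`` in between.  A zero matrix is
    degenerate and flagged as such.
    """
    r = algebra.matrix_rank(M, tol=tol)
    md = min(M.shape)
    ratio = r / md
    if r == 0:
        return RankSignature(r, md, 0.0, "functional-like", M.field_tag, degenerate=True)
    if r == md:
        verdict = "cladistic-like"
    elif ratio <= functional_frac:
        verdict = "functional-like"
    else:
        verdict = "mixed"
    return RankSignature(r, md, ratio, verdict, M.field_tag)
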