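"""The carrier-by-feature character matrix.

A :class:`CharacterMatrix` tabulates the value ``c_ij`` of feature *j*
measured on carrier *i* (a species or higher taxon).  Rows are carriers,
columns are features.  Entries may be real measurements, integer counts or
codes, or 0/1 presence-absence, and the arithmetic used by downstream rank
operations depends on the declared field:

``real``
    measurements; rank is numerical (singular values above a tolerance).
``integer``
    counts or categorical codes; rank is exact over the rationals.
``gf2``
    presence/absence; rank is exact over the two-element field.

Missing entries (a carrier that does not possess a feature, or an
unmeasured cell) are carried in a boolean mask and rendered as ``?`` on
output.  The algebraic operations refuse incomplete matrices; the
geometric (section) view in :mod:`morphospace.presheaf` embraces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import FieldError, MissingDataError

FIELD_TAGS = ("real", "integer", "gf2")


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"values must be two-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class CharacterMatrix:
    """An ``n x m`` table of feature values over ``n`` carriers.

    Parameters
    ----------
    values : array-like of shape (n, m)
        The entries ``c_ij``.  Stored as floats; exact-field operations
        convert to rationals internally (integer/gf2 entries must be whole).
    carrier_ids, feature_ids : sequences of str, optional
        Unique row/column identifiers.  Default ``c1..cn`` / ``f1..fm``.
    field_tag : {"real", "integer", "gf2"}
    missing : boolean array of shape (n, m), optional
        True where the value is not defined for that carrier.
    """

    values: np.ndarray
    carrier_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    field_tag: str = "real"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = _as_2d(self.values)
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one carrier and one feature")
        if self.carrier_ids is None:
            self.carrier_ids = [f"c{i + 1}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"f{j + 1}" for j in range(m)]
        self.carrier_ids = [str(c) for c in self.carrier_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.carrier_ids) != n or len(self.feature_ids) != m:
            raise ValueError("id lists must match the matrix dimensions")
        if len(set(self.carrier_ids)) != n:
            raise ValueError("carrier_ids must be unique")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids must be unique")
        if self.field_tag not in FIELD_TAGS:
            raise FieldError(f"unknown field_tag {self.field_tag!r}; expected one of {FIELD_TAGS}")
        if self.missing is None:
            self.missing = np.isnan(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape must match values")
            self.missing = self.missing | np.isnan(self.values)
        present = self.values[~self.missing]
        if self.field_tag in ("integer", "gf2"):
            if present.size and not np.allclose(present, np.round(present)):
                raise FieldError(f"field {self.field_tag!r} requires whole-number entries")
        if self.field_tag == "gf2":
            if present.size and not np.all(np.isin(np.round(present), (0.0, 1.0))):
                bad = np.argwhere(~np.isin(np.round(self.values), (0.0, 1.0)) & ~self.missing)
                i, j = bad[0]
                raise FieldError(
                    f"gf2 matrix has non-binary entry {self.values[i, j]!r} at "
                    f"({self.carrier_ids[i]}, {self.feature_ids[j]})"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_carriers(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        return not bool(self.missing.any())

    def missing_cells(self) -> list[tuple[str, str]]:
        """(carrier_id, feature_id) pairs of all missing entries."""
        return [
            (self.carrier_ids[i], self.feature_ids[j])
            for i, j in np.argwhere(self.missing)
        ]

    def require_complete(self) -> None:
        """Raise :class:`MissingDataError` naming offending cells if any."""
        if not self.is_complete():
            raise MissingDataError(self.missing_cells())

    # -- views -------------------------------------------------------------
    def exact_rows(self) -> list[list[Fraction]]:
        """Entries as exact rationals (for integer/gf2 elimination)."""
        self.require_complete()
        return [
            [Fraction(int(round(v))) for v in row]
            for row in self.values
        ]

    def complete_column_subset(self) -> tuple["CharacterMatrix", list[str]]:
        """Restrict to the columns with no missing value.

        Returns the submatrix and the list of dropped feature ids.  This is
        the sanctioned route from partial data to the rank machinery, which
        refuses missing entries rather than imputing them.
        """
        keep = ~self.missing.any(axis=0)
        if not keep.any():
            raise MissingDataError(self.missing_cells())
        dropped = [f for f, k in zip(self.feature_ids, keep) if not k]
        sub = CharacterMatrix(
            self.values[:, keep],
            carrier_ids=list(self.carrier_ids),
            feature_ids=[f for f, k in zip(self.feature_ids, keep) if k],
            field_tag=self.field_tag,
            missing=self.missing[:, keep],
        )
        return sub, dropped

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            self.values.copy(),
            carrier_ids=list(self.carrier_ids),
            feature_ids=list(self.feature_ids),
            field_tag=self.field_tag,
            missing=self.missing.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CharacterMatrix({self.n_carriers} carriers x {self.n_features} features,"
            f" field={self.field_tag!r}, missing={int(self.missing.sum())})"
        )


def infer_field_tag(values, missing=None) -> str:
    """Suggest a field tag from the data.

    Whole-number data suggests ``integer`` (callers wanting GF(2) rank on
    0/1 data must ask for ``gf2`` explicitly, since rank depends on the
    field); anything else is ``real``.
    """
    arr = _as_2d(values)
    mask = np.isnan(arr) if missing is None else (np.asarray(missing, dtype=bool) | np.isnan(arr))
    present = arr[~mask]
    if present.size and np.allclose(present, np.round(present)):
        return "integer"
    return "real"
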