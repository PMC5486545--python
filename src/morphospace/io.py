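"""Readers and writers: CSV/TSV, NEXUS STANDARD, JSON (morphospace-v1).

Orientation is fixed: rows are carriers (taxa), columns are features
(characters).  CSV/TSV files carry the carrier id in the first column
and the feature ids in the header row; cells are numeric or ``?`` for
missing.  NEXUS CHARACTERS/DATA blocks with ``DATATYPE=STANDARD`` are
read through dendropy; state symbols map to integer codes by their
position in SYMBOLS (first symbol -> 0), ``?`` to missing and the gap
symbol to missing as well (logged).  All writers are deterministic.
"""

from __future__ import annotations

import io as _io
import json
import logging
from fractions import Fraction
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .algebra import FrequencyModel, RankDecomposition
from .errors import FormatError
from .matrix import CharacterMatrix, infer_field_tag
from .presheaf import ConstraintSet, FeatureSpace, GroupAction, Section

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "morphospace-v1"

__all__ = [
    "read_matrix",
    "write_matrix",
    "decomposition_to_json",
    "frequencies_to_json",
    "space_to_json",
    "space_from_json",
    "action_to_json",
    "action_from_json",
    "SCHEMA_VERSION",
]


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    if suffix in (".nex", ".nexus"):
        return "nexus"
    raise FormatError(f"cannot infer format from {path!r}; pass format= explicitly")


def read_matrix(source, format: str | None = None, field_tag: str | None = None) -> CharacterMatrix:
    """Read a carrier-by-feature matrix from CSV/TSV/NEXUS.

    ``source`` is a path or an open text handle (format required for
    handles).  ``field_tag`` overrides the inferred field; inference
    never chooses gf2 on its own since rank depends on the field.
    """
    if format is None:
        format = _infer_format(source)
    if format in ("csv", "tsv"):
        return _read_delimited(source, sep="," if format == "csv" else "\t", field_tag=field_tag)
    if format == "nexus":
        return _read_nexus(source, field_tag=field_tag)
    raise FormatError(f"unknown format {format!r}")


def _read_delimited(source, sep: str, field_tag: str | None) -> CharacterMatrix:
    try:
        df = pd.read_csv(source, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pandas raises many flavours on ragged/bad input
        raise FormatError(f"could not parse delimited file: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate carrier ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"duplicate feature ids: {dups}")
    n, m = df.shape
    values = np.zeros((n, m))
    missing = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            cell = df.iat[i, j]
            cell = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if cell in ("?", ""):
                missing[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"unparseable cell {cell!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
                    ) from exc
    tag = field_tag or infer_field_tag(values, missing)
    return CharacterMatrix(
        values,
        carrier_ids=[str(c) for c in df.index],
        feature_ids=[str(c) for c in df.columns],
        field_tag=tag,
        missing=missing,
    )


def _read_nexus(source, field_tag: str | None) -> CharacterMatrix:
    try:
        if hasattr(source, "read"):
            ds = dendropy.DataSet.get(data=source.read(), schema="nexus")
        else:
            ds = dendropy.DataSet.get(path=str(source), schema="nexus")
    except Exception as exc:
        raise FormatError(f"could not parse NEXUS: {exc}") from exc
    if not ds.char_matrices:
        raise FormatError("NEXUS file contains no CHARACTERS/DATA block")
    cm = ds.char_matrices[0]
    alphabet = cm.default_state_alphabet
    symbol_order = [
        s.symbol for s in alphabet._fundamental_states if not s.symbol == "-"
    ]
    code_of = {sym: k for k, sym in enumerate(symbol_order)}
    taxa = list(cm.taxon_namespace)
    rows, missing_rows = [], []
    gap_seen = False
    for taxon in taxa:
        seq = cm[taxon]
        row, miss = [], []
        for cell in seq:
            if cell.is_gap_state:
                gap_seen = True
                row.append(0.0)
                miss.append(True)
            elif cell.state_denomination != 0 or cell.symbol in ("?",):
                row.append(0.0)
                miss.append(True)
            elif cell.symbol in code_of:
                row.append(float(code_of[cell.symbol]))
                miss.append(False)
            else:
                raise FormatError(f"unknown state symbol {cell.symbol!r} for taxon {taxon.label!r}")
        rows.append(row)
        missing_rows.append(miss)
    if gap_seen:
        logger.info("NEXUS gap symbol treated as missing")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"ragged NEXUS matrix: row lengths {sorted(lengths)}")
    values = np.array(rows)
    missing = np.array(missing_rows, dtype=bool)
    m = values.shape[1]
    tag = field_tag or ("gf2" if len(symbol_order) <= 2 else "integer")
    M = CharacterMatrix(
        values,
        carrier_ids=[t.label for t in taxa],
        feature_ids=[f"char_{j + 1}" for j in range(m)],
        field_tag=tag,
        missing=missing,
    )
    M.state_symbols = symbol_order  # symbol text per integer code
    return M


def write_matrix(M: CharacterMatrix, target, format: str | None = None) -> None:
    """Write a matrix as CSV/TSV (``?`` for missing) or NEXUS STANDARD."""
    if format is None:
        format = _infer_format(target)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        cells = []
        integral = M.field_tag in ("integer", "gf2")
        for i in range(M.n_carriers):
            row = []
            for j in range(M.n_features):
                if M.missing[i, j]:
                    row.append("?")
                elif integral:
                    row.append(str(int(round(M.values[i, j]))))
                else:
                    row.append(repr(float(M.values[i, j])))
            cells.append(row)
        df = pd.DataFrame(cells, index=M.carrier_ids, columns=M.feature_ids)
        df.to_csv(target, sep=sep, index_label="carrier")
        return
    if format == "nexus":
        if M.field_tag == "real":
            raise FormatError("NEXUS STANDARD output requires integer or gf2 codes")
        codes = np.round(M.values).astype(int)
        top = int(codes[~M.missing].max()) if (~M.missing).any() else 0
        if top > 9:
            raise FormatError("NEXUS STANDARD writer supports codes 0..9")
        symbols = "".join(str(d) for d in range(top + 1))
        lines = ["#NEXUS", "BEGIN TAXA;", f"    DIMENSIONS NTAX={M.n_carriers};"]
        labels = " ".join(_nexus_label(c) for c in M.carrier_ids)
        lines += [f"    TAXLABELS {labels};", "END;", "BEGIN CHARACTERS;"]
        lines += [
            f"    DIMENSIONS NCHAR={M.n_features};",
            f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        width = max(len(_nexus_label(c)) for c in M.carrier_ids) + 2
        for i, cid in enumerate(M.carrier_ids):
            states = "".join(
                "?" if M.missing[i, j] else str(codes[i, j]) for j in range(M.n_features)
            )
            lines.append(f"    {_nexus_label(cid):<{width}}{states}")
        lines += ["    ;", "END;", ""]
        text = "\n".join(lines)
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text)
        return
    raise FormatError(f"unknown format {format!r}")


def _nexus_label(label: str) -> str:
    # underscores must be quoted: unquoted they denote spaces in NEXUS
    if any(ch.isspace() or ch in "()[]{}/\\,;:=*'\"`<>^-_" for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# JSON reports (schema morphospace-v1)
# ---------------------------------------------------------------------------

def _num(x):
    if isinstance(x, Fraction):
        return {"fraction": [x.numerator, x.denominator], "value": float(x)}
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def _vector(v):
    return [_num(x) for x in np.asarray(v).tolist()]


def dumps(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2, default=_num)


def decomposition_to_json(
    dec: RankDecomposition, feature_ids=None, carrier_ids=None, tol=None, seed=None
) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "type": "rank_decomposition",
        "field_tag": dec.field_tag,
        "rank": dec.rank,
        "reconstruction_error": dec.reconstruction_error,
        "tolerance": tol,
        "seed": seed,
        "carrier_ids": carrier_ids,
        "feature_ids": feature_ids,
        "terms": [
            {"carrier_factors": _vector(a), "feature_combination": _vector(b)}
            for a, b in dec.terms
        ],
    }


def frequencies_to_json(F: FrequencyModel, tol=None, seed=None) -> dict:
    out = {
        "schema": SCHEMA_VERSION,
        "type": "frequency_model",
        "convention": F.convention,
        "feature_ids": F.feature_ids,
        "tolerance": tol,
        "seed": seed,
    }
    if F.marginals is not None:
        out["marginals"] = _vector(F.marginals)
    if F.pairwise is not None:
        out["pairwise"] = [_vector(row) for row in F.pairwise]
    if F.cooccurrence is not None:
        out["cooccurrence"] = [_vector(row) for row in F.cooccurrence]
        out["Z"] = _num(F.Z)
    return out


def _value_out(v):
    return v if isinstance(v, (int, float, str, bool)) else repr(v)


def space_to_json(space: FeatureSpace) -> dict:
    out = {
        "schema": SCHEMA_VERSION,
        "type": "feature_space",
        "base": list(space.base),
        "fibers": {j: [_value_out(v) for v in space.fibers[j]] for j in space.base},
    }
    if space.constraints is not None:
        out["admissible"] = [section_to_json(s) for s in space.constraints]
    return out


def section_to_json(s: Section) -> dict:
    return {
        "label": s.label,
        "assignment": {j: _value_out(v) for j, v in s.assignment},
    }


def space_from_json(data: dict) -> FeatureSpace:
    if data.get("schema") != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema {data.get('schema')!r}")
    constraints = None
    if "admissible" in data:
        constraints = ConstraintSet(
            Section(d["assignment"], label=d.get("label", "")) for d in data["admissible"]
        )
    return FeatureSpace(
        tuple(data["base"]),
        {j: tuple(v) for j, v in data["fibers"].items()},
        constraints=constraints,
    )


def action_to_json(G: GroupAction) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "type": "group_action",
        "elements": list(G.elements),
        "identity": G.identity,
        "table": [[g, h, gh] for (g, h), gh in sorted(G.table.items())],
        "action": [
            {
                "element": g,
                "feature": j,
                "map": [[_value_out(x), _value_out(y)] for x, y in sorted(amap.items(), key=lambda kv: repr(kv[0]))],
            }
            for (g, j), amap in sorted(G.action.items())
        ],
    }


def action_from_json(data: dict) -> GroupAction:
    if data.get("schema") != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema {data.get('schema')!r}")
    table = {(g, h): gh for g, h, gh in data["table"]}
    action = {
        (entry["element"], entry["feature"]): {x: y for x, y in entry["map"]}
        for entry in data["action"]
    }
    return GroupAction(tuple(data["elements"]), data["identity"], table, action)
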