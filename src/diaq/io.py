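"""Reading and writing the external table formats.

Canonical inputs are plain UTF-8 TSV: a long-format precursor report (one row
per observed (sample, precursor) pair), a study-design table, and GMT gene
sets.  A *dialect* maps vendor column names onto the canonical schema so that
e.g. a Spectronaut-style export can be ingested without renaming columns by
hand.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, QuantMatrix, StudyDesign, split_precursor_id

__all__ = [
    "CANONICAL_DIALECT",
    "SPECTRONAUT_DIALECT",
    "read_precursor_report",
    "read_design",
    "read_gmt",
    "write_table",
    "write_matrix",
    "read_matrix",
]

#: Canonical column names of the long-format precursor report.
CANONICAL_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "precursor_id": "precursor_id",
    "protein_group_id": "protein_group_id",
    "intensity": "intensity",
    "precursor_qvalue": "precursor_qvalue",
    "protein_qvalue": "protein_qvalue",
}

#: Mapping for Spectronaut-style report headers onto the canonical schema.
SPECTRONAUT_DIALECT: dict[str, str] = {
    "sample_id": "R.FileName",
    "precursor_id": "EG.PrecursorId",
    "protein_group_id": "PG.ProteinGroups",
    "intensity": "EG.TotalQuantity (Settings)",
    "precursor_qvalue": "EG.Qvalue",
    "protein_qvalue": "PG.Qvalue",
}

_MANDATORY = ("sample_id", "precursor_id", "protein_group_id", "intensity")


class FormatError(ValueError):
    """A file does not conform to its expected tabular format."""


def read_precursor_report(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> QuantMatrix:
    """Read a long-format precursor report and pivot it to a QuantMatrix.

    Absent (sample, precursor) combinations and zero intensities become
    missing entries; precursor/protein Q-values, when present, are carried
    alongside the matrix in frames of identical shape.

    Raises
    ------
    FormatError
        If a mandatory column is absent (named in the message) or the file
        contains duplicate (sample, precursor) rows.
    """
    dialect = dict(CANONICAL_DIALECT if dialect is None else dialect)
    long = pd.read_csv(path, sep="\t", dtype={dialect["sample_id"]: str})

    for canon in _MANDATORY:
        src = dialect.get(canon, canon)
        if src not in long.columns:
            raise FormatError(f"precursor report is missing mandatory column {src!r}")
    rename = {src: canon for canon, src in dialect.items() if src in long.columns}
    long = long.rename(columns=rename)

    dup = long.duplicated(subset=["sample_id", "precursor_id"])
    if dup.any():
        first = long.loc[dup, ["sample_id", "precursor_id"]].iloc[0]
        raise FormatError(
            f"duplicate (sample, precursor) row: "
            f"({first['sample_id']!r}, {first['precursor_id']!r})"
        )

    long["intensity"] = pd.to_numeric(long["intensity"], errors="coerce")
    if (long["intensity"].dropna() < 0).any():
        raise FormatError("negative intensity in precursor report")
    # Detection-limit semantics: a stored 0 carries no quantity information.
    long.loc[long["intensity"] == 0, "intensity"] = np.nan

    for qcol in ("precursor_qvalue", "protein_qvalue"):
        if qcol in long.columns:
            q = pd.to_numeric(long[qcol], errors="coerce")
            bad = q.dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise FormatError(f"{qcol} outside [0, 1]")
            long[qcol] = q

    values = long.pivot(index="precursor_id", columns="sample_id", values="intensity")
    values = values.rename_axis(index=None, columns=None)

    meta = long.drop_duplicates("precursor_id").set_index("precursor_id")
    groups = meta["protein_group_id"].reindex(values.index)
    seq_charge = [split_precursor_id(p) for p in values.index]
    rows = pd.DataFrame(
        {
            "protein_group_id": groups,
            "peptide_sequence": [s for s, _ in seq_charge],
            "charge": [c for _, c in seq_charge],
        },
        index=values.index,
    )

    def _pivot_q(col: str) -> pd.DataFrame | None:
        if col not in long.columns:
            return None
        q = long.pivot(index="precursor_id", columns="sample_id", values=col)
        return q.rename_axis(index=None, columns=None).reindex(
            index=values.index, columns=values.columns
        )

    return QuantMatrix(
        values=values,
        rows=rows,
        log_scale=False,
        precursor_q=_pivot_q("precursor_qvalue"),
        protein_q=_pivot_q("protein_qvalue"),
    )


def read_design(
    path: str | Path, cell_types: tuple[str, ...] | None = None
) -> StudyDesign:
    """Read a TSV design table (sample_id, donor_id, cell_type,
    replicate_group and optionally load, run_order)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise FormatError("design is missing mandatory column 'sample_id'")
    if len(table) == 0:
        raise FormatError("design contains no samples")
    table = table.set_index("sample_id")
    return StudyDesign(table, cell_types=cell_types)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, a set name, a description, then members."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = tuple(dict.fromkeys(m for m in members if m))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic column order and
    missing values rendered as ``NA``."""
    result.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Persist a QuantMatrix as wide TSV (metadata columns first)."""
    out = pd.concat([matrix.rows, matrix.values], axis=1)
    out.insert(0, "precursor_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path: str | Path) -> QuantMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    wide = pd.read_csv(path, sep="\t", na_values=["NA"])
    wide = wide.set_index("precursor_id").rename_axis(index=None)
    meta_cols = ["protein_group_id", "peptide_sequence", "charge"]
    rows = wide[meta_cols]
    values = wide.drop(columns=meta_cols).astype(float)
    return QuantMatrix(values=values, rows=rows, log_scale=False)
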