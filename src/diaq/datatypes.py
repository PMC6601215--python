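"""Core domain objects for the DIA quantification pipeline.

The central object is the :class:`QuantMatrix`, a precursor × sample
intensity matrix with an explicit missing mask (NaN), carrying per-precursor
metadata (protein group, peptide sequence, charge) and, optionally, the
precursor- and protein-level Q-values of each entry.  A
:class:`StudyDesign` annotates the samples (donor, cell type, replicate
group, load) and drives all grouping, filtering and contrasts downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "StudyDesign",
    "GeneSetCollection",
    "split_precursor_id",
]

_PRECURSOR_RE = re.compile(r"^(?P<seq>.+)\.(?P<charge>\d+)$")


def split_precursor_id(precursor_id: str) -> tuple[str, int]:
    """Split a precursor token like ``"PEPTIDER.2"`` into (sequence, charge).

    A token without a trailing ``.<charge>`` is treated as charge 0 with the
    whole string as sequence, so foreign identifier schemes degrade gracefully
    (every charge state then counts as its own peptide).
    """
    m = _PRECURSOR_RE.match(precursor_id)
    if m is None:
        return precursor_id, 0
    return m.group("seq"), int(m.group("charge"))


@dataclass
class StudyDesign:
    """Sample annotations: one row per sample_id.

    Parameters
    ----------
    table
        DataFrame indexed by unique ``sample_id`` with columns ``donor_id``,
        ``cell_type``, ``replicate_group`` and optionally ``load`` and
        ``run_order``.
    cell_types
        Optional controlled vocabulary; when given, any sample annotated
        with a cell type outside it raises ``ValueError``.
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("study design contains no samples")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id in design: {dups}")
        for col in ("donor_id", "cell_type", "replicate_group"):
            if col not in self.table.columns:
                raise ValueError(f"design is missing required column {col!r}")
        if self.cell_types is not None:
            unknown = set(self.table["cell_type"]) - set(self.cell_types)
            if unknown:
                raise ValueError(f"unknown cell types in design: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def donors(self) -> list[str]:
        return sorted(self.table["donor_id"].unique())

    @property
    def observed_cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def replicate_groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["replicate_group"]))

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["replicate_group"] == group])

    def sample_for(self, donor: str, cell_type: str) -> str:
        sel = self.table.index[
            (self.table["donor_id"] == donor) & (self.table["cell_type"] == cell_type)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"expected exactly one sample for donor={donor!r}, "
                f"cell_type={cell_type!r}; found {len(sel)}"
            )
        return sel[0]

    def load_of_group(self, group: str):
        loads = self.table.loc[self.table["replicate_group"] == group, "load"].unique()
        if len(loads) != 1:
            raise ValueError(f"replicate group {group!r} has mixed loads: {loads}")
        return loads[0]


@dataclass
class QuantMatrix:
    """Precursor × sample intensity matrix with an explicit missing mask.

    ``values`` is a float DataFrame (rows indexed by precursor_id, columns by
    sample_id) where NaN marks a missing entry.  ``rows`` holds per-precursor
    metadata aligned on the same index: ``protein_group_id``,
    ``peptide_sequence``, ``charge``.  Q-value frames, when present, share
    the exact shape of ``values``.
    """

    values: pd.DataFrame
    rows: pd.DataFrame
    log_scale: bool = False
    precursor_q: pd.DataFrame | None = None
    protein_q: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate precursor_id rows in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample_id columns in matrix")
        if not self.rows.index.equals(self.values.index):
            raise ValueError("row metadata index does not match matrix rows")
        if "protein_group_id" not in self.rows.columns:
            raise ValueError("row metadata must carry protein_group_id")
        for q in (self.precursor_q, self.protein_q):
            if q is not None and q.shape != self.values.shape:
                raise ValueError("Q-value frame shape does not match matrix")
        self.values = self.values.astype(float)

    # -- shape and missingness -------------------------------------------
    @property
    def n_precursors(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_entries(self) -> int:
        return self.values.size

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the entry is observed."""
        return self.values.notna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    @property
    def n_observed(self) -> int:
        return self.n_entries - self.n_missing

    @property
    def protein_group_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["protein_group_id"]))

    # -- derived views ----------------------------------------------------
    def subset_rows(self, precursor_ids) -> "QuantMatrix":
        idx = pd.Index(precursor_ids)
        return QuantMatrix(
            values=self.values.loc[idx],
            rows=self.rows.loc[idx],
            log_scale=self.log_scale,
            precursor_q=None if self.precursor_q is None else self.precursor_q.loc[idx],
            protein_q=None if self.protein_q is None else self.protein_q.loc[idx],
        )

    def with_values(self, values: pd.DataFrame, log_scale: bool | None = None) -> "QuantMatrix":
        return QuantMatrix(
            values=values,
            rows=self.rows.loc[values.index],
            log_scale=self.log_scale if log_scale is None else log_scale,
            precursor_q=None if self.precursor_q is None else self.precursor_q.loc[values.index],
            protein_q=None if self.protein_q is None else self.protein_q.loc[values.index],
        )

    def to_log2(self) -> "QuantMatrix":
        if self.log_scale:
            return self
        with np.errstate(divide="ignore"):
            return self.with_values(np.log2(self.values), log_scale=True)

    def to_long(self) -> pd.DataFrame:
        """Unpivot to long format, dropping missing entries."""
        long = (
            self.values.stack()
            .rename("intensity")
            .reset_index()
            .rename(columns={"level_0": "precursor_id", "level_1": "sample_id"})
        )
        long.columns = ["precursor_id", "sample_id", "intensity"]
        return long[["sample_id", "precursor_id", "intensity"]]

    def check_design(self, design: StudyDesign) -> None:
        """Every matrix column must be annotated in the design."""
        missing = set(self.values.columns) - set(design.table.index)
        if missing:
            raise ValueError(f"samples in matrix absent from design: {sorted(missing)}")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological processes) with unique names and
    deduplicated members."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, members in self.sets.items():
            clean[name] = tuple(dict.fromkeys(members))
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def filtered(self, universe, min_size: int = 5) -> "GeneSetCollection":
        """Restrict members to ``universe`` and drop sets below ``min_size``."""
        uni = set(universe)
        kept = {
            name: tuple(g for g in members if g in uni)
            for name, members in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if len(m) >= min_size}
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )
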