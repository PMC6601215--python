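"""The precursor-matrix processing chain for the donor × cell-type cohort.

Stage order is fixed: Q-value filter → design-consistency filter →
minimum-peptide filter → detection-limit imputation → total-ion-current
normalization.  Each stage takes and returns a :class:`QuantMatrix`;
:func:`process_chain` runs them in order and accumulates a
:class:`ProcessingReport` of the counts before and after every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import QuantMatrix, StudyDesign

__all__ = [
    "ProcessingReport",
    "MissingnessSummary",
    "filter_qvalue",
    "filter_design_consistency",
    "filter_min_peptides",
    "missingness_summary",
    "missingness_from_counts",
    "impute_missing",
    "normalize_tic",
    "process_chain",
]


@dataclass(frozen=True)
class MissingnessSummary:
    """Arithmetic identities of a precursor matrix's missingness."""

    n_entries: int
    n_samples: int
    n_missing: int

    @property
    def n_precursors(self) -> int:
        return self.n_entries // self.n_samples

    @property
    def n_observed(self) -> int:
        return self.n_entries - self.n_missing

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_entries

    @property
    def avg_missing_per_precursor(self) -> float:
        return self.n_missing / self.n_precursors


@dataclass
class ProcessingReport:
    """Per-stage counts plus normalization factors of one pipeline run."""

    stages: list[dict] = field(default_factory=list)
    normalization_factors: pd.Series | None = None
    missingness: MissingnessSummary | None = None

    def record(self, stage: str, matrix: QuantMatrix) -> None:
        self.stages.append(
            {
                "stage": stage,
                "n_precursors": matrix.n_precursors,
                "n_protein_groups": len(set(matrix.rows["protein_group_id"])),
                "n_entries": matrix.n_entries,
                "n_missing": matrix.n_missing,
            }
        )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def missingness_from_counts(
    n_entries: int, n_samples: int, n_missing: int
) -> MissingnessSummary:
    """Missingness identities from raw counts: number of precursors
    (entries / samples), missing fraction and average missing values per
    precursor."""
    if n_samples <= 0 or n_entries <= 0:
        raise ValueError("n_entries and n_samples must be positive")
    if n_entries % n_samples != 0:
        raise ValueError("n_entries must be a multiple of n_samples")
    if not 0 <= n_missing <= n_entries:
        raise ValueError("n_missing out of range")
    return MissingnessSummary(int(n_entries), int(n_samples), int(n_missing))


def missingness_summary(matrix: QuantMatrix) -> MissingnessSummary:
    """Missingness identities of a QuantMatrix (missing entries count as
    entries)."""
    return missingness_from_counts(matrix.n_entries, matrix.n_samples, matrix.n_missing)


def filter_qvalue(
    matrix: QuantMatrix,
    protein_q_cut: float = 0.01,
    precursor_q_cut: float = 0.01,
) -> QuantMatrix:
    """Blank entries whose precursor or protein Q-value exceeds its cutoff;
    drop rows left with no surviving entry.

    Requires Q-value frames on the matrix.
    """
    if matrix.precursor_q is None or matrix.protein_q is None:
        raise ValueError("Q-value filtering requested but Q-values are absent")
    fail = (matrix.precursor_q > precursor_q_cut) | (matrix.protein_q > protein_q_cut)
    values = matrix.values.mask(fail.fillna(False))
    out = matrix.with_values(values)
    keep = out.values.notna().any(axis=1)
    return out.subset_rows(out.values.index[keep])


def _presence_grid(present_row: pd.Series, design: StudyDesign) -> pd.DataFrame:
    """Donor × cell-type presence grid for one precursor."""
    tab = design.table.copy()
    tab["present"] = present_row.reindex(tab.index).to_numpy()
    return tab.pivot_table(
        index="donor_id", columns="cell_type", values="present", aggfunc="any"
    ).fillna(False)


def filter_design_consistency(
    matrix: QuantMatrix, design: StudyDesign
) -> QuantMatrix:
    """Keep precursors present (i) in all donors for at least one cell type,
    or (ii) in all cell types for at least one donor."""
    matrix.check_design(design)
    present = matrix.mask
    donors = design.table["donor_id"]
    cts = design.table["cell_type"]
    # precursor × cell type: observed in every donor of that cell type
    by_ct = present.T.groupby(cts).all().T
    # precursor × donor: observed in every cell type of that donor
    by_donor = present.T.groupby(donors).all().T
    keep = by_ct.any(axis=1) | by_donor.any(axis=1)
    return matrix.subset_rows(matrix.values.index[keep])


def filter_min_peptides(
    matrix: QuantMatrix, min_distinct_peptides: int = 2
) -> QuantMatrix:
    """Remove precursors of protein groups covered by fewer than
    ``min_distinct_peptides`` distinct peptide sequences (charge states of
    one sequence count as a single peptide)."""
    n_seq = matrix.rows.groupby("protein_group_id")["peptide_sequence"].nunique()
    keep_groups = set(n_seq.index[n_seq >= min_distinct_peptides])
    keep = matrix.rows["protein_group_id"].isin(keep_groups)
    return matrix.subset_rows(matrix.values.index[keep])


def impute_missing(
    matrix: QuantMatrix, lo: float = 0.7, hi: float = 0.9, seed: int = 0
) -> QuantMatrix:
    """Replace each missing entry by a uniform draw on
    ``[lo·m, hi·m]`` where ``m`` is the row minimum over observed entries.

    Observed entries are untouched; the draw is deterministic in ``seed``.
    """
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    values = matrix.values
    missing = values.isna()
    if not missing.any().any():
        return matrix
    row_min = values.min(axis=1)
    if row_min.isna().any():
        bad = list(values.index[row_min.isna()])[:5]
        raise ValueError(f"cannot impute all-missing rows, e.g. {bad}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=values.shape)
    fill = draws * row_min.to_numpy()[:, None]
    out = values.to_numpy().copy()
    m = missing.to_numpy()
    out[m] = fill[m]
    return matrix.with_values(
        pd.DataFrame(out, index=values.index, columns=values.columns)
    )


def normalize_tic(
    matrix: QuantMatrix, observed_only: bool = False
) -> tuple[QuantMatrix, pd.Series]:
    """Total-ion-current normalization.

    Per sample *s* with column sum ``T_s``, the factor is
    ``mean_j(T_j) / T_s`` and every intensity in the column is multiplied by
    it; afterwards all column sums equal the pre-normalization grand mean.
    By default the matrix must be complete (post-imputation); with
    ``observed_only=True`` sums run over observed entries only.
    """
    values = matrix.values
    if not observed_only and values.isna().any().any():
        raise ValueError(
            "matrix has missing entries; impute first or pass observed_only=True"
        )
    sums = values.sum(axis=0, skipna=True)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"column(s) with non-positive total signal: {bad}")
    factors = sums.mean() / sums
    factors.name = "normalization_factor"
    return matrix.with_values(values * factors), factors


def process_chain(
    matrix: QuantMatrix,
    design: StudyDesign,
    protein_q_cut: float = 0.01,
    precursor_q_cut: float = 0.01,
    min_distinct_peptides: int = 2,
    impute_lo: float = 0.7,
    impute_hi: float = 0.9,
    seed: int = 0,
) -> tuple[QuantMatrix, ProcessingReport]:
    """Run the full chain (Q-value → consistency → min-peptides → impute →
    TIC-normalize) and report per-stage counts.

    The missingness summary in the report describes the filtered matrix as
    it enters imputation.
    """
    report = ProcessingReport()
    report.record("input", matrix)
    m = filter_qvalue(matrix, protein_q_cut, precursor_q_cut)
    report.record("qvalue_filter", m)
    m = filter_design_consistency(m, design)
    report.record("consistency_filter", m)
    m = filter_min_peptides(m, min_distinct_peptides)
    report.record("min_peptide_filter", m)
    report.missingness = missingness_summary(m)
    m = impute_missing(m, impute_lo, impute_hi, seed=seed)
    report.record("imputation", m)
    m, factors = normalize_tic(m)
    report.record("tic_normalization", m)
    report.normalization_factors = factors
    return m, report
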