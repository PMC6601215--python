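"""Dilution-series QC statistics.

Benchmarking operates on raw linear intensities as exported — no filtering,
imputation or normalization — and summarises, per replicate group:

* per-precursor coefficients of variation (SD/mean over observed replicates),
* identification counts at precursor and protein-group level, split into
  union (seen in >=1 replicate) and intersection (seen in all replicates),
* per-precursor log2 fold changes of average intensity against a reference
  group, to assess quantitative linearity along the series.

Also provides the peptide-mass extrapolation used to translate sorted-cell
counts into on-column peptide loads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import QuantMatrix, StudyDesign

__all__ = [
    "BenchmarkSummary",
    "replicate_cv",
    "identification_counts",
    "foldchange_vs_reference",
    "injectable_fraction",
    "injected_peptide_mass",
]


@dataclass
class BenchmarkSummary:
    """Container accumulating benchmark statistics per replicate group."""

    #: per-group Series of per-precursor CVs (index precursor_id)
    cv: dict[str, pd.Series] = field(default_factory=dict)
    #: per-(group, level) identification counts
    counts: pd.DataFrame | None = None
    #: per-(group, reference) Series of per-precursor log2 fold changes
    fold_changes: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def median_cv(self, group: str) -> float:
        return float(self.cv[group].median())

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate_group": list(self.cv),
                "n_precursors": [len(v) for v in self.cv.values()],
                "median_cv": [float(v.median()) for v in self.cv.values()],
            }
        )

    def foldchange_table(self) -> pd.DataFrame:
        rows = []
        for (group, ref), fc in self.fold_changes.items():
            q1, med, q3 = fc.quantile([0.25, 0.5, 0.75])
            rows.append(
                {
                    "replicate_group": group,
                    "reference_group": ref,
                    "n_precursors": len(fc),
                    "median_log2fc": med,
                    "q1_log2fc": q1,
                    "q3_log2fc": q3,
                }
            )
        return pd.DataFrame(rows)


def replicate_cv(
    matrix: QuantMatrix,
    design: StudyDesign,
    summary: BenchmarkSummary | None = None,
) -> BenchmarkSummary:
    """Per-precursor CV = sample SD (n−1) / mean of the raw linear
    intensities over the observed replicates of each group.

    A precursor contributes to a group's CV distribution only when observed
    in at least two of its replicates; groups with fewer than two samples
    are skipped with a warning.
    """
    if matrix.log_scale:
        raise ValueError("CVs are defined on raw linear intensities")
    matrix.check_design(design)
    summary = summary or BenchmarkSummary()
    for group in design.replicate_groups:
        samples = design.samples_in_group(group)
        if len(samples) < 2:
            warnings.warn(f"replicate group {group!r} has <2 samples; skipped")
            continue
        sub = matrix.values[samples]
        n_obs = sub.notna().sum(axis=1)
        sub = sub.loc[n_obs >= 2]
        cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        summary.cv[group] = cv
    return summary


def identification_counts(
    matrix: QuantMatrix,
    design: StudyDesign,
    summary: BenchmarkSummary | None = None,
) -> BenchmarkSummary:
    """Union and intersection identification counts per replicate group, at
    precursor and protein-group level.

    A protein group counts as present in a replicate when at least one of
    its precursors is observed there.
    """
    matrix.check_design(design)
    summary = summary or BenchmarkSummary()
    present = matrix.mask
    groups_of = matrix.rows["protein_group_id"]
    rows = []
    for group in design.replicate_groups:
        samples = design.samples_in_group(group)
        sub = present[samples]
        prec_union = int((sub.any(axis=1)).sum()) if samples else 0
        prec_inter = int((sub.all(axis=1)).sum()) if samples else 0
        prot_present = sub.groupby(groups_of).any()  # protein × replicate
        prot_union = int(prot_present.any(axis=1).sum()) if samples else 0
        prot_inter = int(prot_present.all(axis=1).sum()) if samples else 0
        rows.append(
            {
                "replicate_group": group,
                "n_replicates": len(samples),
                "n_precursors_union": prec_union,
                "n_precursors_intersection": prec_inter,
                "n_protein_groups_union": prot_union,
                "n_protein_groups_intersection": prot_inter,
            }
        )
    counts = pd.DataFrame(rows)
    summary.counts = (
        counts
        if summary.counts is None
        else pd.concat([summary.counts, counts], ignore_index=True)
    )
    return summary


def foldchange_vs_reference(
    matrix: QuantMatrix,
    design: StudyDesign,
    group: str,
    reference_group: str,
    summary: BenchmarkSummary | None = None,
) -> BenchmarkSummary:
    """Per-precursor log2 fold change of the average linear intensity in
    ``group`` relative to ``reference_group``.

    Averages are taken on the linear scale over observed replicates, then
    log2-transformed; a precursor enters only if observed at least once in
    both groups.
    """
    if matrix.log_scale:
        raise ValueError("fold changes are computed from linear intensities")
    matrix.check_design(design)
    summary = summary or BenchmarkSummary()
    g = matrix.values[design.samples_in_group(group)].mean(axis=1)
    r = matrix.values[design.samples_in_group(reference_group)].mean(axis=1)
    both = g.notna() & r.notna()
    if not both.any():
        warnings.warn(
            f"groups {group!r} and {reference_group!r} share no observed "
            "precursors"
        )
        summary.fold_changes[(group, reference_group)] = pd.Series(dtype=float)
        return summary
    fc = np.log2(g[both]) - np.log2(r[both])
    summary.fold_changes[(group, reference_group)] = fc
    return summary


# ---------------------------------------------------------------------------
# peptide-mass extrapolation


def injectable_fraction(inject_volume_ul: float = 8.0,
                        resuspend_volume_ul: float = 11.0) -> float:
    """Fraction of the recovered peptide mass the autosampler can inject
    (default 8 of 11 μl)."""
    if not 0 < inject_volume_ul <= resuspend_volume_ul:
        raise ValueError("inject volume must be in (0, resuspend volume]")
    return inject_volume_ul / resuspend_volume_ul


def injected_peptide_mass(
    n_cells: float,
    recovered_ug: float = 3.2,
    reference_cells: float = 200_000,
    inject_volume_ul: float = 8.0,
    resuspend_volume_ul: float = 11.0,
) -> float:
    """Extrapolated on-column peptide mass in ng for ``n_cells`` sorted
    cells, assuming recovery proportional to cell count.

    With the defaults (3.2 μg recovered from 200,000 cells, 8/11 μl
    injectable) this gives ≈2,327 ng at 200,000 cells and ≈291 ng at
    25,000 cells.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    frac = injectable_fraction(inject_volume_ul, resuspend_volume_ul)
    return recovered_ug * 1000.0 * frac * (n_cells / reference_cells)
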