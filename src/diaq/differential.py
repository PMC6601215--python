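"""Protein-level differential analysis across one-vs-rest cell-type
contrasts, and presence/absence (on/off) calling.

The protein roll-up is a stable-peptide procedure: peptide-level log2
intensities are winsorized (per-peptide mean ± 2 SD), peptides whose median
Pearson correlation with the protein's other peptides falls below a cutoff
are discarded (keeping at least the best two), and the protein's
one-vs-rest log2 fold change is the median, over selected peptides and
donors, of the within-donor difference between the target cell type and the
mean of the remaining cell types.  Inference is a two-sided paired test of
the per-donor protein-level differences against zero (donors are the
replicates), with Benjamini–Hochberg correction across proteins.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import QuantMatrix, StudyDesign

__all__ = [
    "select_stable_peptides",
    "winsorize_outliers",
    "peptide_rollup",
    "protein_contrast",
    "call_on_off",
]


def select_stable_peptides(
    protein_rows: pd.DataFrame, min_median_corr: float = 0.2
) -> pd.Index:
    """Select peptides of one protein whose median Pearson correlation with
    the protein's other peptides meets the cutoff.

    ``protein_rows`` is a peptide × sample log2 intensity frame with >=2
    rows.  If the cutoff would leave fewer than two peptides, the two with
    the highest median correlation are kept instead.
    """
    if protein_rows.shape[1] < 2:
        raise ValueError("need >=2 samples to correlate peptides")
    if protein_rows.shape[0] < 2:
        raise ValueError("stable-peptide selection needs >=2 peptides")
    corr = np.corrcoef(protein_rows.to_numpy())
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, np.nan)
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(corr, axis=1)
    med = pd.Series(med, index=protein_rows.index)
    kept = med.index[med >= min_median_corr]
    if len(kept) < 2:
        kept = med.sort_values(ascending=False, kind="stable").index[:2]
    return pd.Index(kept)


def winsorize_outliers(protein_rows: pd.DataFrame, sd_factor: float = 2.0) -> pd.DataFrame:
    """Clip each peptide's log2 values to its own mean ± ``sd_factor``·SD
    across samples."""
    mean = protein_rows.mean(axis=1)
    sd = protein_rows.std(axis=1, ddof=1).fillna(0.0)
    lo = mean - sd_factor * sd
    hi = mean + sd_factor * sd
    return protein_rows.clip(lower=lo, upper=hi, axis=0)


def peptide_rollup(matrix: QuantMatrix) -> pd.DataFrame:
    """Collapse charge states: sum linear intensities per (protein group,
    peptide sequence); returns a log2 frame indexed by the
    (protein_group_id, peptide_sequence) MultiIndex."""
    linear = matrix.values if not matrix.log_scale else np.exp2(matrix.values)
    summed = linear.groupby(
        [
            matrix.rows["protein_group_id"].to_numpy(),
            matrix.rows["peptide_sequence"].to_numpy(),
        ]
    ).sum(min_count=1)
    summed.index = summed.index.set_names(["protein_group_id", "peptide_sequence"])
    with np.errstate(divide="ignore"):
        log2 = np.log2(summed)
    return log2


def _sign_flip_pvalue(diffs: np.ndarray, rng: np.random.Generator | None,
                      n_perm: int = 2000) -> float:
    """Two-sided sign-flip test of mean(diffs) == 0; exact enumeration for
    up to 12 replicates, otherwise seeded Monte Carlo."""
    n = len(diffs)
    obs = abs(diffs.mean())
    if n <= 12:
        signs = np.array(list(product([-1.0, 1.0], repeat=n)))
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs((signs * diffs).mean(axis=1))
    return float((null >= obs - 1e-12).mean())


def protein_contrast(
    matrix: QuantMatrix,
    design: StudyDesign,
    target_cell_type: str,
    fdr_cut: float = 0.01,
    lfc_cut: float = 0.5,
    min_median_corr: float = 0.2,
    sd_factor: float = 2.0,
    method: str = "t",
    seed: int = 0,
) -> pd.DataFrame:
    """One-vs-rest differential analysis of ``target_cell_type`` against the
    mean of the remaining cell types, donor-paired.

    Expects the processed (filtered, imputed, normalized) matrix.  Returns a
    table with one row per protein group: ``log2fc``, ``p_value``, ``fdr``
    (Benjamini–Hochberg), ``n_peptides_used``, ``multi_member`` and the
    ``significant`` call at ``fdr < fdr_cut`` and ``|log2fc| > lfc_cut``.
    """
    matrix.check_design(design)
    cts = design.observed_cell_types
    if target_cell_type not in cts:
        raise ValueError(f"cell type {target_cell_type!r} absent from design")
    rest = [c for c in cts if c != target_cell_type]
    donors = design.donors

    log2 = peptide_rollup(matrix)
    target_cols = [design.sample_for(d, target_cell_type) for d in donors]
    rest_cols = {d: [design.sample_for(d, c) for c in rest] for d in donors}

    records = []
    for pg, sub in log2.groupby(level=0):
        sub = sub.droplevel(0)
        if sub.shape[0] < 2:
            # single-peptide proteins are normally excluded upstream; roll
            # up from the lone peptide without stability selection
            kept = sub.index
        else:
            sub = winsorize_outliers(sub, sd_factor=sd_factor)
            kept = select_stable_peptides(sub, min_median_corr=min_median_corr)
        sel = sub.loc[kept]
        # peptide × donor within-donor differences, target − mean(rest)
        diffs = np.column_stack(
            [
                sel[target_cols[i]].to_numpy()
                - sel[rest_cols[d]].mean(axis=1).to_numpy()
                for i, d in enumerate(donors)
            ]
        )
        log2fc = float(np.nanmedian(diffs))
        donor_vals = np.nanmedian(diffs, axis=0)
        donor_vals = donor_vals[np.isfinite(donor_vals)]
        if len(donor_vals) < 2 or np.allclose(donor_vals, donor_vals[0]):
            p = 1.0 if np.allclose(donor_vals, 0.0) else np.nan
            if np.isnan(p):
                p = 1.0
        elif method == "t":
            p = float(stats.ttest_1samp(donor_vals, 0.0).pvalue)
        elif method == "permutation":
            p = _sign_flip_pvalue(donor_vals, np.random.default_rng(seed))
        else:
            raise ValueError(f"unknown method {method!r}")
        records.append(
            {
                "protein_group_id": pg,
                "contrast": f"{target_cell_type}_vs_rest",
                "log2fc": log2fc,
                "p_value": p,
                "n_peptides_used": len(kept),
                "multi_member": ";" in str(pg),
            }
        )
    result = pd.DataFrame(records)
    if len(result):
        result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["significant"] = (result["fdr"] < fdr_cut) & (
            result["log2fc"].abs() > lfc_cut
        )
        result = result[
            [
                "protein_group_id", "contrast", "log2fc", "p_value", "fdr",
                "n_peptides_used", "multi_member", "significant",
            ]
        ].sort_values("protein_group_id", kind="stable").reset_index(drop=True)
    return result


def call_on_off(
    matrix_pre_imputation: QuantMatrix,
    design: StudyDesign,
    on_min_donors: int | None = None,
    off_max_donors: int = 0,
) -> pd.DataFrame:
    """Presence/absence calls per protein and cell type from the
    pre-imputation missing mask.

    A protein is *detected* in a sample when at least one of its precursors
    is observed there.  A cell type is called ``on`` when detected in at
    least ``on_min_donors`` donors (default: all), ``off`` when detected in
    at most ``off_max_donors`` (default 0), otherwise ``ambiguous``.
    Proteins with at least one on and one off cell type are flagged as
    on/off candidates.
    """
    matrix_pre_imputation.check_design(design)
    n_donors = len(design.donors)
    if on_min_donors is None:
        on_min_donors = n_donors
    present = matrix_pre_imputation.mask
    prot_present = present.groupby(
        matrix_pre_imputation.rows["protein_group_id"]
    ).any()
    cts = design.observed_cell_types
    records = []
    for pg, row in prot_present.iterrows():
        rec: dict = {"protein_group_id": pg}
        calls = []
        for ct in cts:
            samples = design.table.index[design.table["cell_type"] == ct]
            count = int(row[samples].sum())
            call = (
                "on" if count >= on_min_donors
                else "off" if count <= off_max_donors
                else "ambiguous"
            )
            rec[f"n_detected_{ct}"] = count
            rec[f"call_{ct}"] = call
            calls.append(call)
        rec["on_off_candidate"] = ("on" in calls) and ("off" in calls)
        records.append(rec)
    return pd.DataFrame(records)
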