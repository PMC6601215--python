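"""Protein-vs-mRNA fold-change concordance and discordance classification.

After joining the two differential layers on gene symbol, each gene falls
into one of four categories by comparing both FDRs against a cutoff
(default 0.01, strict "below"): significant on ``both`` layers,
``protein_only``, ``rna_only``, or ``neither``.  Genes significant on both
layers with opposite fold-change signs are flagged sign-discordant; the
protein-up / mRNA-down subset is the seed list for downstream network
analysis.  Overall agreement per contrast is the squared Pearson
correlation (R²) of the two log2 fold changes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "merge_layers",
    "concordance_r2",
    "classify_discordance",
    "network_seed_list",
]

CATEGORIES = ("both", "protein_only", "rna_only", "neither")


def merge_layers(
    protein_diff: pd.DataFrame,
    mrna_diff: pd.DataFrame,
    id_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join the protein and mRNA differential tables on gene symbol.

    ``protein_diff`` needs columns ``protein_group_id`` (or ``gene``),
    ``contrast``, ``log2fc``, ``fdr``; ``mrna_diff`` needs ``gene``,
    ``cell_type`` (or ``contrast``), ``log2fc``, ``padj`` (or ``fdr``).
    ``id_map`` is an optional two-column (protein_group_id, gene) table;
    protein groups mapping to several genes are dropped and counted.

    Returns the merged table (one row per gene × contrast) and a report
    dict with the dropped/unmatched counts.
    """
    prot = protein_diff.copy()
    report = {"ambiguous_mapping": 0, "protein_only_genes": 0, "rna_only_genes": 0}
    if "gene" not in prot.columns:
        if id_map is None:
            raise ValueError("protein table lacks 'gene'; provide an id_map")
        counts = id_map.groupby("protein_group_id")["gene"].nunique()
        ambiguous = set(counts.index[counts > 1])
        report["ambiguous_mapping"] = int(prot["protein_group_id"].isin(ambiguous).sum())
        unambig = id_map[~id_map["protein_group_id"].isin(ambiguous)]
        prot = prot.merge(unambig, on="protein_group_id", how="inner")
    rna = mrna_diff.rename(columns={"cell_type": "contrast", "padj": "fdr"})
    prot_key = prot["contrast"].str.replace("_vs_rest", "", regex=False)
    prot = prot.assign(_ct=prot_key)
    rna_key = rna["contrast"].str.replace("_vs_rest", "", regex=False)
    rna = rna.assign(_ct=rna_key)
    merged = prot.merge(
        rna[["gene", "_ct", "log2fc", "fdr"]],
        on=["gene", "_ct"],
        how="inner",
        suffixes=("", "_rna"),
    )
    merged = merged.rename(
        columns={
            "log2fc": "protein_log2fc",
            "fdr": "protein_fdr",
            "log2fc_rna": "mrna_log2fc",
            "fdr_rna": "mrna_fdr",
        }
    ).drop(columns=["_ct"])
    prot_genes = set(zip(prot["gene"], prot["_ct"]))
    rna_genes = set(zip(rna["gene"], rna["_ct"]))
    report["protein_only_genes"] = len(prot_genes - rna_genes)
    report["rna_only_genes"] = len(rna_genes - prot_genes)
    if len(merged) == 0:
        warnings.warn("protein and mRNA layers share no (gene, contrast) pairs")
    return merged, report


def concordance_r2(table: pd.DataFrame, contrast: str | None = None) -> float:
    """Squared Pearson correlation of protein vs mRNA log2 fold changes.

    Sign structure is deliberately not captured here (an exactly
    anti-correlated pair also gives R² = 1); discordance is classified
    separately.  Returns NaN when fewer than 3 finite pairs exist or either
    axis has zero variance.
    """
    sub = table if contrast is None else table[table["contrast"] == contrast]
    x = sub["protein_log2fc"].to_numpy(dtype=float)
    y = sub["mrna_log2fc"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        warnings.warn("fewer than 3 finite fold-change pairs; R² undefined")
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in fold changes; R² undefined")
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def classify_discordance(table: pd.DataFrame, fdr_cut: float = 0.01) -> pd.DataFrame:
    """Assign the four-way significance category and the sign-discordance
    flag.

    ``both`` requires FDR strictly below the cutoff on both layers (a gene
    at exactly the cutoff is not significant); ``sign_discordant`` holds for
    ``both`` genes whose fold changes have opposite signs.
    """
    out = table.copy()
    p_sig = out["protein_fdr"] < fdr_cut
    r_sig = out["mrna_fdr"] < fdr_cut
    category = np.select(
        [p_sig & r_sig, p_sig & ~r_sig, ~p_sig & r_sig],
        ["both", "protein_only", "rna_only"],
        default="neither",
    )
    out["category"] = pd.Categorical(category, categories=list(CATEGORIES))
    out["sign_discordant"] = (out["category"] == "both") & (
        out["protein_log2fc"] * out["mrna_log2fc"] < 0
    )
    return out


def network_seed_list(classified: pd.DataFrame) -> pd.DataFrame:
    """Genes significantly up on protein and down on mRNA — the seed list
    exported for protein-association network analysis."""
    sel = classified[
        classified["sign_discordant"] & (classified["protein_log2fc"] > 0)
    ]
    cols = ["gene", "contrast", "protein_log2fc", "protein_fdr",
            "mrna_log2fc", "mrna_fdr", "category"]
    return sel[cols].reset_index(drop=True)
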