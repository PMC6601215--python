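"""Preranked gene-set enrichment analysis.

Genes are ranked by one of two criteria — the log2 fold change itself, or
log2(fold change) × (−log10 adjusted p) — and each gene set is scored with
the weighted Kolmogorov–Smirnov running sum: walking down the ranked list,
the sum rises by |metric|^p / Σ|metric|^p at member genes and falls by
1/(N − N_hits) elsewhere; the enrichment score (ES) is the signed extreme
of the walk.  Significance comes from gene-label permutations: NES is the
ES divided by the mean |null ES| of matching sign, the nominal p is the
fraction of same-sign null ES at least as extreme (add-one corrected), and
the FDR q follows the sign-matched pooled-null procedure.  Sets are deemed
significant at FDR q < 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection

__all__ = [
    "RankedList",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a descending real-valued metric (ties broken by
    gene symbol)."""

    genes: tuple[str, ...]
    metric: np.ndarray
    criterion: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(
    diff: pd.DataFrame,
    criterion: str = "lfc",
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "fdr",
) -> RankedList:
    """Build a ranked list from a differential table.

    ``criterion`` is ``"lfc"`` (metric = log2 fold change) or
    ``"lfc_x_neglogp"`` (metric = log2FC × −log10 adjusted p).  Duplicate
    gene symbols raise; ties are broken by gene symbol so the order is
    deterministic.
    """
    if diff[gene_col].duplicated().any():
        dups = diff.loc[diff[gene_col].duplicated(), gene_col].unique()[:5]
        raise ValueError(f"duplicate gene symbols in differential table: {list(dups)}")
    if criterion == "lfc":
        metric = diff[lfc_col].to_numpy(dtype=float)
    elif criterion == "lfc_x_neglogp":
        padj = diff[padj_col].to_numpy(dtype=float)
        metric = diff[lfc_col].to_numpy(dtype=float) * (-np.log10(padj))
    else:
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    order = np.lexsort((diff[gene_col].to_numpy(), -metric))
    return RankedList(
        genes=tuple(diff[gene_col].to_numpy()[order]),
        metric=metric[order],
        criterion=criterion,
    )


def _es_from_hits(
    hits: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized running-sum ES.

    ``hits`` is a boolean array of shape (..., N); returns (ES, running sum)
    with the leading shape preserved.
    """
    hits = np.atleast_2d(hits)
    n = hits.shape[-1]
    n_hits = hits.sum(axis=-1, keepdims=True)
    hit_w = hits * weights
    total_w = hit_w.sum(axis=-1, keepdims=True)
    # all-zero weights inside the set degrade to unweighted increments
    flat = total_w[:, 0] == 0
    if flat.any():
        hit_w[flat] = hits[flat].astype(float)
        total_w = hit_w.sum(axis=-1, keepdims=True)
    inc = hit_w / total_w
    n_miss = n - n_hits
    with np.errstate(divide="ignore"):
        dec = np.where(n_miss > 0, (~hits) / np.maximum(n_miss, 1), 0.0)
    running = np.cumsum(inc - dec, axis=-1)
    idx = np.argmax(np.abs(running), axis=-1)
    es = running[np.arange(running.shape[0]), idx]
    return es, running


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set against a ranked list, plus the full running sum.

    A set covering every ranked gene has no misses; its running sum is the
    hit-only walk and the ES is 1 by construction.
    """
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                       count=len(ranked))
    if not hits.any():
        raise ValueError("gene set has empty intersection with the ranked list")
    weights = np.abs(ranked.metric) ** weight_p
    es, running = _es_from_hits(hits, weights)
    return float(es[0]), running[0]


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    min_size: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    fdr_cut: float = 0.25,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Sets are restricted to genes in the ranked list and dropped below
    ``min_size``.  The null distribution permutes the gene labels of the
    ranked list (``n_perm`` seeded draws, shared across sets).  Returns one
    row per scored set: ``set_name``, ``size``, ``es``, ``nes``, ``p_value``,
    ``fdr_q``, ``significant``.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for stable tail estimates")
    usable = collection.filtered(ranked.genes, min_size=min_size)
    if len(usable) == 0:
        import warnings

        warnings.warn("no gene set passes the minimum-size filter")
        return pd.DataFrame(
            columns=["set_name", "size", "es", "nes", "p_value", "fdr_q",
                     "significant"]
        )
    n = len(ranked)
    weights = np.abs(ranked.metric) ** weight_p
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    rng = np.random.default_rng(seed)
    # one label permutation per draw, shared by every set
    perms = np.argsort(rng.random((n_perm, n)), axis=1)

    names, sizes, es_obs = [], [], []
    null_es = []
    for name, members in usable:
        member_mask = np.zeros(n, dtype=bool)
        member_mask[[gene_pos[g] for g in members]] = True
        es, _ = _es_from_hits(member_mask, weights)
        null, _ = _es_from_hits(member_mask[perms], weights)
        names.append(name)
        sizes.append(int(member_mask.sum()))
        es_obs.append(es[0])
        null_es.append(null)
    es_obs = np.asarray(es_obs)
    null_es = np.vstack(null_es)  # sets × permutations

    # sign-matched normalization
    pos_mean = np.array(
        [row[row > 0].mean() if (row > 0).any() else np.nan for row in null_es]
    )
    neg_mean = np.array(
        [(-row[row < 0]).mean() if (row < 0).any() else np.nan for row in null_es]
    )
    denom = np.where(es_obs >= 0, pos_mean, neg_mean)
    denom = np.where(np.isnan(denom), 1.0, denom)
    nes = es_obs / denom

    pvals = np.empty(len(es_obs))
    for i, es in enumerate(es_obs):
        same = null_es[i][null_es[i] >= 0] if es >= 0 else -null_es[i][null_es[i] < 0]
        pvals[i] = (1.0 + (same >= abs(es)).sum()) / (1.0 + len(same))

    # pooled-null FDR on the NES scale, sign-matched
    null_nes = np.where(
        null_es >= 0, null_es / pos_mean[:, None], null_es / neg_mean[:, None]
    )
    null_nes = null_nes[np.isfinite(null_nes)]
    pos_null = null_nes[null_nes >= 0]
    neg_null = -null_nes[null_nes < 0]
    fdr_q = np.empty(len(nes))
    for i, v in enumerate(nes):
        if v >= 0:
            frac_null = (pos_null >= v).mean() if len(pos_null) else 0.0
            frac_obs = (nes[nes >= 0] >= v).mean()
        else:
            frac_null = (neg_null >= -v).mean() if len(neg_null) else 0.0
            frac_obs = (nes[nes < 0] <= v).mean()
        fdr_q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0

    return pd.DataFrame(
        {
            "set_name": names,
            "size": sizes,
            "es": es_obs,
            "nes": nes,
            "p_value": pvals,
            "fdr_q": fdr_q,
            "significant": fdr_q < fdr_cut,
        }
    )
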