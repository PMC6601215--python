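"""Synthetic DIA precursor matrices with the statistical structure of a
low-input sorted-cell study.

The generator emulates three experiment families:

* a donor × cell-type cohort (default 5 donors × HSC/CMP/GMP/MEP, one sample
  per combination, 25,000 cells each) with cell-type effects, inter-donor
  variation, detection-limit censoring and on/off proteins;
* a dilution series (descending loads, triplicate process replicates) in
  which expected signal scales with load, attenuated for hydrophobic
  peptides at low loads (adsorptive-loss model);
* a paired mRNA differential table in which a configurable fraction of
  genes is sign-discordant with the protein layer.

All randomness flows from a single integer seed through
:func:`numpy.random.default_rng`; the same (config, seed) pair always yields
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import QuantMatrix, StudyDesign

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_truth",
    "hspc_design",
    "simulate_hspc_matrix",
    "simulate_dilution_series",
    "simulate_mrna_table",
    "one_vs_rest_effects",
    "cv_to_log2_sd",
]

HSPC_CELL_TYPES: tuple[str, ...] = ("HSC", "CMP", "GMP", "MEP")

#: Sentinel for cell types in which an on/off protein is not expressed.
OFF = -np.inf

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def cv_to_log2_sd(cv: float) -> float:
    """log2-scale Gaussian SD giving a linear-scale coefficient of variation
    ``cv`` under the log-normal identity CV² = exp(σ_ln²) − 1."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic study.

    Defaults reflect the emulated study: four cell types over five donors,
    ~10% technical CV, a handful of peptides per protein, modest inter-donor
    variation, and detection-limit missingness.
    """

    n_proteins: int = 500
    mean_peptides_per_protein: float = 3.0
    #: fraction of a peptide's sequences re-observed at a second charge state
    extra_charge_fraction: float = 0.15
    fraction_differential: float = 0.10
    effect_size: float = 1.0          # |log2 FC| of a differential protein
    fraction_on_off: float = 0.02
    cv: float = 0.10                  # linear-scale technical CV target
    donor_sd: float = 0.25            # log2 SD of per-(protein, donor) effects
    baseline_mean: float = 14.0       # log2 abundance centre
    baseline_sd: float = 2.0
    peptide_offset_sd: float = 1.0    # log2 SD of ionization-efficiency offsets
    detection_limit: float = 0.0      # linear-intensity censoring threshold
    loss_coefficient: float = 0.0     # k of the hydrophobic-loss law
    qvalue_fail_fraction: float = 0.0
    cell_types: tuple[str, ...] = HSPC_CELL_TYPES

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if not 0 <= self.fraction_differential <= 1:
            raise ValueError("fraction_differential must be in [0, 1]")
        if not 0 <= self.fraction_on_off <= 1:
            raise ValueError("fraction_on_off must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study; fully determines every matrix
    drawn from it given the stored seed."""

    config: SimulationConfig
    seed: int
    proteins: pd.DataFrame   # index protein_id; gene, baseline, n_peptides
    effects: pd.DataFrame    # protein × cell type log2 effects (OFF = -inf)
    peptides: pd.DataFrame   # index precursor_id; protein_id, peptide_sequence,
                             # charge, offset, hydrophobicity

    @property
    def differential_proteins(self) -> pd.Index:
        finite = self.effects.replace(OFF, np.nan)
        return self.effects.index[(finite.fillna(1.0) != 0).any(axis=1)]

    @property
    def on_off_proteins(self) -> pd.Index:
        return self.effects.index[np.isinf(self.effects).any(axis=1)]

    def gene_of_protein(self) -> pd.Series:
        return self.proteins["gene"]


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    return "".join(rng.choice(_AMINO_ACIDS, size=length)) + "K"


def generate_truth(config: SimulationConfig, seed: int) -> SyntheticTruth:
    """Draw protein baselines, cell-type effects and peptide properties."""
    rng = _rng(seed, 0)
    n = config.n_proteins
    protein_ids = [f"PROT{i:05d}" for i in range(n)]
    genes = [f"GENE{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    effects = pd.DataFrame(
        0.0, index=pd.Index(protein_ids), columns=list(config.cell_types)
    )
    is_diff = rng.random(n) < config.fraction_differential
    target_ct = rng.integers(0, len(config.cell_types), size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    for i in np.flatnonzero(is_diff):
        effects.iloc[i, target_ct[i]] = sign[i] * config.effect_size
    # on/off overrides the graded effect for its silent cell type
    is_onoff = rng.random(n) < config.fraction_on_off
    off_ct = rng.integers(0, len(config.cell_types), size=n)
    for i in np.flatnonzero(is_onoff):
        effects.iloc[i, off_ct[i]] = OFF

    n_peps = 1 + rng.poisson(max(config.mean_peptides_per_protein - 1.0, 0.0), size=n)
    pep_rows = []
    seen: set[str] = set()
    for i, pid in enumerate(protein_ids):
        for _ in range(n_peps[i]):
            seq = _random_peptide(rng)
            while seq in seen:
                seq = _random_peptide(rng)
            seen.add(seq)
            offset = rng.normal(0.0, config.peptide_offset_sd)
            hydro = rng.random()
            charges = [2]
            if rng.random() < config.extra_charge_fraction:
                charges.append(3)
            for z in charges:
                pep_rows.append(
                    {
                        "precursor_id": f"{seq}.{z}",
                        "protein_id": pid,
                        "peptide_sequence": seq,
                        "charge": z,
                        "offset": offset,
                        "hydrophobicity": hydro,
                    }
                )
    peptides = pd.DataFrame(pep_rows).set_index("precursor_id")

    proteins = pd.DataFrame(
        {"gene": genes, "baseline": baseline, "n_peptides": n_peps},
        index=pd.Index(protein_ids),
    )
    return SyntheticTruth(
        config=config, seed=int(seed), proteins=proteins,
        effects=effects, peptides=peptides,
    )


def hspc_design(
    n_donors: int = 5,
    cell_types: tuple[str, ...] = HSPC_CELL_TYPES,
    load: float = 25000,
) -> StudyDesign:
    """Complete donor × cell-type single-replicate design."""
    rows = []
    for d in range(1, n_donors + 1):
        for ct in cell_types:
            rows.append(
                {
                    "sample_id": f"D{d}_{ct}",
                    "donor_id": f"D{d}",
                    "cell_type": ct,
                    "replicate_group": ct,
                    "load": load,
                }
            )
    return StudyDesign(
        pd.DataFrame(rows).set_index("sample_id"), cell_types=cell_types
    )


def _qvalue_frames(
    shape: tuple[int, int],
    index, columns,
    observed: np.ndarray,
    fail_fraction: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    prec_q = rng.uniform(0.0, 0.01, size=shape)
    prot_q = rng.uniform(0.0, 0.01, size=shape)
    if fail_fraction > 0:
        failing = rng.random(shape) < fail_fraction
        prec_q = np.where(failing, rng.uniform(0.011, 0.2, size=shape), prec_q)
    prec_q = np.where(observed, prec_q, np.nan)
    prot_q = np.where(observed, prot_q, np.nan)
    return (
        pd.DataFrame(prec_q, index=index, columns=columns),
        pd.DataFrame(prot_q, index=index, columns=columns),
    )


def _assemble_matrix(
    truth: SyntheticTruth,
    log2_expected: np.ndarray,
    columns: list[str],
    noise_rng: np.random.Generator,
) -> QuantMatrix:
    """Add technical noise, censor at the detection limit, attach Q-values."""
    cfg = truth.config
    sd = cv_to_log2_sd(cfg.cv)
    log2_obs = log2_expected + noise_rng.normal(0.0, sd, size=log2_expected.shape)
    with np.errstate(over="ignore"):
        linear = np.exp2(log2_obs)
    observed = np.isfinite(linear) & (linear > 0) & (linear >= cfg.detection_limit)
    values = pd.DataFrame(
        np.where(observed, linear, np.nan),
        index=truth.peptides.index,
        columns=columns,
    )
    rows = truth.peptides[["protein_id", "peptide_sequence", "charge"]].rename(
        columns={"protein_id": "protein_group_id"}
    )
    prec_q, prot_q = _qvalue_frames(
        values.shape, values.index, values.columns, observed,
        cfg.qvalue_fail_fraction, noise_rng,
    )
    return QuantMatrix(
        values=values, rows=rows, log_scale=False,
        precursor_q=prec_q, protein_q=prot_q,
    )


def simulate_hspc_matrix(
    truth: SyntheticTruth, design: StudyDesign | None = None
) -> QuantMatrix:
    """Simulate the donor × cell-type precursor matrix.

    The expected log2 intensity of precursor *j* (of protein *p*) in the
    sample of donor *d*, cell type *c* is
    ``baseline_p + effect_{p,c} + donor_{p,d} + offset_j``; technical noise
    is Gaussian on the log2 scale with SD matched to the configured linear
    CV, and entries falling below the detection limit (or belonging to an
    "off" cell type) are missing.
    """
    cfg = truth.config
    if design is None:
        design = hspc_design(cell_types=cfg.cell_types)
    if design.table.groupby(["donor_id", "cell_type"]).size().max() > 1:
        raise ValueError("design has replicate_group collisions: a (donor, "
                         "cell type) pair occurs more than once")
    rng = _rng(truth.seed, 1)
    donors = design.donors
    donor_eff = pd.DataFrame(
        rng.normal(0.0, cfg.donor_sd, size=(len(truth.proteins), len(donors))),
        index=truth.proteins.index, columns=donors,
    )
    pep = truth.peptides
    base = truth.proteins.loc[pep["protein_id"], "baseline"].to_numpy()
    offs = pep["offset"].to_numpy()
    cols = design.sample_ids
    expected = np.empty((len(pep), len(cols)))
    for k, s in enumerate(cols):
        d = design.table.loc[s, "donor_id"]
        ct = design.table.loc[s, "cell_type"]
        eff = truth.effects.loc[pep["protein_id"], ct].to_numpy()
        dn = donor_eff.loc[pep["protein_id"], d].to_numpy()
        expected[:, k] = base + eff + dn + offs
    return _assemble_matrix(truth, expected, cols, rng)


def retained_fraction(
    hydrophobicity: np.ndarray | float, load: float, reference_load: float, k: float
) -> np.ndarray | float:
    """Fraction of signal retained after adsorptive losses:
    ``r = exp(−k·h·(L0/L − 1))``.  No loss at the reference load; losses grow
    with hydrophobicity ``h`` and with decreasing load."""
    return np.exp(-k * np.asarray(hydrophobicity) * (reference_load / load - 1.0))


def dilution_design(loads, n_reps: int) -> StudyDesign:
    rows = []
    for load in loads:
        for r in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"L{load:g}_r{r}",
                    "donor_id": "pool",
                    "cell_type": "bulk",
                    "replicate_group": f"load_{load:g}",
                    "load": float(load),
                }
            )
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


def simulate_dilution_series(
    truth: SyntheticTruth, loads, n_reps: int = 3
) -> tuple[QuantMatrix, StudyDesign]:
    """Simulate a replicated dilution series.

    Expected linear intensity scales proportionally to load relative to the
    highest load, multiplied by the hydrophobicity-dependent retained
    fraction; detection-limit censoring applies after scaling.
    """
    loads = list(loads)
    if len(set(loads)) < 2:
        raise ValueError("a dilution series needs >=2 distinct loads")
    if any(l <= 0 for l in loads):
        raise ValueError("loads must be strictly positive")
    if n_reps < 2:
        raise ValueError("n_reps must be >=2")
    cfg = truth.config
    design = dilution_design(loads, n_reps)
    rng = _rng(truth.seed, 2)
    pep = truth.peptides
    base = truth.proteins.loc[pep["protein_id"], "baseline"].to_numpy()
    offs = pep["offset"].to_numpy()
    hydro = pep["hydrophobicity"].to_numpy()
    l0 = max(loads)
    cols = design.sample_ids
    expected = np.empty((len(pep), len(cols)))
    for k_col, s in enumerate(cols):
        load = design.table.loc[s, "load"]
        r = retained_fraction(hydro, load, l0, cfg.loss_coefficient)
        expected[:, k_col] = base + offs + np.log2(load / l0) + np.log2(r)
    return _assemble_matrix(truth, expected, cols, rng), design


def one_vs_rest_effects(truth: SyntheticTruth, off_log2: float = -6.0) -> pd.DataFrame:
    """True protein-level one-vs-rest log2 contrasts implied by the effects
    table: per cell type, effect in that type minus the mean effect of the
    remaining types.  OFF sentinels are clamped to ``off_log2``."""
    eff = truth.effects.replace(OFF, off_log2)
    cts = list(eff.columns)
    out = {}
    for ct in cts:
        rest = [c for c in cts if c != ct]
        out[ct] = eff[ct] - eff[rest].mean(axis=1)
    return pd.DataFrame(out)


def simulate_mrna_table(
    truth: SyntheticTruth,
    discordant_fraction: float,
    mrna_noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.Index]:
    """Simulate a transcript differential table paired with the protein layer.

    Concordant genes receive an mRNA log2FC equal to the protein-level
    one-vs-rest effect plus Gaussian noise; a ``discordant_fraction`` of the
    genes with a non-null protein effect get a sign-flipped mRNA effect in
    the protein's target cell type, with small adjusted p on the mRNA layer.

    Returns the long table (gene, cell_type, log2fc, padj) and the index of
    genes made discordant.
    """
    if not 0 <= discordant_fraction <= 1:
        raise ValueError("discordant_fraction must be in [0, 1]")
    rng = _rng(truth.seed, 3)
    true_fc = one_vs_rest_effects(truth)
    genes = truth.proteins["gene"]

    # only genes with a real protein-layer effect can show visible
    # discordance; each is flipped independently (binomial count)
    diff_idx = truth.differential_proteins
    flip_mask = rng.random(len(diff_idx)) < discordant_fraction
    flipped = diff_idx[flip_mask]

    records = []
    for pid in truth.proteins.index:
        # target cell type = the one with the largest |true effect|
        target = true_fc.loc[pid].abs().idxmax()
        for ct in true_fc.columns:
            fc = true_fc.loc[pid, ct]
            if pid in flipped and ct == target:
                fc = -fc
            fc_obs = fc + rng.normal(0.0, mrna_noise_sd)
            if abs(fc) > 1e-12:
                padj = rng.uniform(1e-6, 1e-3)
            else:
                padj = rng.uniform(0.05, 1.0)
            records.append(
                {
                    "gene": genes.loc[pid],
                    "cell_type": ct,
                    "log2fc": fc_obs,
                    "padj": padj,
                }
            )
    table = pd.DataFrame(records)
    return table, pd.Index(genes.loc[flipped].to_numpy(), name="gene")
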