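"""Shared study definition for the analysis drivers.

All drivers regenerate the same deterministic synthetic study from this one
place (simulation is cheap), so each script can be run independently;
tables written to results/ are for inspection and downstream use.
"""

from pathlib import Path

from diaq import SimulationConfig, generate_truth, hspc_design

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_SEED = 20190411

#: the donor × cell-type cohort: 5 donors, 4 cell types, ~10% technical CV,
#: a quarter of proteins differential at |log2FC| = 1 (roughly the share of
#: differential proteins reported for the stem-cell contrast), a few on/off
#: proteins, detection-limit censoring
COHORT = SimulationConfig(
    n_proteins=600,
    fraction_differential=0.25,
    effect_size=1.0,
    fraction_on_off=0.02,
    cv=0.10,
    detection_limit=2000.0,
    qvalue_fail_fraction=0.01,
)

#: the dilution series: hydrophobicity-dependent adsorptive losses at low load
DILUTION = SimulationConfig(
    n_proteins=400,
    fraction_differential=0.0,
    fraction_on_off=0.0,
    cv=0.10,
    detection_limit=3000.0,
    loss_coefficient=0.15,
)

DILUTION_LOADS = (2000, 1000, 500, 250, 125, 62.5)


def cohort_truth():
    return generate_truth(COHORT, STUDY_SEED)


def dilution_truth():
    return generate_truth(DILUTION, STUDY_SEED + 1)


def cohort_design():
    return hspc_design()
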