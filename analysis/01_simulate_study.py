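"""Generate the synthetic study: a 5-donor × 4-cell-type precursor matrix,
a triplicated dilution series, and a paired mRNA differential table.

Writes the canonical tables under results/simulated/ for inspection and for
the downstream drivers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (  # noqa: E402
    DILUTION_LOADS, RESULTS, cohort_design, cohort_truth, dilution_truth,
)

from diaq import (  # noqa: E402
    simulate_dilution_series, simulate_hspc_matrix, simulate_mrna_table,
    write_matrix,
)


def main() -> None:
    out = RESULTS / "simulated"
    out.mkdir(parents=True, exist_ok=True)

    truth = cohort_truth()
    design = cohort_design()
    matrix = simulate_hspc_matrix(truth, design)
    write_matrix(matrix, out / "cohort_matrix.tsv")
    design.table.reset_index().to_csv(out / "cohort_design.tsv", sep="\t",
                                      index=False)
    truth.effects.rename_axis("protein_group_id").reset_index().to_csv(
        out / "cohort_truth_effects.tsv", sep="\t", index=False
    )
    print(f"cohort: {matrix.n_precursors} precursors x {matrix.n_samples} "
          f"samples, {matrix.n_missing} missing entries "
          f"({100 * matrix.n_missing / matrix.n_entries:.1f}%)")
    print(f"  {len(truth.differential_proteins)} differential and "
          f"{len(truth.on_off_proteins)} on/off proteins configured")

    dtruth = dilution_truth()
    dmatrix, ddesign = simulate_dilution_series(dtruth, DILUTION_LOADS,
                                                n_reps=3)
    write_matrix(dmatrix, out / "dilution_matrix.tsv")
    ddesign.table.reset_index().to_csv(out / "dilution_design.tsv", sep="\t",
                                       index=False)
    print(f"dilution: {dmatrix.n_precursors} precursors over "
          f"{len(DILUTION_LOADS)} loads x 3 replicates, "
          f"{dmatrix.n_missing} censored entries")

    mrna, flipped = simulate_mrna_table(truth, discordant_fraction=0.15)
    mrna.to_csv(out / "mrna_differential.tsv", sep="\t", index=False)
    truth.proteins["gene"].rename_axis("protein_group_id").reset_index().to_csv(
        out / "protein_gene_map.tsv", sep="\t", index=False
    )
    print(f"mRNA layer: {mrna['gene'].nunique()} genes, "
          f"{len(flipped)} configured sign-discordant")


if __name__ == "__main__":
    main()
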