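"""Protein-vs-mRNA concordance: per-contrast R², four-way discordance
classification and the protein-up/mRNA-down network seed list.

Reads the simulated mRNA table and gene map from results/simulated/, reruns
the protein contrasts, and writes the classified table plus seed list under
results/concordance/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, STUDY_SEED, cohort_design, cohort_truth  # noqa: E402

from diaq import (  # noqa: E402
    classify_discordance, concordance_r2, merge_layers, network_seed_list,
    process_chain, protein_contrast, simulate_hspc_matrix, simulate_mrna_table,
    write_table,
)


def main() -> None:
    truth = cohort_truth()
    design = cohort_design()
    matrix = simulate_hspc_matrix(truth, design)
    processed, _ = process_chain(matrix, design, seed=STUDY_SEED)

    prot = pd.concat(
        [protein_contrast(processed, design, ct)
         for ct in design.observed_cell_types],
        ignore_index=True,
    )
    mrna, flipped = simulate_mrna_table(truth, discordant_fraction=0.15)
    id_map = (
        truth.proteins["gene"].rename_axis("protein_group_id").reset_index()
    )
    merged, report = merge_layers(prot, mrna, id_map)
    classified = classify_discordance(merged, fdr_cut=0.01)

    out = RESULTS / "concordance"
    out.mkdir(parents=True, exist_ok=True)
    write_table(classified, out / "concordance_classified.tsv")
    seeds = network_seed_list(classified)
    write_table(seeds, out / "network_seed_list.tsv")

    print(f"joined {len(merged)} (gene, contrast) pairs; dropped: {report}")
    for ct in design.observed_cell_types:
        r2 = concordance_r2(classified, contrast=f"{ct}_vs_rest")
        print(f"  {ct}: protein-vs-mRNA R² = {r2:.2f}")
    counts = classified["category"].value_counts()
    print("categories:", dict(counts))
    recovered = set(classified.loc[classified["sign_discordant"], "gene"])
    print(f"sign-discordant: {len(recovered)} recovered, "
          f"{len(set(flipped))} configured, "
          f"{len(recovered & set(flipped))} overlap")
    print(f"network seed list (protein up, mRNA down): {len(seeds)} genes")


if __name__ == "__main__":
    main()
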