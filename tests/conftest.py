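"""Shared fixtures: small hand-built matrices and synthetic studies."""

import numpy as np
import pandas as pd
import pytest

from diaq import QuantMatrix, SimulationConfig, StudyDesign, generate_truth, hspc_design


def make_matrix(
    values: dict[str, list],
    precursors: list[str],
    protein_groups: list[str] | None = None,
    precursor_q: dict[str, list] | None = None,
    protein_q: dict[str, list] | None = None,
) -> QuantMatrix:
    """Build a QuantMatrix from per-sample value lists (np.nan = missing).

    ``precursors`` are tokens like ``"PEPA.2"``; protein groups default to
    one protein per peptide sequence.
    """
    idx = pd.Index(precursors)
    vals = pd.DataFrame(values, index=idx, dtype=float)
    seqs = [p.rsplit(".", 1)[0] for p in precursors]
    charges = [int(p.rsplit(".", 1)[1]) if "." in p else 0 for p in precursors]
    if protein_groups is None:
        protein_groups = [f"PROT_{s}" for s in seqs]
    rows = pd.DataFrame(
        {
            "protein_group_id": protein_groups,
            "peptide_sequence": seqs,
            "charge": charges,
        },
        index=idx,
    )

    def _q(d):
        return None if d is None else pd.DataFrame(d, index=idx, dtype=float)

    return QuantMatrix(
        values=vals, rows=rows, precursor_q=_q(precursor_q), protein_q=_q(protein_q)
    )


def make_design(samples: dict[str, tuple[str, str]], load: float = 25000) -> StudyDesign:
    """Design from {sample_id: (donor, cell_type)}; replicate_group = cell type."""
    rows = [
        {
            "sample_id": s,
            "donor_id": d,
            "cell_type": ct,
            "replicate_group": ct,
            "load": load,
        }
        for s, (d, ct) in samples.items()
    ]
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def design_5x4() -> StudyDesign:
    return hspc_design()


@pytest.fixture
def small_truth():
    cfg = SimulationConfig(n_proteins=60, fraction_differential=0.2,
                           fraction_on_off=0.0)
    return generate_truth(cfg, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
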