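"""Processing chain: Q-value / consistency / min-peptide filters (with
brute-force oracles), missingness identities, imputation, TIC normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_design, make_matrix
from diaq import (
    SimulationConfig,
    filter_design_consistency,
    filter_min_peptides,
    filter_qvalue,
    generate_truth,
    hspc_design,
    impute_missing,
    missingness_from_counts,
    missingness_summary,
    normalize_tic,
    process_chain,
    simulate_hspc_matrix,
)


# -- Q-value filter --------------------------------------------------------


def _qmatrix(values, prec_q, prot_q, precursors):
    return make_matrix(values, precursors, precursor_q=prec_q, protein_q=prot_q)


def test_all_passing_qvalues_leave_matrix_unchanged():
    m = _qmatrix(
        {"S1": [1.0, 2.0], "S2": [3.0, 4.0]},
        {"S1": [0.001, 0.001], "S2": [0.001, 0.001]},
        {"S1": [0.001, 0.001], "S2": [0.001, 0.001]},
        ["PA.2", "PB.2"],
    )
    out = filter_qvalue(m)
    pd.testing.assert_frame_equal(out.values, m.values)


def test_failing_protein_qvalue_blanks_entry():
    m = _qmatrix(
        {"S1": [1.0, 2.0], "S2": [3.0, 4.0]},
        {"S1": [0.001, 0.001], "S2": [0.001, 0.001]},
        {"S1": [0.02, 0.001], "S2": [0.001, 0.001]},
        ["PA.2", "PB.2"],
    )
    out = filter_qvalue(m)
    assert np.isnan(out.values.loc["PA.2", "S1"])
    assert out.values.loc["PA.2", "S2"] == 3.0


def test_row_with_no_surviving_entries_dropped():
    m = _qmatrix(
        {"S1": [1.0, 2.0], "S2": [3.0, 4.0]},
        {"S1": [0.5, 0.001], "S2": [0.5, 0.001]},
        {"S1": [0.001, 0.001], "S2": [0.001, 0.001]},
        ["PA.2", "PB.2"],
    )
    out = filter_qvalue(m)
    assert list(out.values.index) == ["PB.2"]


def test_qvalue_filter_requires_qvalues():
    m = make_matrix({"S1": [1.0]}, ["PA.2"])
    with pytest.raises(ValueError, match="Q-value"):
        filter_qvalue(m)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_qvalue_filter_matches_bruteforce_oracle(data):
    n_prec, n_samp = 4, 3
    vals = data.draw(
        st.lists(st.lists(st.floats(1, 100), min_size=n_samp, max_size=n_samp),
                 min_size=n_prec, max_size=n_prec)
    )
    qs = st.floats(0.0, 0.05)
    pq = data.draw(st.lists(st.lists(qs, min_size=n_samp, max_size=n_samp),
                            min_size=n_prec, max_size=n_prec))
    gq = data.draw(st.lists(st.lists(qs, min_size=n_samp, max_size=n_samp),
                            min_size=n_prec, max_size=n_prec))
    samples = [f"S{j}" for j in range(n_samp)]
    precs = [f"P{i}K.2" for i in range(n_prec)]
    arr = np.array(vals).T
    m = _qmatrix(
        {s: arr[j] for j, s in enumerate(samples)},
        {s: np.array(pq).T[j] for j, s in enumerate(samples)},
        {s: np.array(gq).T[j] for j, s in enumerate(samples)},
        precs,
    )
    out = filter_qvalue(m, protein_q_cut=0.01, precursor_q_cut=0.01)
    # oracle: entry survives iff both Q-values pass, row kept iff any survives
    expect = {}
    for i, p in enumerate(precs):
        surv = {
            s for j, s in enumerate(samples)
            if pq[i][j] <= 0.01 and gq[i][j] <= 0.01
        }
        if surv:
            expect[p] = surv
    assert set(out.values.index) == set(expect)
    for p, surv in expect.items():
        assert set(out.values.columns[out.values.loc[p].notna()]) == surv


# -- design-consistency filter ---------------------------------------------


def _grid_matrix(present: np.ndarray, design):
    """present: precursor × sample boolean array following design order."""
    vals = np.where(present, 100.0, np.nan)
    precs = [f"P{i}K.2" for i in range(present.shape[0])]
    return make_matrix(
        {s: vals[:, j] for j, s in enumerate(design.sample_ids)}, precs
    )


def test_present_in_all_donors_for_one_cell_type_kept(design_5x4):
    present = np.zeros((1, 20), dtype=bool)
    hsc_cols = [i for i, s in enumerate(design_5x4.sample_ids) if s.endswith("_HSC")]
    present[0, hsc_cols] = True
    out = filter_design_consistency(_grid_matrix(present, design_5x4), design_5x4)
    assert out.n_precursors == 1


def test_four_of_five_donors_everywhere_removed(design_5x4):
    # present in 4/5 donors for every cell type, never all 4 cell types of
    # one donor: drop donor D5 entirely and one cell type per other donor
    present = np.ones((1, 20), dtype=bool)
    for i, s in enumerate(design_5x4.sample_ids):
        donor, ct = s.split("_")
        if donor == "D5":
            present[0, i] = False
        if (donor, ct) in [("D1", "HSC"), ("D2", "CMP"), ("D3", "GMP"),
                           ("D4", "MEP")]:
            present[0, i] = False
    out = filter_design_consistency(_grid_matrix(present, design_5x4), design_5x4)
    assert out.n_precursors == 0


def test_fully_observed_precursor_kept(design_5x4):
    present = np.ones((1, 20), dtype=bool)
    out = filter_design_consistency(_grid_matrix(present, design_5x4), design_5x4)
    assert out.n_precursors == 1


def test_sample_absent_from_design_rejected():
    design = make_design({"D1_HSC": ("D1", "HSC")})
    m = make_matrix({"D1_HSC": [1.0], "D9_HSC": [1.0]}, ["PA.2"])
    with pytest.raises(ValueError, match="absent from design"):
        filter_design_consistency(m, design)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_consistency_filter_matches_bruteforce_oracle(data):
    n_donors, n_cts, n_prec = 3, 4, 8
    design = make_design(
        {
            f"D{d}_{ct}": (f"D{d}", ct)
            for d in range(n_donors)
            for ct in ("W", "X", "Y", "Z")[:n_cts]
        }
    )
    present = np.array(
        data.draw(
            st.lists(
                st.lists(st.booleans(), min_size=n_donors * n_cts,
                         max_size=n_donors * n_cts),
                min_size=n_prec, max_size=n_prec,
            )
        )
    )
    m = _grid_matrix(present, design)
    out = filter_design_consistency(m, design)
    kept = set(out.values.index)
    # oracle: direct evaluation of rule (i) OR rule (ii)
    expect = set()
    for i, p in enumerate(m.values.index):
        row = dict(zip(design.sample_ids, present[i]))
        rule_i = any(
            all(row[f"D{d}_{ct}"] for d in range(n_donors))
            for ct in ("W", "X", "Y", "Z")[:n_cts]
        )
        rule_ii = any(
            all(row[f"D{d}_{ct}"] for ct in ("W", "X", "Y", "Z")[:n_cts])
            for d in range(n_donors)
        )
        if rule_i or rule_ii:
            expect.add(p)
    assert kept == expect


# -- minimum-peptide filter ------------------------------------------------


def test_charge_states_of_one_sequence_count_as_one_peptide():
    m = make_matrix(
        {"S1": [1.0, 2.0]}, ["PEPA.2", "PEPA.3"], protein_groups=["P", "P"]
    )
    assert filter_min_peptides(m).n_precursors == 0


def test_two_distinct_sequences_kept():
    m = make_matrix(
        {"S1": [1.0, 2.0]}, ["PEPA.2", "PEPB.2"], protein_groups=["P", "P"]
    )
    assert filter_min_peptides(m).n_precursors == 2


def test_min_one_peptide_is_identity():
    m = make_matrix({"S1": [1.0, 2.0]}, ["PEPA.2", "PEPB.2"])
    out = filter_min_peptides(m, min_distinct_peptides=1)
    pd.testing.assert_frame_equal(out.values, m.values)


# -- missingness -----------------------------------------------------------


def test_missingness_identities_from_reported_dimensions():
    s = missingness_from_counts(n_entries=785_280, n_samples=20,
                                n_missing=50_382)
    assert s.n_precursors == 39_264
    assert round(100 * s.missing_fraction, 1) == 6.4
    assert round(s.avg_missing_per_precursor, 2) == 1.28


def test_complete_matrix_has_zero_missingness():
    m = make_matrix({"S1": [1.0, 2.0], "S2": [3.0, 4.0]}, ["PA.2", "PB.2"])
    s = missingness_summary(m)
    assert s.n_missing == 0 and s.missing_fraction == 0.0


def test_missingness_count_identity():
    m = make_matrix({"S1": [1.0, np.nan], "S2": [np.nan, 4.0]}, ["PA.2", "PB.2"])
    s = missingness_summary(m)
    assert s.n_missing + s.n_observed == s.n_entries == 4


# -- imputation ------------------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_imputed_values_in_bounds_and_observed_untouched(data):
    n_prec, n_samp = 5, 4
    vals = np.array(
        data.draw(
            st.lists(st.lists(st.floats(10, 1e5), min_size=n_samp,
                              max_size=n_samp),
                     min_size=n_prec, max_size=n_prec)
        )
    )
    miss = np.array(
        data.draw(
            st.lists(st.lists(st.booleans(), min_size=n_samp, max_size=n_samp),
                     min_size=n_prec, max_size=n_prec)
        )
    )
    miss[:, 0] = False  # keep one observed value per row
    vals = np.where(miss, np.nan, vals)
    samples = [f"S{j}" for j in range(n_samp)]
    m = make_matrix({s: vals[:, j] for j, s in enumerate(samples)},
                    [f"P{i}K.2" for i in range(n_prec)])
    out = impute_missing(m, seed=1)
    assert out.values.notna().all().all()
    row_min = m.values.min(axis=1)
    for i in range(n_prec):
        for j in range(n_samp):
            if miss[i, j]:
                v = out.values.iloc[i, j]
                assert 0.7 * row_min.iloc[i] <= v <= 0.9 * row_min.iloc[i]
            else:
                assert out.values.iloc[i, j] == m.values.iloc[i, j]


def test_imputation_seed_determinism():
    m = make_matrix({"S1": [1000.0, 10.0], "S2": [np.nan, 20.0]},
                    ["PA.2", "PB.2"])
    a = impute_missing(m, seed=7).values
    b = impute_missing(m, seed=7).values
    c = impute_missing(m, seed=8).values
    pd.testing.assert_frame_equal(a, b)
    assert a.loc["PA.2", "S2"] != c.loc["PA.2", "S2"]
    assert a.loc["PB.2", "S2"] == c.loc["PB.2", "S2"]  # observed untouched


def test_imputation_without_missing_is_identity():
    m = make_matrix({"S1": [1.0], "S2": [2.0]}, ["PA.2"])
    assert impute_missing(m, seed=1) is m


def test_all_missing_row_cannot_be_imputed():
    m = make_matrix({"S1": [np.nan], "S2": [np.nan]}, ["PA.2"])
    with pytest.raises(ValueError, match="all-missing"):
        impute_missing(m, seed=1)


# -- TIC normalization -----------------------------------------------------


def test_normalization_factors_from_stated_formula():
    """Column sums 100 and 300: factors 2.0 and 2/3, post sums both 200."""
    m = make_matrix({"S1": [40.0, 60.0], "S2": [120.0, 180.0]},
                    ["PA.2", "PB.2"])
    out, factors = normalize_tic(m)
    assert factors["S1"] == pytest.approx(2.0)
    assert factors["S2"] == pytest.approx(2 / 3)
    assert out.values.sum(axis=0).to_numpy() == pytest.approx([200.0, 200.0])


def test_equal_column_sums_are_fixed_point():
    m = make_matrix({"S1": [40.0, 60.0], "S2": [70.0, 30.0]}, ["PA.2", "PB.2"])
    out, factors = normalize_tic(m)
    assert np.allclose(factors, 1.0)
    pd.testing.assert_frame_equal(out.values, m.values)


def test_normalization_is_idempotent():
    m = make_matrix({"S1": [40.0, 60.0], "S2": [120.0, 180.0]},
                    ["PA.2", "PB.2"])
    once, _ = normalize_tic(m)
    twice, factors2 = normalize_tic(once)
    assert np.allclose(factors2, 1.0)
    pd.testing.assert_frame_equal(twice.values, once.values)


def test_normalization_commutes_with_global_rescale():
    m = make_matrix({"S1": [40.0, 60.0], "S2": [120.0, 180.0]},
                    ["PA.2", "PB.2"])
    scaled = m.with_values(m.values * 3.5)
    a, _ = normalize_tic(m)
    b, _ = normalize_tic(scaled)
    pd.testing.assert_frame_equal(b.values / 3.5, a.values)


def test_incomplete_matrix_requires_flag_and_zero_sum_rejected():
    m = make_matrix({"S1": [np.nan, 2.0], "S2": [1.0, 2.0]}, ["PA.2", "PB.2"])
    with pytest.raises(ValueError, match="missing"):
        normalize_tic(m)
    out, _ = normalize_tic(m, observed_only=True)
    assert out.values["S1"].sum() == pytest.approx(out.values["S2"].sum())
    z = make_matrix({"S1": [np.nan], "S2": [1.0]}, ["PA.2"])
    with pytest.raises(ValueError, match="non-positive"):
        normalize_tic(z, observed_only=True)


# -- chain -----------------------------------------------------------------


def test_chain_counts_never_increase_through_filters():
    cfg = SimulationConfig(n_proteins=150, detection_limit=3000.0,
                           qvalue_fail_fraction=0.05)
    design = hspc_design()
    matrix = simulate_hspc_matrix(generate_truth(cfg, 13), design)
    _, report = process_chain(matrix, design, seed=2)
    t = report.table()
    filters = t.iloc[:4]  # input + three filter stages
    assert (filters["n_precursors"].diff().dropna() <= 0).all()
    assert (filters["n_entries"].diff().dropna() <= 0).all()
    assert (filters["n_protein_groups"].diff().dropna() <= 0).all()
    # post-imputation matrix is complete and normalized
    assert t.iloc[-1]["n_missing"] == 0
    assert report.missingness is not None
    assert report.normalization_factors is not None
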