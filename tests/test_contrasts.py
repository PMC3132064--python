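import numpy as np
import pytest
from scipy import stats

from twindiff._exceptions import ParameterError
from twindiff.contrasts import (
    MatchedContrastTest,
    bh_adjust,
    contrast_PvU,
    contrast_vs_controls,
    signed_fold,
)
from twindiff.simulate import SimParams, simulate_cohort

from conftest import build_design, matrix_for


def _pvu_matrix(p_vals, u_vals, n_ctrl=1):
    design = build_design(n_pairs=len(p_vals), n_ctrl=n_ctrl)
    row = []
    for k in range(len(p_vals)):
        row += [p_vals[k], u_vals[k]] + [0.0] * n_ctrl
    return matrix_for(design, [row]), design


def test_paired_t_matches_textbook_oracle():
    p_vals, u_vals = [2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 3.0]  # d = (1, 2, 3, 2)
    m, design = _pvu_matrix(p_vals, u_vals)
    res = contrast_PvU(m, design).iloc[0]
    assert res["delta_log2"] == pytest.approx(2.0)
    assert res["se"] == pytest.approx(0.40825, abs=1e-5)
    assert res["statistic"] == pytest.approx(4.899, abs=1e-3)
    assert res["df"] == 3
    oracle = stats.ttest_rel(p_vals, u_vals)
    assert res["p"] == pytest.approx(oracle.pvalue, rel=1e-10)


def test_zero_spread_nonzero_delta_is_untestable():
    m, design = _pvu_matrix([3.0, 4.0, 5.0, 6.0], [1.0, 2.0, 3.0, 4.0])  # d = 2,2,2,2
    res = contrast_PvU(m, design).iloc[0]
    assert res["delta_log2"] == 2.0 and res["se"] == 0.0
    assert np.isnan(res["p"])


def test_identical_twins_give_t_zero_p_one():
    m, design = _pvu_matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    res = contrast_PvU(m, design).iloc[0]
    assert res["statistic"] == 0.0 and res["p"] == 1.0


def test_exact_unit_offset_vs_controls_untestable():
    design = build_design(n_pairs=4, n_ctrl=2)
    row = []
    for k in range(4):
        base = float(k)
        row += [base + 1.0, base, base - 0.5, base + 0.5]  # case = ctrl mean + 1
    m = matrix_for(design, [row])
    res = contrast_vs_controls(m, design, "P").iloc[0]
    assert res["delta_log2"] == pytest.approx(1.0)
    assert res["se"] == 0.0 and np.isnan(res["p"])


def test_fewer_than_two_usable_units_untestable():
    design = build_design(n_pairs=3, n_ctrl=1)
    row = [1.0, 0.0, 0.0, np.nan, 0.5, 0.0, 2.0, 1.0, 0.0]
    m = matrix_for(design, [row])
    res = contrast_PvU(m, design).iloc[0]  # only pairs 0 and 2 complete -> n=2 ok
    assert res["n_units"] == 2
    row2 = [1.0, 0.0, 0.0, np.nan, 0.5, 0.0, np.nan, 1.0, 0.0]
    res2 = contrast_PvU(matrix_for(design, [row2]), design).iloc[0]
    assert res2["n_units"] == 1 and np.isnan(res2["p"])


def test_type_one_error_matches_alpha_on_null():
    matrix, design, _ = simulate_cohort(SimParams(n_probes=2000, frac_de=0.0, seed=17))
    for table in (contrast_PvU(matrix, design), contrast_vs_controls(matrix, design, "P")):
        p = table["p"].to_numpy()
        for alpha in (0.01, 0.05):
            margin = 3 * np.sqrt(alpha * (1 - alpha) / p.size)
            assert abs((p < alpha).mean() - alpha) < margin


def test_estimator_interface_selects_by_fdr():
    matrix, design, truth = simulate_cohort(
        SimParams(n_probes=500, frac_de=0.1, seed=4)
    )
    est = MatchedContrastTest(contrast="PvC", fdr_q=0.1).fit(matrix, design)
    assert est.get_params()["contrast"] == "PvC"
    sel = set(est.selected_probes())
    affected = set(truth.frame.loc[truth.frame.affected, "probe_id"])
    assert sel and len(sel & affected) / len(sel) > 0.8


# -- BH adjustment ---------------------------------------------------------


def _bh_bruteforce(p):
    """Independent step-up enumeration of BH adjusted values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            min(1.0, p[order[j - 1]] * m / j) for j in range(rank_pos, m + 1)
        ]
        adj[idx] = min(candidates)
    return adj


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_worked_examples(p, expected):
    adj, selected = bh_adjust(p, q=0.1)
    np.testing.assert_allclose(adj, expected)
    if expected == [1.0, 1.0, 1.0]:
        assert not selected.any()


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        adj, _ = bh_adjust(p)
        np.testing.assert_allclose(adj, _bh_bruteforce(p), atol=1e-12)
        np.testing.assert_allclose(
            adj, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


def test_bh_missing_values_reinserted(rng):
    p = np.array([0.01, np.nan, 0.04, np.nan])
    adj, selected = bh_adjust(p, q=0.1)
    assert np.isnan(adj[1]) and np.isnan(adj[3])
    np.testing.assert_allclose(adj[[0, 2]], _bh_bruteforce([0.01, 0.04]))
    assert not selected[1] and not selected[3]


def test_bh_monotone_in_p(rng):
    p = rng.random(100)
    adj, _ = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ParameterError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ParameterError):
        bh_adjust([0.5], q=1.0)


# -- signed fold -----------------------------------------------------------


@pytest.mark.parametrize(
    "delta, fold",
    [(1.0, 2.0), (-0.485, -1.40), (2.856, 7.24), (0.0, 1.0)],
)
def test_signed_fold_examples(delta, fold):
    assert signed_fold(delta) == pytest.approx(fold, abs=5e-3)


def test_signed_fold_invariants(rng):
    d = rng.normal(size=200)
    f = signed_fold(d)
    assert np.all(np.abs(f) >= 1.0)
    assert np.all(np.sign(f[d != 0]) == np.sign(d[d != 0]))
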