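import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from twindiff._exceptions import ParameterError
from twindiff.ordering import (
    IntermediateOrdering,
    enrichment_binomial,
    enrichment_permutation,
    estimate_lambda,
    group_means,
    is_intermediate,
    null_expectation,
)
from twindiff.simulate import DeltaSpec, SimParams, simulate_cohort

from conftest import build_design, matrix_for


def test_group_means_constant_matrix():
    design = build_design(n_pairs=2, n_ctrl=1)
    m = matrix_for(design, np.full((2, 6), 5.0))
    gm = group_means(m, design)
    np.testing.assert_array_equal(gm.to_numpy(), 5.0)


def test_group_means_arithmetic():
    design = build_design(n_pairs=2, n_ctrl=1)
    # columns: P0 U0 C0 P1 U1 C1
    m = matrix_for(design, [[1.0, 2.0, 0.0, 3.0, 2.0, 0.0]])
    gm = group_means(m, design).iloc[0]
    assert (gm["m_P"], gm["m_U"], gm["m_C"]) == (2.0, 2.0, 0.0)


def test_group_means_equal_bruteforce(rng):
    design = build_design(n_pairs=3, n_ctrl=2)
    values = rng.normal(size=(15, len(design.samples)))
    values[rng.random(values.shape) < 0.1] = np.nan
    m = matrix_for(design, values)
    gm = group_means(m, design)
    roles = design.roles()
    for role in "PUC":
        expected = np.nanmean(values[:, roles == role], axis=1)
        np.testing.assert_allclose(gm[f"m_{role}"], expected)


def test_probe_with_empty_group_excluded(rng):
    design = build_design(n_pairs=2, n_ctrl=1)
    values = rng.normal(size=(3, 6))
    values[1, [2, 5]] = np.nan  # both controls missing for probe 1
    with pytest.warns(UserWarning, match="entire group"):
        gm = group_means(matrix_for(design, values), design)
    assert len(gm) == 2 and "g1" not in gm.index


@pytest.mark.parametrize(
    "mP, mU, mC, expected",
    [
        (1.0, 0.5, 0.0, True),
        (1.0, 1.5, 0.0, False),
        (1.0, 1.0, 0.0, False),  # tie -> not intermediate
        (0.0, 0.5, 1.0, True),
        (1.0, 0.5, 0.5, False),
    ],
)
def test_strict_intermediacy(mP, mU, mC, expected):
    assert is_intermediate(mP, mU, mC) is expected


def test_chance_expectation_by_enumeration():
    count = sum(
        1
        for perm in itertools.permutations((1, 2, 3))
        if is_intermediate(*perm)  # assign to (m_P, m_U, m_C)
    )
    assert count == 2
    assert null_expectation() == pytest.approx(count / 6)


# -- binomial enrichment ---------------------------------------------------


def _binom_tail_exact(k, n, p0: Fraction) -> Fraction:
    return sum(
        Fraction(comb(n, x)) * p0**x * (1 - p0) ** (n - x) for x in range(k, n + 1)
    )


@pytest.mark.parametrize("k, n, p0", [(0, 10, 1 / 3), (2, 3, 0.5)])
def test_binomial_trivial_values(k, n, p0):
    expected = {(0, 10): 1.0, (2, 3): 0.5}[(k, n)]
    assert enrichment_binomial(k, n, p0) == pytest.approx(expected)


@pytest.mark.parametrize("k, n", [(84, 104), (10, 30), (5, 5), (0, 7)])
def test_binomial_matches_arbitrary_precision_tail(k, n):
    exact = float(_binom_tail_exact(k, n, Fraction(1, 3)))
    assert enrichment_binomial(k, n) == pytest.approx(exact, rel=1e-12)


def test_binomial_monotone_in_k():
    ps = [enrichment_binomial(k, 104) for k in range(0, 105)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_binomial_rejects_invalid_counts():
    with pytest.raises(ParameterError):
        enrichment_binomial(5, 3)
    with pytest.raises(ParameterError):
        enrichment_binomial(1, 3, p0=1.0)


# -- permutation enrichment ------------------------------------------------


def test_permutation_rejects_bad_arguments():
    matrix, design, _ = simulate_cohort(SimParams(n_probes=20, seed=0))
    with pytest.raises(ParameterError):
        enrichment_permutation(matrix, design, matrix.probe_ids, n_perm=0)
    with pytest.raises(ParameterError):
        enrichment_permutation(matrix, design, [], n_perm=200)


def test_permutation_seed_reproducible():
    matrix, design, _ = simulate_cohort(SimParams(n_probes=100, seed=2))
    p1 = enrichment_permutation(matrix, design, matrix.probe_ids, 199, seed=7)
    p2 = enrichment_permutation(matrix, design, matrix.probe_ids, 199, seed=7)
    assert p1 == p2 and 0 < p1 <= 1


# -- lambda recovery and estimator interface --------------------------------


def test_lambda_recovered_in_low_noise_regime():
    p = SimParams(
        n_probes=2000, frac_de=1.0, lambda_intermediacy=0.5,
        sd_pair=0.1, sd_set=0.1, sd_batch=0.1, sd_resid=0.1, seed=3,
    )
    matrix, design, truth = simulate_cohort(p)
    lam = estimate_lambda(matrix, design, truth.frame["probe_id"])
    assert lam == pytest.approx(0.5, abs=0.03)


def test_ordering_estimator_summary_consistency():
    matrix, design, truth = simulate_cohort(
        SimParams(n_probes=400, frac_de=0.2, delta_log2=DeltaSpec(1.0, 2.0), seed=6)
    )
    affected = truth.frame.loc[truth.frame.affected, "probe_id"].tolist()
    est = IntermediateOrdering(probe_subset=affected, label="affected").fit(
        matrix, design
    )
    r = est.result_
    assert r.n == len(affected)
    assert r.fraction == pytest.approx(r.k / r.n)
    assert r.k == int(r.per_probe["intermediate"].sum())
    # strong disease effects with lambda=0.6 make intermediacy dominate
    assert r.fraction > 0.8 and r.p_binomial < 1e-10
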