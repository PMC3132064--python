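from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from twindiff._exceptions import ParameterError
from twindiff.cluster import (
    SampleClustering,
    category_enrichment,
    hcluster,
    two_branch_membership,
)
from twindiff.io import ProbeMatrix
from twindiff.simulate import DeltaSpec, SimParams, simulate_cohort


def _matrix(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ProbeMatrix([f"g{i}" for i in range(values.shape[0])], ids, values)


def _brute_agglomerate(D, method):
    """Naive agglomeration oracle: returns [(member frozenset, height), ...]."""
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            pair_d = [D[i, j] for i in clusters[a] for j in clusters[b]]
            d = max(pair_d) if method == "complete" else float(np.mean(pair_d))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        new_id = max(list(clusters) + [a, b]) + 1
        clusters[new_id] = merged
        merges.append((merged, d))
    return merges


def _scipy_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_i, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_i] = merged
        out.append((merged, float(h)))
    return out


@pytest.mark.parametrize("distance", ["correlation", "euclidean"])
@pytest.mark.parametrize("linkage", ["average", "complete"])
@pytest.mark.parametrize("n_samples", [4, 5])
def test_hcluster_matches_exhaustive_agglomeration(rng, distance, linkage, n_samples):
    for _ in range(10):
        values = rng.normal(size=(8, n_samples))
        m = _matrix(values)
        dend = hcluster(m, distance=distance, linkage=linkage)
        from twindiff.cluster import _sample_distances

        D = _sample_distances(values.T, distance)
        expected = _brute_agglomerate(D, linkage)
        got = _scipy_merges(dend.linkage, n_samples)
        for (mem_e, h_e), (mem_g, h_g) in zip(expected, got):
            assert mem_e == mem_g
            assert h_g == pytest.approx(h_e, abs=1e-10)


def test_identical_profiles_merge_at_height_zero(rng):
    base = rng.normal(size=5)
    values = np.column_stack([base, base, base + rng.normal(size=5)])
    dend = hcluster(_matrix(values), distance="euclidean")
    assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    branches = two_branch_membership(dend)
    assert branches["s0"] == branches["s1"]


def test_two_samples_split_one_per_branch(rng):
    dend = hcluster(_matrix(rng.normal(size=(4, 2))))
    branches = two_branch_membership(dend)
    assert set(branches.index) == {"s0", "s1"} and set(branches.values) == {1, 2}
    assert branches[min(branches.index)] == 1  # deterministic anchoring


def test_constant_profile_gets_max_correlation_distance(rng):
    values = rng.normal(size=(6, 3))
    values[:, 0] = 2.0  # constant sample
    with pytest.warns(UserWarning, match="constant sample profile"):
        dend = hcluster(_matrix(values), distance="correlation")
    # the constant sample joins last, at distance >= 1
    assert dend.linkage[-1, 2] >= 1.0 - 1e-12


def test_heights_nondecreasing_under_average_linkage(rng):
    m = _matrix(rng.normal(size=(10, 8)))
    dend = hcluster(m, distance="correlation", linkage="average")
    assert np.all(np.diff(dend.linkage[:, 2]) >= -1e-12)


def test_sample_order_invariance(rng):
    values = rng.normal(size=(10, 6))
    m = _matrix(values)
    perm = rng.permutation(6)
    m2 = ProbeMatrix(m.probe_ids, [m.sample_ids[i] for i in perm], values[:, perm])
    b1 = two_branch_membership(hcluster(m))
    b2 = two_branch_membership(hcluster(m2))
    assert (b1.sort_index() == b2.sort_index()).all()


def test_newick_contains_all_samples(rng):
    import io as _io

    from skbio.tree import TreeNode

    m = _matrix(rng.normal(size=(6, 5)))
    nwk = hcluster(m).to_newick()
    tree = TreeNode.read(_io.StringIO(nwk))
    assert {t.name for t in tree.tips()} == set(m.sample_ids)


def test_probands_segregate_from_controls_under_strong_effects():
    params = SimParams(
        n_probes=300, frac_de=0.3, delta_log2=DeltaSpec(1.5, 2.5), seed=13
    )
    matrix, design, truth = simulate_cohort(params)
    affected = truth.frame.loc[truth.frame.affected, "probe_id"].tolist()
    est = SampleClustering(probe_subset=affected).fit(matrix, design)
    roles = dict(zip(design.subject_ids, design.roles()))
    table = np.zeros((2, 2), dtype=int)
    for sid, branch in est.branches_.items():
        if roles[sid] == "P":
            table[0, branch - 1] += 1
        elif roles[sid] == "C":
            table[1, branch - 1] += 1
    assert stats.fisher_exact(table).pvalue < 0.01


# -- category enrichment ---------------------------------------------------


def _hyper_tail_exact(k, n, K, N) -> Fraction:
    return sum(
        Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
        for x in range(k, min(n, K) + 1)
    )


@pytest.mark.parametrize(
    "k, n, K, N, expected",
    [
        (3, 3, 5, 5, 1.0),  # whole universe in the category
        (2, 2, 2, 4, 1 / 6),
    ],
)
def test_enrichment_worked_examples(k, n, K, N, expected):
    assert category_enrichment(k, n, K, N) == pytest.approx(expected, rel=1e-12)


def test_enrichment_matches_exact_enumeration(rng):
    for _ in range(50):
        N = int(rng.integers(2, 12))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(0, N + 1))
        lo = max(0, n + K - N)
        k = int(rng.integers(lo, min(n, K) + 1))
        expected = float(_hyper_tail_exact(k, n, K, N))
        assert category_enrichment(k, n, K, N) == pytest.approx(expected, rel=1e-10)


def test_enrichment_p_is_one_at_minimum_attainable_count(rng):
    # when k equals its minimum attainable value the tail covers all outcomes
    N, n, K = 10, 6, 8
    k_min = max(0, n + K - N)
    assert category_enrichment(k_min, n, K, N) == pytest.approx(1.0)


def test_enrichment_rejects_inconsistent_counts():
    with pytest.raises(ParameterError):
        category_enrichment(5, 3, 4, 10)
    with pytest.raises(ParameterError):
        category_enrichment(0, 4, 9, 10)  # below the minimum attainable overlap
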