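"""Intermediate-ordering statistic for the unaffected co-twin.

If unaffected co-twins occupy a transitional state between disease and
health, their group mean expression should lie strictly between the proband
and control group means for disease-relevant probes.  For three exchangeable
group means, 2 of the 6 orderings place the twin group in the middle, so the
chance expectation of strict intermediacy is 1/3 per probe.  Enrichment over
a probe subset is scored by an exact upper-tail binomial test against 1/3
and, optionally, by a within-matched-set permutation null that reassigns the
"unaffected twin" label uniformly among that set's twin and controls while
probands stay fixed (the hypothesis being that U is exchangeable with
healthy controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import ParameterError
from .io import CohortDesign, ProbeMatrix, align


def group_means(matrix: ProbeMatrix, design: CohortDesign) -> pd.DataFrame:
    """Per-probe arithmetic means of the P, U and C groups (missing-aware).

    Probes with a role entirely missing are excluded with a warning.
    """
    matrix = align(matrix, design)
    roles = design.roles()
    out = {}
    for role in ("P", "U", "C"):
        vals = matrix.values[:, roles == role]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"m_{role}"] = np.nanmean(vals, axis=1)
    df = pd.DataFrame(out, index=pd.Index(matrix.probe_ids, name="probe_id"))
    bad = df.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} probe(s) lack values for an entire group; excluded"
        )
        df = df[~bad]
    return df


def is_intermediate(m_P, m_U, m_C):
    """Strict betweenness of the twin-group mean: ``(m_U-m_P)*(m_U-m_C) < 0``.

    Any tie counts as not intermediate (ties have measure zero on
    continuous data).
    """
    m_P = np.asarray(m_P, dtype=float)
    m_U = np.asarray(m_U, dtype=float)
    m_C = np.asarray(m_C, dtype=float)
    out = (m_U - m_P) * (m_U - m_C) < 0
    return bool(out) if out.ndim == 0 else out


def null_expectation() -> float:
    """Chance probability that the twin mean is the middle one: 1/3.

    Of the 6 orderings of three exchangeable distinct means, exactly 2
    place the twin group in the middle.
    """
    return 1.0 / 3.0


def enrichment_binomial(k: int, n: int, p0: float = 1.0 / 3.0) -> float:
    """Exact upper-tail binomial probability of >= k successes in n at p0."""
    if not (0 <= k <= n) or n < 1:
        raise ParameterError("need 0 <= k <= n with n >= 1")
    if not (0 < p0 < 1):
        raise ParameterError("p0 must lie in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)


def _set_membership(matrix: ProbeMatrix, design: CohortDesign):
    """Column indices of P, and of the {U, C...} pool, per matched set."""
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    sets = design.sets()
    set_ids = sorted(sets)
    p_cols = np.array([idx[sets[s]["P"]] for s in set_ids])  # type: ignore[index]
    pools = [
        [idx[sets[s]["U"]]] + [idx[c] for c in sets[s]["C"]]  # type: ignore[index,union-attr]
        for s in set_ids
    ]
    width = max(len(p) for p in pools)
    if any(len(p) != width for p in pools):
        raise ParameterError("permutation null requires equal-size matched sets")
    return p_cols, np.array(pools)


def enrichment_permutation(
    matrix: ProbeMatrix,
    design: CohortDesign,
    probe_subset,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Within-set label-permutation p value for the intermediacy fraction.

    For each permutation the U label is reassigned uniformly within each
    matched set's {U, controls} pool (probands fixed); the statistic is the
    strict-intermediacy fraction over ``probe_subset``;
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    probe_subset = list(probe_subset)
    if not probe_subset:
        raise ParameterError("probe_subset is empty")
    matrix = align(matrix, design)
    rows = {p: i for i, p in enumerate(matrix.probe_ids)}
    try:
        ridx = np.array([rows[p] for p in probe_subset])
    except KeyError as exc:
        raise ParameterError(f"unknown probe id {exc.args[0]!r}") from exc
    V = matrix.values[ridx]
    p_cols, pools = _set_membership(matrix, design)
    n_sets, width = pools.shape

    m_P = V[:, p_cols].mean(axis=1)
    pool_vals = V[:, pools]  # probes x sets x width
    pool_sum = pool_vals.sum(axis=2)

    def frac(choice: np.ndarray) -> float:
        u_vals = pool_vals[:, np.arange(n_sets), choice]
        m_U = u_vals.mean(axis=1)
        m_C = (pool_sum - u_vals).sum(axis=1) / (n_sets * (width - 1))
        return float(np.mean((m_U - m_P) * (m_U - m_C) < 0))

    observed = frac(np.zeros(n_sets, dtype=int))
    rng = np.random.default_rng(seed)
    choices = rng.integers(0, width, size=(n_perm, n_sets))
    perm_stats = np.array([frac(c) for c in choices])
    return float((1 + np.sum(perm_stats >= observed)) / (1 + n_perm))


def estimate_lambda(
    matrix: ProbeMatrix, design: CohortDesign, affected_probes
) -> float:
    """Recover the intermediacy coefficient from group means of affected probes.

    Uses the regression-through-origin ratio
    ``sum(x*y) / sum(x**2)`` with ``x = m_P - m_C`` and ``y = m_U - m_C``,
    which targets lambda and, unlike the plain mean of per-probe ratios,
    is stable when some disease effects are small relative to noise.
    """
    gm = group_means(matrix, design)
    gm = gm.loc[gm.index.intersection(list(affected_probes))]
    if gm.empty:
        raise ParameterError("no affected probes with complete group means")
    x = (gm["m_P"] - gm["m_C"]).to_numpy()
    y = (gm["m_U"] - gm["m_C"]).to_numpy()
    return float(np.sum(x * y) / np.sum(x * x))


def mean_intermediacy_ratio(
    matrix: ProbeMatrix, design: CohortDesign, affected_probes
) -> float:
    """Plain mean of per-probe ratios ``(m_U-m_C)/(m_P-m_C)`` (low-noise use)."""
    gm = group_means(matrix, design)
    gm = gm.loc[gm.index.intersection(list(affected_probes))]
    x = (gm["m_P"] - gm["m_C"]).to_numpy()
    y = (gm["m_U"] - gm["m_C"]).to_numpy()
    return float(np.mean(y / x))


@dataclass
class OrderingResult:
    """Summary of strict intermediacy over one probe subset."""

    probe_subset_label: str
    n: int
    k: int
    fraction: float
    p_binomial: float
    p_permutation: float | None
    per_probe: pd.DataFrame  # m_P, m_U, m_C, intermediate


class IntermediateOrdering(BaseEstimator):
    """Estimator scoring strict intermediacy of the twin group mean.

    Parameters
    ----------
    probe_subset : list of probe ids or None (all probes).
    n_perm : permutations for the within-set label null (0 disables it).
    seed : permutation seed.
    """

    def __init__(self, probe_subset=None, n_perm: int = 0, seed: int = 0,
                 label: str = "all"):
        self.probe_subset = probe_subset
        self.n_perm = n_perm
        self.seed = seed
        self.label = label

    def fit(self, matrix: ProbeMatrix, design: CohortDesign):
        gm = group_means(matrix, design)
        if self.probe_subset is not None:
            subset = [p for p in self.probe_subset if p in gm.index]
            if not subset:
                raise ParameterError("probe_subset is empty")
            gm = gm.loc[subset]
        gm = gm.assign(
            intermediate=is_intermediate(gm["m_P"], gm["m_U"], gm["m_C"])
        )
        k = int(gm["intermediate"].sum())
        n = int(len(gm))
        p_perm = None
        if self.n_perm:
            p_perm = enrichment_permutation(
                matrix, design, list(gm.index), self.n_perm, self.seed
            )
        self.result_ = OrderingResult(
            probe_subset_label=self.label,
            n=n,
            k=k,
            fraction=k / n,
            p_binomial=enrichment_binomial(k, n),
            p_permutation=p_perm,
            per_probe=gm,
        )
        return self
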