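"""Disease-subtype-specific tests on matched differences.

Two complementary questions about subtype specificity (SLE vs RA vs IIM):

* do within-pair differences ``d_j = y_P - y_U`` differ among the probands'
  diagnoses? — a three-category one-way ANOVA per probe;
* do within-set proband-minus-controls contrasts differ among diagnoses?
  — the disease-status x subtype fixed-effect interaction under a
  random-intercept-per-matched-set model, which on balanced data reduces to
  the same one-way ANOVA applied to the within-set contrasts.

Both families are BH-adjusted genome-wide (q = 0.1 by default).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import ParameterError
from .contrasts import bh_adjust, pair_difference_matrix, set_contrast_matrix
from .io import CohortDesign, ProbeMatrix, align


def pair_differences(
    matrix: ProbeMatrix, design: CohortDesign
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-probe within-pair differences with each pair's subtype.

    Returns (DataFrame probes x pair_ids, subtype array aligned to columns).
    """
    matrix = align(matrix, design)
    D, pair_ids = pair_difference_matrix(matrix, design)
    subtype = design.subtype_of_pair()
    frame = pd.DataFrame(D, index=matrix.probe_ids, columns=pair_ids)
    return frame, np.array([subtype[p] for p in pair_ids])


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with explicit degenerate handling.

    Groups with fewer than 2 observations are dropped; with fewer than 2
    groups left the test is untestable (``(nan, nan)``).  All values equal
    gives ``F = 0, p = 1``; zero within-group spread with distinct group
    means gives ``F = inf, p = 0``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    levels = [g for g in dict.fromkeys(groups) if np.sum(groups == g) >= 2]
    if len(levels) < 2:
        return (np.nan, np.nan)
    samples = [values[groups == g] for g in levels]
    N = sum(len(s) for s in samples)
    k = len(samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return float(F), float(stats.f.sf(F, k - 1, N - k))


def _anova_matrix(V: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Vectorized one-way ANOVA across the rows of ``V`` (missing-aware)."""
    levels = list(dict.fromkeys(groups))
    masks = [groups == g for g in levels]
    G = V.shape[0]
    present = ~np.isnan(V)
    counts = np.column_stack([present[:, m].sum(axis=1) for m in masks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sums = np.column_stack([np.nansum(V[:, m], axis=1) for m in masks])
        means = sums / counts
    usable = counts >= 2
    k_eff = usable.sum(axis=1)
    n_eff = np.where(usable, counts, 0).sum(axis=1)
    tot = np.where(usable, np.where(np.isnan(means), 0, means) * counts, 0).sum(axis=1)
    grand = tot / n_eff
    ssb = np.where(
        usable, counts * (np.where(np.isnan(means), 0, means) - grand[:, None]) ** 2, 0
    ).sum(axis=1)
    sst = np.zeros(G)
    for m, u in zip(masks, usable.T):
        block = V[:, m]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dev = (block - grand[:, None]) ** 2
        sst += np.where(u, np.nansum(dev, axis=1), 0.0)
    ssw = sst - ssb
    ssw = np.where(np.abs(ssw) < 1e-12 * np.maximum(sst, 1.0), np.maximum(ssw, 0.0), ssw)
    df_b = k_eff - 1.0
    df_w = n_eff - k_eff
    F = np.full(G, np.nan)
    p = np.full(G, np.nan)
    ok = (k_eff >= 2) & (df_w > 0)
    pos = ok & (ssw > 0)
    F[pos] = (ssb[pos] / df_b[pos]) / (ssw[pos] / df_w[pos])
    p[pos] = stats.f.sf(F[pos], df_b[pos], df_w[pos])
    flat = ok & (ssw == 0) & (ssb == 0)
    F[flat], p[flat] = 0.0, 1.0
    sep = ok & (ssw == 0) & (ssb > 0)
    F[sep], p[sep] = np.inf, 0.0
    return pd.DataFrame(
        {"F": F, "df_between": df_b, "df_within": df_w, "p": p}
    )


def _subtype_table(
    probe_ids, V: np.ndarray, groups: np.ndarray, fdr_q: float
) -> pd.DataFrame:
    res = _anova_matrix(V, groups)
    adj, _ = bh_adjust(res["p"].to_numpy(), q=fdr_q)
    res.insert(0, "probe_id", probe_ids)
    res["fdr"] = adj
    return res


def subtype_anova(
    matrix: ProbeMatrix, design: CohortDesign, fdr_q: float = 0.1
) -> pd.DataFrame:
    """One-way ANOVA of within-pair differences across disease subtypes."""
    frame, groups = pair_differences(matrix, design)
    return _subtype_table(list(frame.index), frame.to_numpy(), groups, fdr_q)


def subtype_interaction(
    matrix: ProbeMatrix, design: CohortDesign, fdr_q: float = 0.1
) -> pd.DataFrame:
    """Status x subtype interaction via ANOVA on within-set P-vs-C contrasts."""
    matrix = align(matrix, design)
    C, set_ids = set_contrast_matrix(matrix, design, "P")
    sets = design.sets()
    groups = np.array([sets[s]["subtype"] for s in set_ids])
    return _subtype_table(list(matrix.probe_ids), C, groups, fdr_q)


class SubtypeAnova(BaseEstimator):
    """Estimator for subtype-specificity tests.

    ``unit='pair_difference'`` analyses within-pair differences;
    ``unit='set_contrast'`` analyses within-set proband-vs-controls
    contrasts (the mixed-model interaction reduction).
    """

    def __init__(self, unit: str = "pair_difference", fdr_q: float = 0.1):
        self.unit = unit
        self.fdr_q = fdr_q

    def fit(self, matrix: ProbeMatrix, design: CohortDesign):
        if self.unit == "pair_difference":
            self.results_ = subtype_anova(matrix, design, self.fdr_q)
        elif self.unit == "set_contrast":
            self.results_ = subtype_interaction(matrix, design, self.fdr_q)
        else:
            raise ParameterError(f"unknown unit {self.unit!r}")
        fdr = self.results_["fdr"].to_numpy()
        self.selected_ = ~np.isnan(fdr) & (fdr <= self.fdr_q)
        return self
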