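"""Matched per-probe contrasts with BH-FDR and signed fold changes.

Three binary comparisons are defined on the twin cohort:

* ``PvU`` — proband versus unaffected co-twin, a paired analysis on the
  within-pair differences ``d_j = y_P - y_U``;
* ``PvC`` / ``UvC`` — case (proband or unaffected twin) versus the matched
  controls, using within-matched-set contrasts
  ``c_j = y_case - mean(controls in set j)``.

Both reduce a random-intercept mixed model to its exact closed form: in a
balanced design the between-unit information about the group effect is nil,
so the mean of the within-unit contrasts *is* the generalized-least-squares
fixed-effect estimate, with a t test on the unit-level contrasts
(``df = n_units - 1``).  P values from each genome-wide family are adjusted
with the Benjamini-Hochberg step-up procedure (FDR target 0.1 in the
motivating analysis).

Display convention: a log2 effect ``d`` is shown as the signed fold change
``2**d`` when ``d >= 0`` and ``-2**(-d)`` otherwise, so ``|fold| >= 1``
always and the sign tracks the direction of regulation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import ParameterError
from .io import CohortDesign, ProbeMatrix, align

CONTRASTS = ("PvC", "UvC", "PvU")


def signed_fold(delta_log2):
    """Signed fold change: ``2**d`` if ``d >= 0`` else ``-2**(-d)``."""
    d = np.asarray(delta_log2, dtype=float)
    out = np.where(d >= 0, 2.0**d, -(2.0 ** (-d)))
    return float(out) if np.isscalar(delta_log2) else out


def bh_adjust(pvalues, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and selection at level ``q``.

    Missing p values are excluded from the adjustment and reinserted as
    missing (never selected).  Returns ``(adjusted, selected)``.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ParameterError("q must lie in (0, 1)")
    adj = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        a = np.empty(m)
        a[order] = np.minimum(ranked, 1.0)
        adj[finite] = a
    selected = np.zeros(p.shape, dtype=bool)
    selected[finite] = adj[finite] <= q
    return adj, selected


def _unit_contrast_table(
    probe_ids, contrast: str, D: np.ndarray, fdr_q: float
) -> pd.DataFrame:
    """t statistics from a probes x units matrix of within-unit contrasts."""
    n = np.sum(~np.isnan(D), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(D, axis=1)
        sd = np.nanstd(D, axis=1, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    df = n - 1.0
    t = np.full(D.shape[0], np.nan)
    p = np.full(D.shape[0], np.nan)
    testable = (n >= 2) & (se > 0)
    t[testable] = delta[testable] / se[testable]
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df[testable])
    # exact-null degeneracy: zero spread around zero is evidence of no effect
    null_flat = (n >= 2) & (se == 0) & (delta == 0)
    t[null_flat] = 0.0
    p[null_flat] = 1.0
    delta = np.where(n >= 1, delta, np.nan)
    adj, _ = bh_adjust(p, q=fdr_q)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "contrast": contrast,
            "delta_log2": delta,
            "se": se,
            "statistic": t,
            "df": df,
            "p": p,
            "fdr": adj,
            "fold_signed": signed_fold(np.where(np.isnan(delta), 0.0, delta)),
            "n_units": n,
        }
    )


def pair_difference_matrix(
    matrix: ProbeMatrix, design: CohortDesign
) -> tuple[np.ndarray, list[str]]:
    """Probes x pairs matrix of ``y_P - y_U`` plus the pair-id order."""
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    pairs = design.pairs()
    pair_ids = sorted(pairs)
    P = np.array([idx[pairs[pid]["P"]] for pid in pair_ids])
    U = np.array([idx[pairs[pid]["U"]] for pid in pair_ids])
    return matrix.values[:, P] - matrix.values[:, U], pair_ids


def set_contrast_matrix(
    matrix: ProbeMatrix, design: CohortDesign, case_role: str = "P"
) -> tuple[np.ndarray, list[str]]:
    """Probes x sets matrix of ``y_case - mean(controls)`` per matched set."""
    if case_role not in ("P", "U"):
        raise ParameterError("case_role must be 'P' or 'U'")
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    sets = design.sets()
    set_ids = sorted(sets)
    cols = []
    for sid in set_ids:
        members = sets[sid]
        case = matrix.values[:, idx[members[case_role]]]  # type: ignore[index]
        ctrl_idx = [idx[c] for c in members["C"]]  # type: ignore[union-attr]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctrl = np.nanmean(matrix.values[:, ctrl_idx], axis=1)
        cols.append(case - ctrl)
    return np.column_stack(cols), set_ids


def contrast_PvU(
    matrix: ProbeMatrix, design: CohortDesign, fdr_q: float = 0.1
) -> pd.DataFrame:
    """Paired proband-versus-unaffected-twin test per probe."""
    matrix = align(matrix, design)
    D, _ = pair_difference_matrix(matrix, design)
    return _unit_contrast_table(matrix.probe_ids, "PvU", D, fdr_q)


def contrast_vs_controls(
    matrix: ProbeMatrix,
    design: CohortDesign,
    case_role: str = "P",
    fdr_q: float = 0.1,
) -> pd.DataFrame:
    """Case-versus-matched-controls test per probe (case role P or U).

    Equals the random-intercept-per-set GLS fixed effect on balanced data.
    """
    matrix = align(matrix, design)
    C, _ = set_contrast_matrix(matrix, design, case_role)
    name = "PvC" if case_role == "P" else "UvC"
    return _unit_contrast_table(matrix.probe_ids, name, C, fdr_q)


def all_contrasts(
    matrix: ProbeMatrix, design: CohortDesign, fdr_q: float = 0.1
) -> dict[str, pd.DataFrame]:
    return {
        "PvC": contrast_vs_controls(matrix, design, "P", fdr_q),
        "UvC": contrast_vs_controls(matrix, design, "U", fdr_q),
        "PvU": contrast_PvU(matrix, design, fdr_q),
    }


class MatchedContrastTest(BaseEstimator):
    """Sklearn-style estimator for one matched contrast.

    Parameters
    ----------
    contrast : {'PvC', 'UvC', 'PvU'}
        Which of the three cohort comparisons to run.
    fdr_q : float
        Benjamini-Hochberg selection level.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : DataFrame with per-probe effect, SE, t, df, p, fdr, signed
        fold change and the number of pairs/sets used.
    selected_ : boolean array, BH selection at ``fdr_q``.
    """

    def __init__(self, contrast: str = "PvC", fdr_q: float = 0.1):
        self.contrast = contrast
        self.fdr_q = fdr_q

    def fit(self, matrix: ProbeMatrix, design: CohortDesign):
        if self.contrast not in CONTRASTS:
            raise ParameterError(f"unknown contrast {self.contrast!r}")
        if self.contrast == "PvU":
            self.results_ = contrast_PvU(matrix, design, self.fdr_q)
        else:
            role = "P" if self.contrast == "PvC" else "U"
            self.results_ = contrast_vs_controls(matrix, design, role, self.fdr_q)
        self.selected_ = (
            self.results_["fdr"].to_numpy() <= self.fdr_q
        ) & ~self.results_["fdr"].isna().to_numpy()
        return self

    def selected_probes(self) -> list[str]:
        return list(self.results_.loc[self.selected_, "probe_id"])
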