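"""Hybridization-batch median centering and PCA quality diagnostics.

Two-color arrays hybridized in different runs show probe-level shifts that
dominate the leading principal components.  The correction subtracts, for
each probe, the median of that probe's values within each hybridization
batch, so every (probe, batch) cell block has median exactly zero.  PCA on
the probe-mean-centered matrix (no unit-variance scaling: log ratios share a
scale) then serves as the before/after diagnostic, together with a one-way
ANOVA of any candidate grouping variable on the leading component scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._exceptions import ParameterError
from .io import CohortDesign, ProbeMatrix


@dataclass
class PCAResult:
    """Sample scores on the top-k principal axes plus variance fractions."""

    scores: pd.DataFrame  # samples x k, columns PC1..PCk
    variance_fraction: np.ndarray

    def to_frame(self, labels: pd.DataFrame | None = None) -> pd.DataFrame:
        out = self.scores.copy()
        if labels is not None:
            out = out.join(labels)
        return out


class BatchMedianCenterer(BaseEstimator, TransformerMixin):
    """Per-probe, per-batch median centering (sklearn-style transformer).

    ``X`` is samples x probes.  Batch labels are supplied at fit time; the
    fitted medians are reused by :meth:`transform` for data with the same
    batch labelling.  The operation is idempotent.
    """

    def fit(self, X, y=None, *, batches):
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        if batches.shape[0] != X.shape[0]:
            raise ParameterError("one batch label per sample is required")
        self.batch_levels_ = [str(b) for b in dict.fromkeys(batches)]
        self.medians_ = {}
        for b in self.batch_levels_:
            block = X[batches == b]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(block, axis=0)
            if np.isnan(med).any():
                warnings.warn(
                    f"batch {b}: {int(np.isnan(med).sum())} probe(s) entirely "
                    "missing; left uncentered (missing)"
                )
            self.medians_[b] = med
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, batches):
        X = np.asarray(X, dtype=float).copy()
        batches = np.asarray(batches)
        for b, med in self.medians_.items():
            mask = batches == b
            X[mask] -= np.where(np.isnan(med), 0.0, med)[None, :]
        return X

    def fit_transform(self, X, y=None, *, batches):  # type: ignore[override]
        return self.fit(X, batches=batches).transform(X, batches=batches)


def median_center(matrix: ProbeMatrix, design: CohortDesign) -> ProbeMatrix:
    """Center each probe by its hybridization batch median.

    Probes entirely missing within a batch stay missing there (warning).
    """
    if matrix.sample_ids != design.subject_ids:
        from .io import align

        matrix = align(matrix, design)
    centerer = BatchMedianCenterer()
    out = centerer.fit_transform(matrix.values.T, batches=design.batches()).T
    return ProbeMatrix(list(matrix.probe_ids), list(matrix.sample_ids), out)


class CohortPCA(BaseEstimator, TransformerMixin):
    """PCA of samples over probes with per-probe mean imputation of missing.

    Thin estimator around :class:`sklearn.decomposition.PCA` (full SVD);
    scores are the sample projections on the probe-mean-centered data.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        if self.n_components <= 0:
            raise ParameterError("n_components must be positive")
        X = self._impute(np.asarray(X, dtype=float))
        if self.n_components > min(X.shape):
            raise ParameterError(
                "n_components exceeds min(n_samples, n_probes)"
            )
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self.scores_ = self._pca.fit_transform(X)
        self.variance_fraction_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X):
        return self._pca.transform(self._impute(np.asarray(X, dtype=float)))

    @staticmethod
    def _impute(X: np.ndarray) -> np.ndarray:
        if np.isnan(X).any():
            X = X.copy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_mean = np.nanmean(X, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nan_r, nan_c = np.nonzero(np.isnan(X))
            X[nan_r, nan_c] = col_mean[nan_c]
        return X


def pca(matrix: ProbeMatrix, k: int = 3) -> PCAResult:
    """Top-k principal components of the samples (probes as features)."""
    est = CohortPCA(n_components=k).fit(matrix.values.T)
    scores = pd.DataFrame(
        est.scores_,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(scores, est.variance_fraction_)


def grouping_check(pca_result: PCAResult, labels) -> np.ndarray:
    """One-way ANOVA p-value of a categorical label on each leading component.

    Returns p-values for the first (up to 3) components; a single label
    level yields missing values.
    """
    from .subtype import anova_oneway

    labels = np.asarray(labels)
    k = min(3, pca_result.scores.shape[1])
    out = np.full(k, np.nan)
    if len(set(labels.tolist())) < 2:
        return out
    for i in range(k):
        _, out[i] = anova_oneway(pca_result.scores.iloc[:, i].to_numpy(), labels)
    return out
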