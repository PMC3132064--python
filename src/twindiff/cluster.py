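"""Unsupervised structure summaries: sample clustering and category enrichment.

Samples are clustered agglomeratively on a probe subset (typically the
BH-selected differentially expressed probes), by default with correlation
distance (1 - Pearson over the subset) and average linkage — the common
choice for expression heat maps; Euclidean distance and complete linkage are
available as switches.  The first split of the dendrogram gives the
two-branch membership used to ask whether probands segregate from controls.
Category over-representation among selected probes is scored with the
hypergeometric (one-sided Fisher) tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

from ._exceptions import ParameterError
from .io import CohortDesign, ProbeMatrix


@dataclass
class Dendrogram:
    """Binary merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    sample_ids: list[str]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.sample_ids[i] for i in order]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree)


def _sample_distances(
    X: np.ndarray, distance: str
) -> np.ndarray:
    """Full sample x sample distance matrix; X is samples x probes."""
    if distance == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if distance != "correlation":
        raise ParameterError(f"unknown distance {distance!r}")
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant sample profile(s); correlation "
            "distance to other samples set to 1"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.where(constant, 1.0, np.sqrt((Xc**2).sum(axis=1)))
    R = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    D = 1.0 - R
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def hcluster(
    matrix: ProbeMatrix,
    probe_subset=None,
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples on a probe subset."""
    if linkage not in ("average", "complete"):
        raise ParameterError(f"unknown linkage {linkage!r}")
    if len(matrix.sample_ids) < 2:
        raise ParameterError("need at least 2 samples")
    if probe_subset is None:
        sub = matrix.values
    else:
        probe_subset = list(probe_subset)
        if not probe_subset:
            raise ParameterError("probe subset is empty")
        rows = {p: i for i, p in enumerate(matrix.probe_ids)}
        sub = matrix.values[[rows[p] for p in probe_subset]]
    X = sub.T.astype(float)
    if np.isnan(X).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            probe_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), np.where(np.isnan(probe_mean), 0.0, probe_mean), X)
    D = _sample_distances(X, distance)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(Z, list(matrix.sample_ids))


def two_branch_membership(dendrogram: Dendrogram) -> pd.Series:
    """Branch labels {1, 2} from the root's two children.

    Branch 1 is the child containing the lexicographically smallest
    sample id, making the labelling deterministic.
    """
    flat = hierarchy.fcluster(dendrogram.linkage, 2, criterion="maxclust")
    ids = dendrogram.sample_ids
    if len(set(flat)) == 1:  # all merges at identical height
        flat = np.ones(len(ids), dtype=int)
        flat[0] = 2
    smallest = min(ids)
    anchor = flat[ids.index(smallest)]
    labels = np.where(flat == anchor, 1, 2)
    return pd.Series(labels, index=ids, name="branch")


def category_enrichment(
    k_in: int, n_selected: int, K_in_universe: int, N_universe: int
) -> float:
    """Hypergeometric upper-tail probability of >= k_in category members.

    ``n_selected`` probes drawn from a universe of ``N_universe`` containing
    ``K_in_universe`` category members.
    """
    ok = (
        0 <= k_in <= min(n_selected, K_in_universe)
        and 0 < n_selected <= N_universe
        and 0 <= K_in_universe <= N_universe
        and k_in >= max(0, n_selected + K_in_universe - N_universe)
    )
    if not ok:
        raise ParameterError("inconsistent enrichment counts")
    return float(hypergeom.sf(k_in - 1, N_universe, K_in_universe, n_selected))


class SampleClustering(BaseEstimator):
    """Estimator wrapping :func:`hcluster` with two-branch membership.

    Attributes after fit: ``dendrogram_``, ``branches_`` (pd.Series of
    {1, 2} per sample), ``leaf_order_``.
    """

    def __init__(
        self,
        probe_subset=None,
        distance: str = "correlation",
        linkage: str = "average",
    ):
        self.probe_subset = probe_subset
        self.distance = distance
        self.linkage = linkage

    def fit(self, matrix: ProbeMatrix, design: CohortDesign | None = None):
        self.dendrogram_ = hcluster(
            matrix, self.probe_subset, self.distance, self.linkage
        )
        self.branches_ = two_branch_membership(self.dendrogram_)
        self.leaf_order_ = self.dendrogram_.leaf_order()
        return self
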