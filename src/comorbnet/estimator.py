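"""scikit-learn style estimators over the association and bootstrap engines.

Both estimators accept a subjects x diseases binary matrix (DataFrame or
ndarray, NaN = missing) and follow the sklearn contract: parameters set in
``__init__``, computation in ``fit``, fitted attributes with trailing
underscores, ``get_params``/``set_params`` inherited from ``BaseEstimator``.
They compose with sklearn model-selection utilities where that makes sense
(e.g. cloning inside a grid over bootstrap settings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import pairwise_table
from .bootstrap import (
    BootstrapConfig,
    bootstrap_pairs,
    network_density,
    node_connectivity,
    significant_edges,
)
from .cohort import CohortTable


def _as_cohort(X, feature_names=None) -> CohortTable:
    """Wrap a plain matrix as a CohortTable (flags all zero, unused here)."""
    if isinstance(X, CohortTable):
        return X
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("X must be a 2D subjects x diseases matrix")
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"d{i}" for i in range(values.shape[1])]
        )
    n = values.shape[0]
    subjects = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    return CohortTable(
        subjects, np.zeros(n), np.zeros(n), pd.DataFrame(values, columns=names)
    )


class PairwiseAssociation(BaseEstimator):
    """Pooled-sample pairwise association statistics.

    ``fit`` computes, for every disease pair over pairwise-complete subjects,
    the phi coefficient, the co-occurrence relative risk with its 95% CI and
    the chi-square/Fisher p-value.

    Attributes
    ----------
    table_ : DataFrame
        Long-format per-pair statistics.
    phi_ : ndarray of shape (K, K)
        Symmetric phi matrix, NaN where undefined, 1 on the diagonal.
    feature_names_in_ : list of str
    """

    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        self.feature_names_in_ = cohort.disease_names
        self.n_features_in_ = len(self.feature_names_in_)
        self.table_ = pairwise_table(cohort)
        k = self.n_features_in_
        phi = np.full((k, k), np.nan)
        np.fill_diagonal(phi, 1.0)
        idx = {d: i for i, d in enumerate(self.feature_names_in_)}
        for row in self.table_.itertuples():
            a, b = idx[row.disease_i], idx[row.disease_j]
            phi[a, b] = phi[b, a] = row.phi
        self.phi_ = phi
        return self


class BootstrapNetwork(BaseEstimator):
    """Bootstrap comorbidity-network estimator.

    Parameters mirror :class:`~comorbnet.bootstrap.BootstrapConfig` plus the
    connectivity aggregation mode.  ``fit`` runs the within-stratum resampling
    engine and derives the network summaries.

    Attributes
    ----------
    result_ : BootstrapResult
        Full per-pair distributions and summaries.
    density_ : float
        Mean of per-pair mean phi over all candidate pairs.
    edges_ : set of (str, str)
        Pairs passing the lower-percentile > 0 rule.
    connectivity_ : dict
        Disease -> aggregated incident mean phi.
    mean_phi_ : ndarray of shape (K, K)
        Symmetric matrix of per-pair bootstrap mean phi.
    """

    def __init__(
        self,
        n_resamples: int = 10_000,
        resample_size: int | None = None,
        percentile: float = 0.025,
        connectivity_mode: str = "mean",
        compute_pair_tests: bool = True,
        random_state: int = 0,
        stratum_label: str = "all",
    ):
        self.n_resamples = n_resamples
        self.resample_size = resample_size
        self.percentile = percentile
        self.connectivity_mode = connectivity_mode
        self.compute_pair_tests = compute_pair_tests
        self.random_state = random_state
        self.stratum_label = stratum_label

    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        config = BootstrapConfig(
            n_resamples=self.n_resamples,
            resample_size=self.resample_size,
            percentile=self.percentile,
            seed=self.random_state,
            compute_pair_tests=self.compute_pair_tests,
        )
        self.feature_names_in_ = cohort.disease_names
        self.n_features_in_ = len(self.feature_names_in_)
        res = bootstrap_pairs(cohort, None, config, self.stratum_label)
        self.result_ = res
        self.density_ = network_density(res)
        self.edges_ = significant_edges(res)
        self.connectivity_ = node_connectivity(res, self.connectivity_mode)
        k = self.n_features_in_
        mat = np.full((k, k), np.nan)
        idx = {d: i for i, d in enumerate(res.disease_names)}
        for (a, b), v in zip(res.pairs, res.mean_phi):
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = v
        self.mean_phi_ = mat
        return self
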