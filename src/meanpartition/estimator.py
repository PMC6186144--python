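"""Scikit-learn style estimator for the mean (consensus) partition."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from .config import MeanConfig
from .errors import ConfigError
from .mean_classic import approximate_mean
from .mean_dynamic import approximate_mean_dynamic
from .sample import PosteriorSample

__all__ = ["MeanPartition"]


class MeanPartition(BaseEstimator):
    """Mean partition of a sample of clusterings, by local search.

    Finds an approximate minimizer of the weighted objective
    ``sum_k w_k * D(mean, P_k)^exponent`` over partitions, where ``D`` is
    the partition distance (minimum number of elements to delete from both
    partitions to equalize them) — the consensus summary of a clustering
    posterior, e.g. the partitions drawn by a Dirichlet-process mixture
    sampler.

    Parameters
    ----------
    algorithm : {"dynamic", "classic"}, default="dynamic"
        "classic" recomputes every distance from scratch per candidate
        move; "dynamic" maintains one Hungarian graph state per sample
        partition and updates it per move.  Both produce identical results;
        "dynamic" is faster.
    strategy : {"rematch", "case-analysis"}, default="rematch"
        Dynamic engine only: how a candidate move is scored (see
        :mod:`meanpartition.costchange`).
    exponent : {1, 2}, default=2
        Power applied to each distance in the objective.
    init : {"best-sample", "singletons", "one-cluster", "crp"}
        Initial candidate rule.
    best_of_row : bool, default=False
        Evaluate all target clusters per element and take the best move,
        instead of accepting the first strict improvement.
    collapse_duplicates : bool, default=True
        Merge identical sample partitions, summing their weights
        (multiplicities are the empirical posterior probabilities).
    max_cycles : int, default=1000
        Safety cap on full scans.
    random_state : int or None
        Seed; only consulted by the "crp" init.
    verify : bool, default=False
        Debug mode: cross-check every dynamic distance against a
        from-scratch recomputation (slow).

    Attributes
    ----------
    labels_ : ndarray of shape (n_elements,)
        Canonical cluster labels of the mean partition.
    n_clusters_ : int
    objective_ : float
        Final objective value.
    n_cycles_ : int
    converged_ : bool
    result_ : MeanResult
        Full result including the accepted-move trace.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 1, 1]])
    >>> MeanPartition().fit_predict(X)
    array([0, 0, 1, 1])
    """

    def __init__(self, *, algorithm: str = "dynamic",
                 strategy: str = "rematch", exponent: int = 2,
                 init: str = "best-sample", best_of_row: bool = False,
                 collapse_duplicates: bool = True, max_cycles: int = 1000,
                 random_state=None, verify: bool = False):
        self.algorithm = algorithm
        self.strategy = strategy
        self.exponent = exponent
        self.init = init
        self.best_of_row = best_of_row
        self.collapse_duplicates = collapse_duplicates
        self.max_cycles = max_cycles
        self.random_state = random_state
        self.verify = verify

    def _as_sample(self, X, sample_weight) -> PosteriorSample:
        if isinstance(X, PosteriorSample):
            sample = X if sample_weight is None else \
                PosteriorSample(X.partitions, sample_weight)
            return sample.collapsed() if self.collapse_duplicates else sample
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ConfigError("X must be a (K, N) label matrix with K,N >= 1")
        if not np.issubdtype(X.dtype, np.integer):
            if not np.all(np.equal(np.mod(X, 1), 0)):
                raise ConfigError("labels must be integral")
            X = X.astype(np.int64)
        return PosteriorSample.from_labels(X, sample_weight,
                                           collapse=self.collapse_duplicates)

    def fit(self, X, y=None, sample_weight=None) -> "MeanPartition":
        """Compute the mean partition of the sample ``X``.

        ``X`` is a (K, N) integer label matrix — row k gives the cluster
        label of every element under sample partition k — or a
        :class:`PosteriorSample`.
        """
        if self.algorithm not in ("classic", "dynamic"):
            raise ConfigError("algorithm must be 'classic' or 'dynamic'")
        if not isinstance(self.max_cycles, numbers.Integral):
            raise ConfigError("max_cycles must be an integer")
        sample = self._as_sample(X, sample_weight)
        seed = None if self.random_state is None else int(self.random_state)
        cfg = MeanConfig(exponent=self.exponent, init=self.init,
                         best_of_row=self.best_of_row, strategy=self.strategy,
                         max_cycles=int(self.max_cycles), seed=seed,
                         verify=self.verify)
        if self.algorithm == "classic":
            result = approximate_mean(sample, cfg)
        else:
            result = approximate_mean_dynamic(sample, cfg)
        self.result_ = result
        self.labels_ = result.mean.labels.copy()
        self.n_clusters_ = result.mean.n_clusters
        self.objective_ = result.objective
        self.n_cycles_ = result.cycles
        self.converged_ = result.converged
        self.n_features_in_ = sample.n_elements
        return self

    def fit_predict(self, X, y=None, sample_weight=None) -> np.ndarray:
        """Fit and return the mean partition's labels."""
        return self.fit(X, y, sample_weight=sample_weight).labels_
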