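"""Modularity communities of muscles and comparison with the homunculus.

Community detection maximizes the (unnormalized) modularity

    Q = sum_ij (B_ij - gamma * P_ij) * delta(g_i, g_j)

on the muscle-centric weight matrix B, where P is the Newman-Girvan
null expectation.  Following the resolution-parameter formulation, the
matrix is first adjusted to B' = B - gamma * k k^T / sum(k) with
k_p = sum_q B_pq, and a locally greedy, Louvain-like algorithm then
maximizes sum_ij B'_ij delta(g_i, g_j).  Because single runs are
stochastic (seeded tie-breaking), a consensus partition is extracted
from many runs by thresholding the co-assignment matrix at its
permutation-null expectation and re-clustering to convergence.

Partition similarity is measured by the z-score of the Rand
coefficient under the hypergeometric permutation model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .hypergraph import Projection

__all__ = [
    "ModularityModel", "Partition", "adjusted_matrix", "modularity",
    "ModularityClustering", "ConsensusClustering", "louvain_partition",
    "consensus_partition", "z_rand", "resolution_sweep",
]


@dataclass
class ModularityModel:
    """Resolution-adjusted modularity matrix B' = B - gamma k k^T / sum k."""

    base: np.ndarray
    gamma: float
    strengths: np.ndarray
    adjusted: np.ndarray
    labels: list[str] | None = None


@dataclass
class Partition:
    """Muscle -> community assignment with contiguous labels from 1."""

    labels: np.ndarray
    quality: float
    provenance: dict

    def __post_init__(self) -> None:
        _, self.labels = np.unique(np.asarray(self.labels), return_inverse=True)
        self.labels = self.labels + 1

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())


def _as_matrix(B) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(B, Projection):
        return np.asarray(B.weights, dtype=float), list(B.labels)
    return np.asarray(B, dtype=float), None


def adjusted_matrix(B, gamma: float) -> ModularityModel:
    """Subtract the resolution-scaled Newman-Girvan null term from B."""
    W, labels = _as_matrix(B)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    total = W.sum()
    if total == 0:
        raise ValueError("degenerate all-zero weight matrix")
    k = W.sum(axis=1)
    adjusted = W - gamma * np.outer(k, k) / total
    return ModularityModel(W, gamma, k, adjusted, labels)


def modularity(B, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Direct evaluation of Q = sum_ij B'_ij delta(g_i, g_j)."""
    model = B if isinstance(B, ModularityModel) else adjusted_matrix(B, gamma)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(model.adjusted[same].sum())


def _greedy_louvain(W: np.ndarray, rng: np.random.Generator,
                    max_sweeps: int = 100) -> np.ndarray:
    """One level of greedy node moves on a (possibly signed) modularity
    matrix W; the diagonal stays with its node and never affects moves."""
    n = W.shape[0]
    labels = np.arange(n)
    Wo = W.copy()
    np.fill_diagonal(Wo, 0.0)
    for _ in range(max_sweeps):
        moved = False
        for node in rng.permutation(n):
            current = labels[node]
            # affinity of node to every community
            aff = np.zeros(n)
            np.add.at(aff, labels, Wo[node])
            best, best_gain = current, 0.0
            base = aff[current]
            for c in np.unique(labels):
                if c == current:
                    continue
                gain = aff[c] - base
                if gain > best_gain + 1e-12:
                    best, best_gain = c, gain
            if best != current:
                labels[node] = best
                moved = True
        if not moved:
            break
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    agg = np.zeros((k, k))
    for a in range(k):
        ia = labels == a
        for b in range(a, k):
            ib = labels == b
            agg[a, b] = agg[b, a] = W[np.ix_(ia, ib)].sum()
    return agg


class ModularityClustering(BaseEstimator, ClusterMixin):
    """Louvain-like greedy modularity maximization with resolution gamma.

    Parameters
    ----------
    gamma : resolution parameter of the Newman-Girvan null term; larger
        values favour more, smaller communities.
    random_state : seed for the node-visit order (tie-breaking).
    max_sweeps : cap on move sweeps per aggregation level.

    Attributes
    ----------
    labels_ : community id per node, 0-based contiguous.
    modularity_ : Q of the returned partition (unnormalized).
    n_communities_ : number of communities.
    """

    def __init__(self, gamma: float = 1.0, random_state: int | None = None,
                 max_sweeps: int = 100):
        self.gamma = gamma
        self.random_state = random_state
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        model = (X if isinstance(X, ModularityModel)
                 else adjusted_matrix(X, self.gamma))
        W = model.adjusted
        n = W.shape[0]
        rng = np.random.default_rng(self.random_state)
        labels = np.arange(n)
        level_W = W
        while True:
            level_labels = _greedy_louvain(level_W, rng, self.max_sweeps)
            if level_labels.max() + 1 == level_W.shape[0]:
                break  # no merge happened at this level
            labels = level_labels[labels]
            level_W = _aggregate(level_W, level_labels)
        _, labels = np.unique(labels, return_inverse=True)
        self.labels_ = labels
        self.modularity_ = modularity(model, labels)
        self.n_communities_ = int(labels.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _coassignment(partitions: np.ndarray) -> np.ndarray:
    """Fraction of runs assigning each node pair to the same community."""
    runs, n = partitions.shape
    C = np.zeros((n, n))
    for p in partitions:
        C += p[:, None] == p[None, :]
    return C / runs


def _null_coassignment(partitions: np.ndarray) -> float:
    """Expected co-assignment of a random node pair under label
    permutation, averaged over runs."""
    runs, n = partitions.shape
    expect = 0.0
    for p in partitions:
        sizes = np.bincount(p)
        expect += (sizes * (sizes - 1)).sum() / (n * (n - 1))
    return expect / runs


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Consensus over many stochastic modularity partitions.

    Runs :class:`ModularityClustering` *n_runs* times, thresholds the
    co-assignment matrix at its permutation-null expectation, and
    re-clusters the thresholded matrix iteratively until all runs agree.

    Attributes
    ----------
    labels_ : consensus community per node.
    runs_ : (n_runs, n) array of the level-0 partitions.
    n_communities_ : number of consensus communities.
    """

    def __init__(self, gamma: float = 1.0, n_runs: int = 100,
                 random_state: int | None = None, consensus_gamma: float = 1.0,
                 max_iter: int = 20):
        self.gamma = gamma
        self.n_runs = n_runs
        self.random_state = random_state
        self.consensus_gamma = consensus_gamma
        self.max_iter = max_iter

    def fit(self, X, y=None):
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_runs)
        runs = np.array([
            ModularityClustering(
                self.gamma,
                random_state=int(s.generate_state(1)[0] % (2 ** 31)),
            ).fit_predict(X)
            for s in seeds
        ])
        self.runs_ = runs.copy()
        for it in range(self.max_iter):
            if all(np.array_equal(_canon(runs[0]), _canon(p)) for p in runs[1:]):
                break
            C = _coassignment(runs)
            tau = _null_coassignment(runs)
            C = np.where(C > tau, C, 0.0)
            np.fill_diagonal(C, 0.0)
            if C.sum() == 0:  # nothing above chance: fall back to plurality
                break
            seeds = np.random.SeedSequence([self.random_state or 0, it + 1]
                                           ).spawn(len(runs))
            runs = np.array([
                ModularityClustering(
                    self.consensus_gamma,
                    random_state=int(s.generate_state(1)[0] % (2 ** 31)),
                ).fit_predict(C)
                for s in seeds
            ])
        self.labels_ = _canon(runs[0])
        self.n_communities_ = int(self.labels_.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _canon(labels: np.ndarray) -> np.ndarray:
    """Relabel communities in order of first appearance."""
    _, idx = np.unique(labels, return_index=True)
    mapping = {labels[i]: rank for rank, i in enumerate(sorted(idx))}
    return np.array([mapping[l] for l in labels])


def louvain_partition(model, rng_seed: int = 0) -> Partition:
    """Single seeded Louvain-like run returning a :class:`Partition`."""
    est = ModularityClustering(
        gamma=model.gamma if isinstance(model, ModularityModel) else 1.0,
        random_state=rng_seed).fit(model)
    return Partition(est.labels_, est.modularity_,
                     {"seed": rng_seed, "method": "louvain"})


def consensus_partition(partitions: Sequence[Partition | np.ndarray],
                        rng_seed: int = 0, max_iter: int = 20) -> Partition:
    """Consensus of pre-computed partitions via co-assignment clustering."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    arrs = [p.labels if isinstance(p, Partition) else np.asarray(p)
            for p in partitions]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("partitions cover non-identical node sets")
    runs = np.array([_canon(a) for a in arrs])
    for it in range(max_iter):
        if all(np.array_equal(runs[0], p) for p in runs[1:]):
            break
        C = _coassignment(runs)
        tau = _null_coassignment(runs)
        C = np.where(C > tau, C, 0.0)
        np.fill_diagonal(C, 0.0)
        if C.sum() == 0:
            break
        runs = np.array([
            ModularityClustering(1.0, random_state=rng_seed + 7 * it + r
                                 ).fit_predict(C)
            for r in range(len(runs))
        ])
        runs = np.array([_canon(p) for p in runs])
    labels = runs[0]
    return Partition(labels, np.nan, {"seed": rng_seed, "method": "consensus"})


def z_rand(p1, p2) -> float:
    """z-score of the Rand coefficient under the permutation model.

    Uses the exact hypergeometric mean and variance of the pair count w
    (number of node pairs co-assigned in both partitions) given the two
    group-size profiles.  Symmetric in its arguments.  Returns NaN with
    a warning for degenerate partitions (zero variance).
    """
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same node set")
    n = len(a)
    M = n * (n - 1) / 2
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na = np.bincount(ai).astype(float)
    nb = np.bincount(bi).astype(float)
    cont = np.zeros((len(na), len(nb)))
    np.add.at(cont, (ai, bi), 1.0)
    w = float((cont * (cont - 1) / 2).sum())
    M1 = float((na * (na - 1) / 2).sum())
    M2 = float((nb * (nb - 1) / 2).sum())
    mean_w = M1 * M2 / M
    C1 = n * (n ** 2 - 3 * n - 2) - 8 * (n + 1) * M1 + 4 * (na ** 3).sum()
    C2 = n * (n ** 2 - 3 * n - 2) - 8 * (n + 1) * M2 + 4 * (nb ** 3).sum()
    var_w = (M / 16
             - (4 * M1 - 2 * M) ** 2 * (4 * M2 - 2 * M) ** 2 / (256 * M ** 2)
             + C1 * C2 / (16 * n * (n - 1) * (n - 2))
             + ((4 * M1 - 2 * M) ** 2 - 4 * C1 - 4 * M)
             * ((4 * M2 - 2 * M) ** 2 - 4 * C2 - 4 * M)
             / (64 * n * (n - 1) * (n - 2) * (n - 3)))
    if var_w <= 0:
        warnings.warn("degenerate partitions: z_rand undefined (zero variance)")
        return float("nan")
    return (w - mean_w) / np.sqrt(var_w)


def resolution_sweep(B, gamma_grid: Sequence[float], runs: int = 100,
                     random_state: int = 0) -> pd.DataFrame:
    """Consensus community count per gamma plus adjacent-gamma stability.

    Returns a table with columns gamma, n_communities and
    stability_z_rand (z-Rand between this gamma's consensus and the
    previous one; NaN for the first row).
    """
    gammas = list(gamma_grid)
    if gammas != sorted(gammas):
        raise ValueError("gamma_grid must be ascending")
    rows, prev = [], None
    for g in gammas:
        est = ConsensusClustering(gamma=g, n_runs=runs,
                                  random_state=random_state).fit(B)
        stab = np.nan
        if prev is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stab = z_rand(prev, est.labels_)
        rows.append({"gamma": g, "n_communities": est.n_communities_,
                     "stability_z_rand": stab})
        prev = est.labels_
    return pd.DataFrame(rows)
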