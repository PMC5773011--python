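"""One-dimensional muscle ordering from network topology.

The weighted muscle-centric matrix is binarized (edge iff weight above a
threshold, default 0), hop-count shortest paths between muscles form a
distance matrix — with unreachable pairs encoded as distance 0, a
deliberate convention kept as the faithful default (an alternative
restricts to the largest connected component) — and classical
(Torgerson) MDS of that matrix yields a scalar coordinate per muscle:
the first principal coordinate of the double-centered squared-distance
matrix.  Variants: a weighted-distance pipeline (edge length 1/weight,
Dijkstra) that avoids thresholding, and short-/long-connection subgraphs
split at the mean Euclidean centroid distance of connected muscle pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .hypergraph import Hypergraph, Projection

__all__ = [
    "DistanceMatrix", "LinearOrdering", "binarize", "shortest_paths",
    "mds_coordinate", "max_connected_threshold", "weighted_distance_matrix",
    "split_by_physical_length", "muscle_centroids", "ShortestPathMDS",
]


@dataclass
class DistanceMatrix:
    """Symmetric muscle-muscle distance matrix with provenance."""

    labels: list[str]
    values: np.ndarray
    threshold: float | None
    variant: Literal["binary_bfs", "weighted"]
    has_disconnected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class LinearOrdering:
    """First principal coordinate per muscle (defined up to sign)."""

    labels: list[str]
    coordinate: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self, variant: str = "binary_bfs",
                 threshold: float | None = 0.0) -> pd.DataFrame:
        return pd.DataFrame({"muscle": self.labels,
                             "coordinate": self.coordinate,
                             "variant": variant, "threshold": threshold})


def binarize(B: Projection | np.ndarray, threshold: float = 0.0) -> nx.Graph:
    """Edge iff projection weight > threshold; warns if this disconnects
    the graph (the distance matrix then contains 0-coded pairs)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    W = B.weights if isinstance(B, Projection) else np.asarray(B)
    labels = (list(B.labels) if isinstance(B, Projection)
              else list(range(W.shape[0])))
    g = nx.Graph()
    g.add_nodes_from(labels)
    ii, jj = np.nonzero(np.triu(W > threshold, k=1))
    g.add_edges_from((labels[i], labels[j]) for i, j in zip(ii, jj))
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        warnings.warn(f"threshold {threshold} disconnects the graph; "
                      "unreachable pairs will be distance-coded 0")
    return g


def max_connected_threshold(B: Projection | np.ndarray) -> float:
    """Largest threshold that keeps the binarized graph connected."""
    W = B.weights if isinstance(B, Projection) else np.asarray(B)
    candidates = np.unique(W[W > 0])
    best = 0.0
    for t in candidates:
        g = nx.from_numpy_array((W > t).astype(int))
        if g.number_of_edges() and nx.is_connected(g):
            best = float(t)
        else:
            break
    return best


def shortest_paths(g: nx.Graph,
                   labels: list | None = None) -> DistanceMatrix:
    """BFS hop-count distances; unreachable pairs are encoded 0 (flagged
    in metadata)."""
    labels = labels if labels is not None else list(g.nodes)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    reachable = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        reachable += len(dists)
        for dst, d in dists.items():
            D[index[src], index[dst]] = d
    disconnected = reachable < n * n
    return DistanceMatrix(list(labels), D, None, "binary_bfs", disconnected)


def weighted_distance_matrix(B: Projection | np.ndarray) -> DistanceMatrix:
    """Thresholding-free variant: edge length 1/weight, Dijkstra paths."""
    W = B.weights if isinstance(B, Projection) else np.asarray(B)
    labels = (list(B.labels) if isinstance(B, Projection)
              else list(range(W.shape[0])))
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    g = nx.Graph()
    g.add_nodes_from(range(len(labels)))
    ii, jj = np.nonzero(np.triu(W > 0, k=1))
    g.add_weighted_edges_from((i, j, 1.0 / W[i, j]) for i, j in zip(ii, jj))
    n = len(labels)
    D = np.zeros((n, n))
    disconnected = False
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n):
        row = lengths.get(i, {})
        for j, d in row.items():
            D[i, j] = d
        if len(row) < n:
            disconnected = True
    D = (D + D.T) / 2
    dm = DistanceMatrix(labels, D, None, "weighted", disconnected)
    return dm


def mds_coordinate(D: DistanceMatrix | np.ndarray) -> LinearOrdering:
    """Classical (Torgerson) MDS, first principal coordinate.

    Double-centers -1/2 * J D^2 J and returns the leading eigenvector
    scaled by the square root of its eigenvalue.  Coordinates are
    centered at zero and defined only up to a global sign.
    """
    if isinstance(D, DistanceMatrix):
        labels, vals = D.labels, D.values
    else:
        vals = np.asarray(D, dtype=float)
        labels = list(range(vals.shape[0]))
    n = vals.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (vals ** 2) @ J
    Bmat = (Bmat + Bmat.T) / 2
    evals, evecs = eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 1e-12:
        raise ValueError("degenerate geometry: leading eigenvalue <= 0")
    coord = evecs[:, 0] * np.sqrt(evals[0])
    return LinearOrdering(list(labels), coord, evals)


def muscle_centroids(h: Hypergraph,
                     coordinates: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Centroid of each muscle = mean position of its member bones."""
    out = {}
    for m in h.muscle_labels:
        bones = h.members(m)
        missing = [b for b in bones if b not in coordinates]
        if missing:
            raise ValueError(f"missing centroids/coordinates for bones {missing}"
                             f" of muscle {m!r}")
        out[m] = np.mean([np.asarray(coordinates[b], dtype=float)[:3]
                          for b in bones], axis=0)
    return out


def split_by_physical_length(h: Hypergraph | Projection,
                             centroids: Mapping[str, np.ndarray],
                             which: Literal["short", "long"],
                             projection: Projection | None = None) -> Projection:
    """Keep only muscle-muscle connections shorter (<=) or longer (>)
    than the mean Euclidean centroid distance over existing connections.

    Edges exactly at the mean go to the short subgraph by convention, so
    short and long edge sets partition the full set.
    """
    from .hypergraph import project
    if isinstance(h, Projection):
        B = h
    else:
        B = projection or project(h, "muscle_centric")
    labels = list(B.labels)
    missing = [m for m in labels if m not in centroids]
    if missing:
        raise ValueError(f"missing centroids for muscles: {missing[:10]}")
    pts = np.array([np.asarray(centroids[m], dtype=float)[:3] for m in labels])
    W = B.weights
    ii, jj = np.nonzero(np.triu(W > 0, k=1))
    if len(ii) == 0:
        raise ValueError("projection has no connections to split")
    lengths = np.linalg.norm(pts[ii] - pts[jj], axis=1)
    mean_len = lengths.mean()
    keep = lengths <= mean_len if which == "short" else lengths > mean_len
    Wout = np.zeros_like(W)
    Wout[ii[keep], jj[keep]] = W[ii[keep], jj[keep]]
    Wout = Wout + Wout.T
    return Projection(labels, Wout, B.kind)


class ShortestPathMDS(BaseEstimator, TransformerMixin):
    """Transformer: muscle-centric weights -> 1D linear coordinate.

    Parameters
    ----------
    threshold : binarization threshold (edge iff weight > threshold);
        ignored by the weighted variant.
    variant : 'binary_bfs' (threshold + hop counts) or 'weighted'
        (edge length 1/weight, Dijkstra, no thresholding).
    disconnected : 'zero' keeps the 0-for-unreachable convention;
        'lcc' restricts the analysis to the largest connected component
        (coordinates of dropped muscles are NaN).

    Attributes
    ----------
    coordinate_ : per-muscle scalar coordinate.
    eigenvalues_ : MDS eigenvalue spectrum (diagnostics).
    distance_matrix_ : the :class:`DistanceMatrix` used.
    """

    def __init__(self, threshold: float = 0.0,
                 variant: Literal["binary_bfs", "weighted"] = "binary_bfs",
                 disconnected: Literal["zero", "lcc"] = "zero"):
        self.threshold = threshold
        self.variant = variant
        self.disconnected = disconnected

    def fit(self, X, y=None):
        B = X
        W = B.weights if isinstance(B, Projection) else np.asarray(B)
        labels = (list(B.labels) if isinstance(B, Projection)
                  else list(range(W.shape[0])))
        if self.variant == "weighted":
            dm = weighted_distance_matrix(B)
            dm = DistanceMatrix(labels, dm.values, None, "weighted",
                                dm.has_disconnected)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = binarize(W, self.threshold)
            dm = shortest_paths(g, labels=list(g.nodes))
            dm = DistanceMatrix(labels, dm.values, self.threshold,
                                "binary_bfs", dm.has_disconnected)
        coord = np.full(len(labels), np.nan)
        if dm.has_disconnected and self.disconnected == "lcc":
            gg = nx.from_numpy_array((dm.values > 0).astype(int))
            comp = max(nx.connected_components(gg), key=len)
            idx = sorted(comp)
            sub = dm.values[np.ix_(idx, idx)]
            ordering = mds_coordinate(sub)
            coord[idx] = ordering.coordinate
            self.eigenvalues_ = ordering.eigenvalues
        else:
            ordering = mds_coordinate(dm)
            coord = ordering.coordinate
            self.eigenvalues_ = ordering.eigenvalues
        self.labels_in_ = labels
        self.coordinate_ = coord
        self.distance_matrix_ = dm
        return self

    def transform(self, X=None):
        return self.coordinate_.reshape(-1, 1)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()

    def to_ordering(self) -> LinearOrdering:
        return LinearOrdering(self.labels_in_, self.coordinate_,
                              self.eigenvalues_)
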