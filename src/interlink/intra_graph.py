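"""Patient-similarity graphs from a single expression layer.

Patients are nodes; edge weights come from a Gaussian kernel on the Euclidean
distance between expression profiles, restricted to k-nearest-neighbor pairs
(an edge exists if either endpoint lists the other among its k nearest).
The module also provides the graph Laplacian L = D - W and a random
edge-removal operator used to emulate incomplete similarity information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .datasets import ExpressionDataset, standardize_features
from .errors import ConfigurationError, InvalidLaplacianError

__all__ = [
    "SimilarityGraph",
    "GraphLaplacian",
    "build_knn_gaussian_graph",
    "laplacian",
    "damage_graph",
    "median_bandwidth",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric nonnegative patients x patients weight matrix, zero diagonal."""

    weights: np.ndarray
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        n = len(self.patient_ids)
        if w.shape != (n, n):
            raise ConfigurationError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.all(np.isfinite(w)):
            raise ConfigurationError("weights contain non-finite entries")
        if np.any(w < 0):
            raise ConfigurationError("weights must be nonnegative")
        if np.abs(w - w.T).max(initial=0.0) > _SYM_TOL:
            raise ConfigurationError("weight matrix is not symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ConfigurationError("weight matrix diagonal must be zero")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero upper-triangle entries)."""
        iu = np.triu_indices(self.n_patients, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def write_edge_list(self, path) -> None:
        iu, ju = np.triu_indices(self.n_patients, k=1)
        mask = self.weights[iu, ju] != 0
        pd.DataFrame(
            {
                "patient_i": [self.patient_ids[i] for i in iu[mask]],
                "patient_j": [self.patient_ids[j] for j in ju[mask]],
                "weight": self.weights[iu[mask], ju[mask]],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GraphLaplacian:
    """L = D - W with D = diag(row sums of W); symmetric PSD, zero row sums."""

    matrix: np.ndarray
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        n = len(self.patient_ids)
        if m.shape != (n, n):
            raise InvalidLaplacianError(f"Laplacian shape {m.shape} != ({n}, {n})")
        if np.abs(m - m.T).max(initial=0.0) > _SYM_TOL:
            raise InvalidLaplacianError("Laplacian is not symmetric")
        scale = max(1.0, np.abs(m).max(initial=0.0))
        if np.abs(m.sum(axis=1)).max(initial=0.0) > 1e-8 * scale:
            raise InvalidLaplacianError("Laplacian rows do not sum to zero")
        if np.any(np.diag(m) < -1e-12):
            raise InvalidLaplacianError("Laplacian has negative degree entries")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def median_bandwidth(distances_sq: np.ndarray) -> float:
    """Median-heuristic bandwidth: sigma^2 = median nonzero squared distance."""
    iu = np.triu_indices(distances_sq.shape[0], k=1)
    vals = distances_sq[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.sqrt(np.median(vals)))


def build_knn_gaussian_graph(
    data: ExpressionDataset,
    k: int = 5,
    sigma: float | None = None,
    standardize: bool = True,
) -> SimilarityGraph:
    """Gaussian-weighted k-NN patient graph.

    w_ij = exp(-||x_i - x_j||^2 / sigma^2) when i is among j's k nearest
    neighbors or vice versa (OR rule, which makes W symmetric), else 0.
    Nearest-neighbor ties are broken by patient order. ``sigma=None`` selects
    the median heuristic (sigma^2 = median of the nonzero squared pairwise
    distances). Features are standardized before distances unless
    ``standardize=False``.
    """
    n = data.n_patients
    if not 1 <= k < n:
        raise ConfigurationError(f"k={k} must satisfy 1 <= k < n_patients={n}")
    if sigma is not None and sigma <= 0:
        raise ConfigurationError(f"sigma={sigma} must be positive")

    x = standardize_features(data.values) if standardize else np.asarray(data.values, float)
    d2 = squareform(pdist(x, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
    if sigma is None:
        sigma = median_bandwidth(d2)

    # stable argsort on distance-with-self-excluded gives index-order tie-breaks
    order = np.argsort(d2 + np.where(np.eye(n, dtype=bool), np.inf, 0.0), axis=1, kind="stable")
    neighbor = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    neighbor[rows, order[:, :k].ravel()] = True
    adjacency = neighbor | neighbor.T

    w = np.where(adjacency, np.exp(-d2 / sigma**2), 0.0)
    np.fill_diagonal(w, 0.0)
    return SimilarityGraph(w, data.patient_ids)


def laplacian(graph: SimilarityGraph) -> GraphLaplacian:
    """Unnormalized graph Laplacian L = D - W."""
    w = graph.weights
    return GraphLaplacian(np.diag(w.sum(axis=1)) - w, graph.patient_ids)


def damage_graph(graph: SimilarityGraph, fraction: float, seed: int) -> SimilarityGraph:
    """Remove a uniformly random ``round(fraction * E)`` of the E undirected edges.

    Both directions of each selected edge are zeroed, so symmetry is
    preserved; surviving weights are unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction={fraction} outside [0, 1]")
    w = graph.weights.copy()
    iu, ju = np.triu_indices(graph.n_patients, k=1)
    mask = w[iu, ju] != 0
    edges_i, edges_j = iu[mask], ju[mask]
    n_edges = edges_i.size
    n_remove = int(round(fraction * n_edges))
    if n_remove:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_edges, size=n_remove, replace=False)
        w[edges_i[chosen], edges_j[chosen]] = 0.0
        w[edges_j[chosen], edges_i[chosen]] = 0.0
    return SimilarityGraph(w, graph.patient_ids)
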