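"""Reconstructed patient graphs from miRNA -> target-gene inter-relations.

The similarity between patient i's miRNA profile and patient j's gene profile
cannot be taken with an ordinary vector metric because the two layers have
different dimensions. Instead the cross-layer score

    f_ij = sum over target pairs (l, m) of miRNA(i, l) * gene(j, m)

sums the products of a miRNA's expression in patient i and its target gene's
expression in patient j over exactly the known target pairs. The raw scores
are z-normalized over the whole matrix, squashed through a logistic to (0, 1)
and symmetrized, yielding a weight matrix usable by the graph-based
semi-supervised solver.

Four alternative measures are provided for comparison:

* ``gr1`` — Hadamard product of the two patient-patient correlation matrices;
* ``gr2`` — Gaussian k-NN graph on concatenated gene + miRNA profiles;
* ``gr3`` — gr2 restricted to features appearing in the target map;
* ``gr4`` — like the main measure but gene-centric, averaging over the
  miRNAs targeting each gene.

The main measure (miRNA-centric plain sum) is tagged ``gr5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .datasets import ExpressionDataset, check_same_patients, standardize_features
from .errors import ConfigurationError, DegenerateScoresError, EmptyTargetMapError
from .intra_graph import SimilarityGraph, build_knn_gaussian_graph
from .target_map import TargetMap

__all__ = [
    "InterRelationScores",
    "inter_scores_gr5",
    "inter_scores_gr4",
    "normalize_scores",
    "inter_graph_gr1",
    "inter_graph_gr2",
    "inter_graph_gr3",
    "build_inter_graph",
    "GR_METHODS",
]

GR_METHODS = ("GR1", "GR2", "GR3", "GR4", "GR5")


@dataclass(frozen=True)
class InterRelationScores:
    """Raw N x N cross-layer scores f_ij (row: miRNA patient, col: gene patient)."""

    raw: np.ndarray
    patient_ids: tuple[str, ...]
    method_tag: str

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        n = len(self.patient_ids)
        if raw.shape != (n, n):
            raise ConfigurationError(f"score matrix shape {raw.shape} != ({n}, {n})")
        if not np.all(np.isfinite(raw)):
            raise ConfigurationError("scores contain non-finite entries")


def _target_matrix(targets: TargetMap, n_mirnas: int, n_genes: int) -> sparse.csr_matrix:
    if len(targets) == 0:
        raise EmptyTargetMapError("target map has no pairs")
    idx = np.asarray(targets.index_pairs(), dtype=int)
    return sparse.csr_matrix(
        (np.ones(len(idx)), (idx[:, 0], idx[:, 1])), shape=(n_mirnas, n_genes)
    )


def inter_scores_gr5(
    mirna: ExpressionDataset,
    genes: ExpressionDataset,
    targets: TargetMap,
    standardize: bool = True,
) -> InterRelationScores:
    """miRNA-centric cross-patient sum over target pairs (the main measure).

    f_ij = sum_{(l,m) in targets} miRNA(i, l) * gene(j, m). Vectorized as
    M T G^T with T the sparse miRNA x gene pair-indicator matrix.
    """
    check_same_patients(mirna, genes)
    t = _target_matrix(targets, mirna.n_features, genes.n_features)
    m = standardize_features(mirna.values) if standardize else mirna.values
    g = standardize_features(genes.values) if standardize else genes.values
    raw = (m @ t) @ g.T
    return InterRelationScores(np.asarray(raw), mirna.patient_ids, "GR5")


def inter_scores_gr4(
    mirna: ExpressionDataset,
    genes: ExpressionDataset,
    targets: TargetMap,
    standardize: bool = True,
) -> InterRelationScores:
    """Gene-centric variant: average the miRNAs targeting each gene.

    f_ij = sum_m gene(j, m) * mean_{l : (l,m) in targets} miRNA(i, l);
    genes with no targeting miRNA contribute nothing.
    """
    check_same_patients(mirna, genes)
    t = _target_matrix(targets, mirna.n_features, genes.n_features)
    counts = np.asarray(t.sum(axis=0)).ravel()
    scale = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    t_mean = t.multiply(scale[np.newaxis, :]).tocsr()
    m = standardize_features(mirna.values) if standardize else mirna.values
    g = standardize_features(genes.values) if standardize else genes.values
    raw = (m @ t_mean) @ g.T
    return InterRelationScores(np.asarray(raw), mirna.patient_ids, "GR4")


def normalize_scores(
    scores: InterRelationScores, orientation: str = "positive"
) -> SimilarityGraph:
    """z-normalize over all N^2 entries, logistic-transform, symmetrize.

    Z_ij = (f_ij - mean(f)) / std(f) with the population standard deviation
    over the whole matrix; w_ij = 1 / (1 + exp(-Z_ij)), strictly in (0, 1).
    The asymmetric w is averaged with its transpose and the diagonal zeroed
    so the result satisfies the similarity-graph invariants.

    ``orientation`` fixes which tail of the score distribution counts as
    similar. ``"positive"`` is the plain logistic above. ``"repression"``
    uses 1 / (1 + exp(+Z)): when every target pair encodes repression, a
    patient pair sharing the same regulatory state drives the cross-layer
    sum strongly *negative* (miRNA up times target down), so coherence
    lives in the lower tail and the logistic must be mirrored for the
    weights to mean similarity.
    """
    if orientation not in ("positive", "repression"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    f = scores.raw
    sd = float(f.std())
    if sd == 0.0:
        raise DegenerateScoresError(
            f"constant {scores.method_tag} scores: the target map carries no "
            "patient-discriminating information"
        )
    z = (f - f.mean()) / sd
    if orientation == "repression":
        z = -z
    w = 1.0 / (1.0 + np.exp(-z))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return SimilarityGraph(w, scores.patient_ids)


def inter_graph_gr1(mirna: ExpressionDataset, genes: ExpressionDataset) -> SimilarityGraph:
    """Hadamard product of the two patient-patient Pearson correlation matrices."""
    check_same_patients(mirna, genes)
    for data, name in ((mirna, "miRNA"), (genes, "gene")):
        sd = data.values.std(axis=1)
        if np.any(sd == 0):
            bad = data.patient_ids[int(np.argmax(sd == 0))]
            raise ConfigurationError(
                f"patient {bad!r} has a constant {name} profile; correlation undefined"
            )
    product = np.corrcoef(mirna.values) * np.corrcoef(genes.values)
    return normalize_scores(InterRelationScores(product, mirna.patient_ids, "GR1"))


def inter_graph_gr2(
    mirna: ExpressionDataset,
    genes: ExpressionDataset,
    k: int = 5,
    sigma: float | None = None,
) -> SimilarityGraph:
    """Gaussian k-NN graph on concatenated standardized gene + miRNA profiles."""
    check_same_patients(mirna, genes)
    combined = ExpressionDataset(
        np.hstack([standardize_features(genes.values), standardize_features(mirna.values)]),
        genes.patient_ids,
        tuple(f"g:{f}" for f in genes.feature_ids) + tuple(f"m:{f}" for f in mirna.feature_ids),
    )
    return build_knn_gaussian_graph(combined, k=k, sigma=sigma, standardize=False)


def inter_graph_gr3(
    mirna: ExpressionDataset,
    genes: ExpressionDataset,
    targets: TargetMap,
    k: int = 5,
    sigma: float | None = None,
) -> SimilarityGraph:
    """As gr2, restricted to miRNAs and genes that occur in the target map."""
    mirna_kept = [f for f in mirna.feature_ids if f in targets.mirna_ids]
    gene_kept = [f for f in genes.feature_ids if f in targets.gene_ids]
    if not mirna_kept or not gene_kept:
        raise EmptyTargetMapError("no measured features participate in the target map")
    return inter_graph_gr2(
        mirna.subset_features(mirna_kept), genes.subset_features(gene_kept), k=k, sigma=sigma
    )


def build_inter_graph(
    method: str,
    mirna: ExpressionDataset,
    genes: ExpressionDataset,
    targets: TargetMap | None,
    k: int = 5,
    sigma: float | None = None,
    orientation: str = "repression",
) -> SimilarityGraph:
    """Dispatch on the measure tag GR1..GR5 (GR5 is the main measure).

    ``orientation`` applies to the target-pair sum measures (GR4, GR5) only;
    the default treats the target map as repressive regulation, so strongly
    negative cross-layer sums mark similar patients (see
    :func:`normalize_scores`).
    """
    method = method.upper()
    if method == "GR1":
        return inter_graph_gr1(mirna, genes)
    if method == "GR2":
        return inter_graph_gr2(mirna, genes, k=k, sigma=sigma)
    if method == "GR3":
        if targets is None:
            raise ConfigurationError("GR3 requires a target map")
        return inter_graph_gr3(mirna, genes, targets, k=k, sigma=sigma)
    if method == "GR4":
        if targets is None:
            raise ConfigurationError("GR4 requires a target map")
        return normalize_scores(inter_scores_gr4(mirna, genes, targets), orientation)
    if method == "GR5":
        if targets is None:
            raise ConfigurationError("GR5 requires a target map")
        return normalize_scores(inter_scores_gr5(mirna, genes, targets), orientation)
    raise ConfigurationError(f"unknown inter-relation method {method!r}")
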