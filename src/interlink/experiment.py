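"""Evaluation protocol: feature selection, cross-validated AUC, edge-damage runs.

The central experiment asks whether a patient graph reconstructed from
miRNA -> target-gene inter-relations can compensate for missing similarity
information. Four graphs are compared:

* ``GO`` — original Gaussian k-NN graph on t-test-selected gene features;
* ``GD`` — GO with a random fraction of its undirected edges removed;
* ``GR`` — graph reconstructed from the cross-layer inter-relation measure;
* ``GA`` — augmented graph fusing GD and GR with optimized Laplacian
  combination coefficients.

Per repeat, patients are split into stratified folds; training patients keep
their labels, test patients are unlabeled, feature selection and the
combination coefficients are fitted on training labels only, and the test
patients' real-valued scores are summarized as ROC AUC. Damaged and
augmented graphs are paired per fold, so a Wilcoxon signed-rank test can
compare them at each damage fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .datasets import ExpressionDataset, LabelVector, check_same_patients
from .errors import ConfigurationError, EmptyTargetMapError, UndefinedAUCError
from .inter_graph import GR_METHODS, build_inter_graph
from .intra_graph import build_knn_gaussian_graph, damage_graph, laplacian
from .ssl_core import combine_graphs, ssl_solve, ssl_solve_combined
from .synthetic_data import SyntheticCohort
from .target_map import filter_by_votes

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "GRComparison",
    "ttest_select",
    "compute_auc",
    "wilcoxon_compare",
    "run_fold",
    "run_damage_experiment",
    "auc_diff",
    "compare_gr_methods",
]

DEFAULT_DAMAGE_FRACTIONS = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of the evaluation protocol.

    ``sigma=None`` selects the median-heuristic bandwidth per graph.
    ``n_select_genes`` / ``n_select_mirnas`` are the per-fold t-test
    signature sizes for the intra-relation graphs. ``mu_smooth`` is the
    loss-vs-smoothness trade-off of the single-graph solver; ``mu_budget``
    bounds the total mass of the graph-combination coefficients.
    """

    damage_fractions: tuple[float, ...] = DEFAULT_DAMAGE_FRACTIONS
    n_repeats: int = 3
    n_folds: int = 5
    k_nn: int = 5
    sigma: float | None = None
    mu_smooth: float = 1.0
    mu_budget: float = 1.0
    n_select_genes: int = 11
    n_select_mirnas: int = 19
    min_votes: int = 1
    seed: int = 0
    gr_method: str = "GR5"
    gr_orientation: str = "repression"
    equal_var_ttest: bool = False
    select_features_for_intra: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "damage_fractions", tuple(float(f) for f in self.damage_fractions))
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if any(not 0.0 <= f <= 1.0 for f in self.damage_fractions):
            raise ConfigurationError("damage_fractions must lie in [0, 1]")
        if self.gr_method.upper() not in GR_METHODS:
            raise ConfigurationError(f"gr_method must be one of {GR_METHODS}")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-(kind, fraction, repeat, fold) AUC records and paired-test summaries."""

    records: pd.DataFrame
    summaries: pd.DataFrame
    wilcoxon: pd.DataFrame
    config: ExperimentConfig


@dataclass(frozen=True)
class GRComparison:
    """Mean AUCs of each inter-relation measure alone and fused with GO."""

    methods: pd.DataFrame
    auc_go: float
    auc_mirna: float


# ---------------------------------------------------------------------------
# feature selection


def _t_statistics(values: np.ndarray, y: np.ndarray, equal_var: bool) -> np.ndarray:
    pos = values[y == 1]
    neg = values[y == -1]
    n1, n2 = pos.shape[0], neg.shape[0]
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each class needs at least 2 labeled patients for the t-test")
    m1, m2 = pos.mean(axis=0), neg.mean(axis=0)
    v1, v2 = pos.var(axis=0, ddof=1), neg.var(axis=0, ddof=1)
    if equal_var:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom_sq = pooled * (1 / n1 + 1 / n2)
    else:
        denom_sq = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom_sq)
    # zero-variance features: infinite evidence if the means differ, none if equal
    zero = denom_sq == 0
    t[zero & (diff != 0)] = np.inf * np.sign(diff[zero & (diff != 0)])
    t[zero & (diff == 0)] = 0.0
    return t


def ttest_select(
    data: ExpressionDataset,
    labels: LabelVector,
    n_select: int,
    equal_var: bool = False,
) -> ExpressionDataset:
    """Keep the ``n_select`` features with largest |t| between the labeled classes.

    Welch's unequal-variance statistic by default (``equal_var=True`` for
    the pooled-variance form). Only labeled patients enter the statistic.
    Ties and the final feature order follow the original feature order.
    """
    check_same_patients(data, labels)
    if not 1 <= n_select <= data.n_features:
        raise ConfigurationError(f"n_select={n_select} outside [1, {data.n_features}]")
    mask = labels.labeled_mask
    t = _t_statistics(data.values[mask], labels.values[mask], equal_var)
    order = np.argsort(-np.abs(t), kind="stable")  # stable: ties keep feature order
    chosen = np.sort(order[:n_select])
    return ExpressionDataset(
        data.values[:, chosen],
        data.patient_ids,
        tuple(data.feature_ids[i] for i in chosen),
    )


# ---------------------------------------------------------------------------
# metrics


def compute_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC of real-valued scores against +1/-1 truth.

    Equals the Mann-Whitney U statistic normalized by n+ * n-, with tied
    scores counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ConfigurationError("scores and truth lengths differ")
    if not np.isin(truth, (-1, 1)).all():
        raise ConfigurationError("truth labels must be +1 or -1")
    n_pos = int(np.sum(truth == 1))
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined with a single class in the truth labels")
    ranks = rankdata(scores)
    r_pos = ranks[truth == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def wilcoxon_compare(aucs_a, aucs_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired AUC vectors.

    Zero differences are discarded; the statistic is min(W+, W-). For
    n <= 25 the p-value is exact over the 2^n equiprobable sign assignments
    (average ranks for tied |differences|); larger n uses the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired AUC vectors must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ConfigurationError("all paired differences are zero; test degenerate")
    if n < 5:
        raise ConfigurationError(f"only {n} nonzero differences; need >= 5")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    if n <= 25:
        # exact null distribution of 2*W+ (doubling makes average ranks integer)
        r2 = np.rint(2 * ranks).astype(int)
        counts = np.zeros(r2.sum() + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r] if r > 0 else counts
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        p_low = counts[: w2 + 1].sum()
        p_high = counts[w2:].sum()
        p = min(1.0, 2 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
        z = (stat - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2 * norm.cdf(z))
    return stat, float(p)


# ---------------------------------------------------------------------------
# cross-validated damage / augmentation protocol


def _as_parts(cohort: SyntheticCohort):
    return cohort.gene_expr, cohort.mirna_expr, cohort.targets, cohort.labels


def _derived_seed(root: int, *path: int) -> int:
    """Deterministic child seed below 2^31 from a root seed and an index path."""
    ss = np.random.SeedSequence([int(root), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_fold(
    cohort: SyntheticCohort,
    train_mask: np.ndarray,
    config: ExperimentConfig,
    fold_seed: int = 0,
) -> dict[str, np.ndarray]:
    """Score every patient with each graph kind for one train/test split.

    Returns raw SSL score vectors keyed ``"GO"``, ``"GR"`` and
    ``"GD@<fraction>"`` / ``"GA@<fraction>"`` per configured damage
    fraction. Labels of patients outside ``train_mask`` are zeroed before
    any fitting (feature selection, combination coefficients), so the
    returned scores never see test labels.
    """
    genes, mirna, targets, labels = _as_parts(cohort)
    train_mask = np.asarray(train_mask, dtype=bool)
    y_train = labels.masked(train_mask)

    usable = filter_by_votes(targets, config.min_votes)
    if len(usable) == 0:
        raise EmptyTargetMapError(f"no target pairs with votes >= {config.min_votes}")

    if config.select_features_for_intra:
        gene_view = ttest_select(genes, y_train, min(config.n_select_genes, genes.n_features),
                                 equal_var=config.equal_var_ttest)
    else:
        gene_view = genes
    g_o = build_knn_gaussian_graph(gene_view, k=config.k_nn, sigma=config.sigma)
    l_o = laplacian(g_o)
    g_r = build_inter_graph(config.gr_method, mirna, genes, usable,
                            k=config.k_nn, sigma=config.sigma,
                            orientation=config.gr_orientation)
    l_r = laplacian(g_r)

    scores: dict[str, np.ndarray] = {
        "GO": ssl_solve(l_o, y_train, config.mu_smooth).scores,
        "GR": ssl_solve(l_r, y_train, config.mu_smooth).scores,
    }
    for i, fraction in enumerate(config.damage_fractions):
        g_d = damage_graph(g_o, fraction, _derived_seed(fold_seed, i))
        l_d = laplacian(g_d)
        scores[f"GD@{fraction:g}"] = ssl_solve(l_d, y_train, config.mu_smooth).scores
        comb = combine_graphs([l_d, l_r], y_train, budget=config.mu_budget)
        scores[f"GA@{fraction:g}"] = ssl_solve_combined(comb, y_train).scores
    return scores


def _stratified_splits(labels: LabelVector, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    dummy = np.zeros(labels.n_patients)
    return skf.split(dummy, labels.values)


def run_damage_experiment(cohort: SyntheticCohort, config: ExperimentConfig) -> ExperimentResult:
    """Repeated stratified CV over all graph kinds and damage fractions.

    All randomness (fold shuffles, edge damage) derives from ``config.seed``
    through per-(repeat, fold) seed paths, so identical configurations give
    identical results.
    """
    labels = cohort.labels
    if not labels.labeled_mask.all():
        raise ConfigurationError("the damage experiment needs fully labeled patients")

    rows = []
    for repeat in range(config.n_repeats):
        split_seed = _derived_seed(config.seed, 0, repeat)
        for fold, (train_idx, test_idx) in enumerate(
            _stratified_splits(labels, config.n_folds, split_seed)
        ):
            train_mask = np.zeros(labels.n_patients, dtype=bool)
            train_mask[train_idx] = True
            fold_seed = _derived_seed(config.seed, 1, repeat, fold)
            scores = run_fold(cohort, train_mask, config, fold_seed)
            truth = labels.values[test_idx]
            for fraction in config.damage_fractions:
                tag = f"{fraction:g}"
                for kind, key in (
                    ("GO", "GO"),
                    ("GR", "GR"),
                    ("GD", f"GD@{tag}"),
                    ("GA", f"GA@{tag}"),
                ):
                    rows.append(
                        {
                            "graph_kind": kind,
                            "damage_fraction": fraction,
                            "repeat": repeat,
                            "fold": fold,
                            "auc": compute_auc(scores[key][test_idx], truth),
                        }
                    )

    records = pd.DataFrame(rows)
    summaries = (
        records.groupby(["graph_kind", "damage_fraction"])["auc"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "auc_mean", "std": "auc_sd"})
    )

    wilcoxon_rows = []
    for fraction in config.damage_fractions:
        sub = records[records["damage_fraction"] == fraction]
        gd = sub[sub["graph_kind"] == "GD"].sort_values(["repeat", "fold"])["auc"].to_numpy()
        ga = sub[sub["graph_kind"] == "GA"].sort_values(["repeat", "fold"])["auc"].to_numpy()
        try:
            stat, p = wilcoxon_compare(gd, ga)
        except ConfigurationError:
            stat, p = np.nan, np.nan
        wilcoxon_rows.append(
            {
                "damage_fraction": fraction,
                "auc_gd": gd.mean(),
                "auc_ga": ga.mean(),
                "statistic": stat,
                "p_value": p,
            }
        )
    return ExperimentResult(records, summaries, pd.DataFrame(wilcoxon_rows), config)


# ---------------------------------------------------------------------------
# per-feature importance and measure comparison


def _cv_intra_auc(
    genes: ExpressionDataset,
    labels: LabelVector,
    config: ExperimentConfig,
) -> float:
    """Mean CV AUC of the intra-relation graph built on the given features."""
    aucs = []
    for repeat in range(config.n_repeats):
        split_seed = _derived_seed(config.seed, 0, repeat)
        for train_idx, test_idx in _stratified_splits(labels, config.n_folds, split_seed):
            train_mask = np.zeros(labels.n_patients, dtype=bool)
            train_mask[train_idx] = True
            y_train = labels.masked(train_mask)
            g = build_knn_gaussian_graph(genes, k=config.k_nn, sigma=config.sigma)
            f = ssl_solve(laplacian(g), y_train, config.mu_smooth).scores
            aucs.append(compute_auc(f[test_idx], labels.values[test_idx]))
    return float(np.mean(aucs))


def auc_diff(
    cohort: SyntheticCohort,
    config: ExperimentConfig,
    selected_features: list[str],
) -> pd.DataFrame:
    """Leave-one-feature-out importance of each selected gene feature.

    AUC_diff(g) = AUC(selected set) - AUC(selected set without g), both under
    the same CV protocol and seeds; larger means removing g hurts more.
    Sorted descending, ties in original feature order.
    """
    if not selected_features:
        raise ConfigurationError("selected_features must be nonempty")
    base_data = cohort.gene_expr.subset_features(selected_features)
    base_auc = _cv_intra_auc(base_data, cohort.labels, config)
    rows = []
    for i, feature in enumerate(selected_features):
        rest = [f for f in selected_features if f != feature]
        if not rest:
            raise ConfigurationError("need at least two selected features")
        auc_without = _cv_intra_auc(
            cohort.gene_expr.subset_features(rest), cohort.labels, config
        )
        rows.append({"feature": feature, "auc_diff": base_auc - auc_without, "_order": i})
    out = pd.DataFrame(rows).sort_values(
        ["auc_diff", "_order"], ascending=[False, True], kind="stable"
    )
    out["auc_full"] = base_auc
    return out.drop(columns="_order").reset_index(drop=True)


def compare_gr_methods(cohort: SyntheticCohort, config: ExperimentConfig) -> GRComparison:
    """Mean CV AUC of every inter-relation measure, alone and fused with GO.

    All methods share the same seed-derived folds, so the GO baseline is
    identical across methods. The augmented graph here fuses the *undamaged*
    GO with each measure's GR. The miRNA-only intra-relation graph (t-test
    selected miRNA features) is reported as an additional baseline.
    """
    genes, mirna, targets, labels = _as_parts(cohort)
    usable = filter_by_votes(targets, config.min_votes)
    if len(usable) == 0:
        raise EmptyTargetMapError(f"no target pairs with votes >= {config.min_votes}")

    per_method: dict[str, dict[str, list[float]]] = {
        m: {"gr": [], "ga": []} for m in GR_METHODS
    }
    go_aucs: list[float] = []
    mirna_aucs: list[float] = []

    graphs = {
        m: build_inter_graph(m, mirna, genes, usable, k=config.k_nn, sigma=config.sigma,
                             orientation=config.gr_orientation)
        for m in GR_METHODS
    }
    for repeat in range(config.n_repeats):
        split_seed = _derived_seed(config.seed, 0, repeat)
        for train_idx, test_idx in _stratified_splits(labels, config.n_folds, split_seed):
            train_mask = np.zeros(labels.n_patients, dtype=bool)
            train_mask[train_idx] = True
            y_train = labels.masked(train_mask)
            truth = labels.values[test_idx]

            gene_view = ttest_select(
                genes, y_train, min(config.n_select_genes, genes.n_features),
                equal_var=config.equal_var_ttest,
            )
            l_o = laplacian(build_knn_gaussian_graph(gene_view, k=config.k_nn, sigma=config.sigma))
            go_aucs.append(
                compute_auc(ssl_solve(l_o, y_train, config.mu_smooth).scores[test_idx], truth)
            )

            mirna_view = ttest_select(
                mirna, y_train, min(config.n_select_mirnas, mirna.n_features),
                equal_var=config.equal_var_ttest,
            )
            l_m = laplacian(build_knn_gaussian_graph(mirna_view, k=config.k_nn, sigma=config.sigma))
            mirna_aucs.append(
                compute_auc(ssl_solve(l_m, y_train, config.mu_smooth).scores[test_idx], truth)
            )

            for method, g_r in graphs.items():
                l_r = laplacian(g_r)
                f_r = ssl_solve(l_r, y_train, config.mu_smooth).scores
                per_method[method]["gr"].append(compute_auc(f_r[test_idx], truth))
                comb = combine_graphs([l_o, l_r], y_train, budget=config.mu_budget)
                f_a = ssl_solve_combined(comb, y_train).scores
                per_method[method]["ga"].append(compute_auc(f_a[test_idx], truth))

    methods = pd.DataFrame(
        {
            "method": list(GR_METHODS),
            "auc_gr": [float(np.mean(per_method[m]["gr"])) for m in GR_METHODS],
            "auc_ga": [float(np.mean(per_method[m]["ga"])) for m in GR_METHODS],
        }
    )
    return GRComparison(methods, float(np.mean(go_aucs)), float(np.mean(mirna_aucs)))
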