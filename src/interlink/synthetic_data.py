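"""Synthetic coupled miRNA / gene-expression cohorts with planted structure.

The generator emulates a tumor cohort profiled on two layers: a miRNA
expression matrix and a gene expression matrix over the same patients, a
sparse miRNA -> target-gene map with per-pair vote counts, and a binary
clinical outcome (e.g. short- vs long-term survival, coded -1 / +1).

Class signal is planted through *informative* miRNA-target pairs: the miRNA
of such a pair is shifted upward in the +1 class, and its target gene is
generated as a negatively-scaled copy of the miRNA signal plus independent
noise — the repression-like anticorrelated pattern through which the
cross-layer similarity measure can recover patient similarity. All other
features are pure Gaussian noise. Default dimensions are desk-scale (82
patients with a 54/28 class split, 200 genes, 60 miRNAs, 120 target pairs
of which 15 are informative); full cohort-scale dimensions are a
configuration choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset, LabelVector
from .errors import ConfigurationError
from .target_map import MAX_VOTES, TargetMap, write_target_map

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the cohort generator.

    ``effect_size`` is the standardized mean shift of an informative miRNA
    between classes (in units of ``noise_sd``); ``repression_strength`` is
    the magnitude of the negative correlation between an informative miRNA
    and its target gene; ``class_balance`` is the fraction of patients in
    class +1.
    """

    n_patients: int = 82
    n_genes: int = 200
    n_mirnas: int = 60
    n_target_pairs: int = 120
    n_informative_pairs: int = 15
    effect_size: float = 1.5
    repression_strength: float = 0.8
    class_balance: float = 28 / 82
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_genes", "n_mirnas"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_informative_pairs < 0:
            raise ConfigurationError("n_informative_pairs must be >= 0")
        if self.n_informative_pairs > self.n_target_pairs:
            raise ConfigurationError("n_informative_pairs exceeds n_target_pairs")
        if self.n_target_pairs > self.n_genes * self.n_mirnas:
            raise ConfigurationError("n_target_pairs exceeds n_genes * n_mirnas")
        if self.n_informative_pairs > min(self.n_genes, self.n_mirnas):
            raise ConfigurationError(
                "n_informative_pairs exceeds min(n_genes, n_mirnas); informative "
                "pairs use distinct miRNAs and distinct genes"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must lie strictly in (0, 1)")
        if not 0.0 <= self.repression_strength <= 1.0:
            raise ConfigurationError("repression_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth of what was planted."""

    gene_expr: ExpressionDataset
    mirna_expr: ExpressionDataset
    targets: TargetMap
    labels: LabelVector
    truth: dict = field(default_factory=dict)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort; identical config (including seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n, ng, nm = config.n_patients, config.n_genes, config.n_mirnas

    patient_ids = tuple(f"P{i:04d}" for i in range(n))
    gene_ids = tuple(f"gene{j:05d}" for j in range(ng))
    mirna_ids = tuple(f"miR{j:04d}" for j in range(nm))

    # class assignment: fixed counts, shuffled over patients
    n_pos = int(round(config.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.full(n, -1, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1

    # informative pairs use distinct miRNAs and distinct genes so each
    # planted repression acts on its own target
    info_mirnas = rng.permutation(nm)[: config.n_informative_pairs]
    info_genes = rng.permutation(ng)[: config.n_informative_pairs]
    info_pairs = set(zip(info_mirnas.tolist(), info_genes.tolist()))

    # remaining target pairs sampled without replacement from the full grid
    n_rest = config.n_target_pairs - len(info_pairs)
    pairs = list(info_pairs)
    if n_rest > 0:
        taken = set(info_pairs)
        flat = rng.permutation(nm * ng)
        for code in flat:
            cand = (int(code) // ng, int(code) % ng)
            if cand not in taken:
                taken.add(cand)
                pairs.append(cand)
                if len(pairs) == config.n_target_pairs:
                    break

    mirna_values = rng.normal(0.0, config.noise_sd, size=(n, nm))
    shift = config.effect_size * config.noise_sd
    mirna_values[:, info_mirnas] += shift * (labels == 1)[:, np.newaxis]

    gene_values = rng.normal(0.0, config.noise_sd, size=(n, ng))
    rho = config.repression_strength
    resid = np.sqrt(max(0.0, 1.0 - rho**2))
    for lm, gm in zip(info_mirnas, info_genes):
        gene_values[:, gm] = -rho * mirna_values[:, lm] + resid * config.noise_sd * rng.normal(
            0.0, 1.0, size=n
        )

    votes = rng.integers(1, MAX_VOTES + 1, size=len(pairs))
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    target_rows = tuple(
        (mirna_ids[lm], gene_ids[gm], int(v)) for (lm, gm), v in zip(pairs, votes)
    )
    targets = TargetMap(target_rows, mirna_index, gene_index)

    truth = {
        "informative_mirnas": [mirna_ids[i] for i in info_mirnas],
        "informative_genes": [gene_ids[i] for i in info_genes],
        "informative_pairs": [
            (mirna_ids[lm], gene_ids[gm]) for lm, gm in zip(info_mirnas, info_genes)
        ],
    }
    return SyntheticCohort(
        gene_expr=ExpressionDataset(gene_values, patient_ids, gene_ids),
        mirna_expr=ExpressionDataset(mirna_values, patient_ids, mirna_ids),
        targets=targets,
        labels=LabelVector(labels, patient_ids),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write gene_expr.tsv, mirna_expr.tsv, targets.tsv, labels.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_expr": directory / "gene_expr.tsv",
        "mirna_expr": directory / "mirna_expr.tsv",
        "targets": directory / "targets.tsv",
        "labels": directory / "labels.tsv",
    }
    cohort.gene_expr.write_tsv(paths["gene_expr"])
    cohort.mirna_expr.write_tsv(paths["mirna_expr"])
    write_target_map(cohort.targets, paths["targets"])
    cohort.labels.write_tsv(paths["labels"])
    return paths
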