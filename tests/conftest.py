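import numpy as np
import pytest

from interlink.datasets import ExpressionDataset, LabelVector
from interlink.synthetic_data import SyntheticConfig, generate_cohort
from interlink.target_map import TargetMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort():
    """Desk-scale cohort with planted signal, shared across modules."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture
def tiny_pair_data(rng):
    """4 patients, 3 miRNAs, 5 genes, 4 target pairs; for oracle checks."""
    patients = tuple(f"P{i}" for i in range(4))
    mirna = ExpressionDataset(rng.normal(size=(4, 3)), patients, ("m0", "m1", "m2"))
    genes = ExpressionDataset(rng.normal(size=(4, 5)), patients, tuple(f"g{j}" for j in range(5)))
    pairs = (("m0", "g1", 3), ("m1", "g0", 5), ("m1", "g4", 7), ("m2", "g2", 11))
    targets = TargetMap(
        pairs,
        {f: i for i, f in enumerate(mirna.feature_ids)},
        {f: i for i, f in enumerate(genes.feature_ids)},
    )
    return mirna, genes, targets


def random_expression(rng, n_patients, n_features, prefix="f"):
    return ExpressionDataset(
        rng.normal(size=(n_patients, n_features)),
        tuple(f"P{i}" for i in range(n_patients)),
        tuple(f"{prefix}{j}" for j in range(n_features)),
    )


def labels_from_array(values):
    return LabelVector(np.asarray(values), tuple(f"P{i}" for i in range(len(values))))
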