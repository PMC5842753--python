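import numpy as np
import pytest

from epiconnect.cohort import NetworkTemplate, make_template, simulate_subject
from epiconnect.features import FeatureTable
from epiconnect.forest import BalancedForestSpec


@pytest.fixture(scope="session")
def small_spec() -> BalancedForestSpec:
    """A forest small enough for unit tests but large enough for stable votes."""
    return BalancedForestSpec(n_trees=120)


@pytest.fixture(scope="session")
def control_template() -> NetworkTemplate:
    return make_template("CONTROL", seed=0)


@pytest.fixture(scope="session")
def three_node_model():
    """A known stable 3-node order-2 MVAR system used as a PDC ground truth."""
    coeffs = np.zeros((2, 3, 3))
    coeffs[0] = [[0.55, 0.0, 0.0], [0.35, 0.5, 0.0], [0.0, 0.3, 0.45]]
    coeffs[1] = [[-0.2, 0.0, 0.0], [0.0, -0.15, 0.0], [0.1, 0.0, -0.1]]
    noise_cov = np.eye(3)
    return coeffs, noise_cov


@pytest.fixture(scope="session")
def two_pair_template() -> NetworkTemplate:
    """Minimal 2-ROI template (one left/right pair) built by hand."""
    coeffs = np.array([[[0.5, 0.0], [0.4, 0.5]]])
    return NetworkTemplate(
        group_label="CONTROL",
        roi_names=("Hipp-L", "Hipp-R"),
        order=1,
        coeffs=coeffs,
        noise_cov=np.eye(2),
    )


def make_noise_table(n_subjects: int, n_features: int, seed: int,
                     labels=None) -> FeatureTable:
    rng = np.random.default_rng(seed)
    if labels is None:
        half = n_subjects // 2
        labels = ["A"] * half + ["B"] * (n_subjects - half)
    return FeatureTable(
        subject_ids=[f"s{i:03d}" for i in range(n_subjects)],
        feature_names=[f"f{j:03d}" for j in range(n_features)],
        values=rng.standard_normal((n_subjects, n_features)),
        labels=list(labels),
    )


def make_xor_table(n_subjects: int = 40, n_noise: int = 3, seed: int = 7) -> FeatureTable:
    """Two features individually useless but jointly decisive, plus noise."""
    rng = np.random.default_rng(seed)
    a = rng.random(n_subjects) < 0.5
    b = rng.random(n_subjects) < 0.5
    labels = np.where(a ^ b, "A", "B").tolist()
    values = np.column_stack([
        a + 0.05 * rng.standard_normal(n_subjects),
        b + 0.05 * rng.standard_normal(n_subjects),
        rng.standard_normal((n_subjects, n_noise)),
    ])
    names = ["xor_a", "xor_b"] + [f"noise{j}" for j in range(n_noise)]
    return FeatureTable(
        subject_ids=[f"s{i:03d}" for i in range(n_subjects)],
        feature_names=names, values=values, labels=labels,
    )
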