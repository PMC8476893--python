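import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gpsig import ExpressionMatrix, PhenotypeTable, RFConfig
from gpsig.pipeline import run_discover, run_validate
from gpsig.simulate import SimulationConfig, apply_batch_transforms, train_test_pair

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def recovery_world():
    """Reference world: 500 genes, 50 planted pairs at stability 0.95,
    40+40 samples per cohort, survival linked to true response."""
    config = SimulationConfig(seed=RECOVERY_SEED)
    train, test = train_test_pair(config)
    return config, train, test


@pytest.fixture(scope="session")
def discovered(recovery_world):
    """Full discovery on the reference training cohort with the published
    forest hyperparameters (ntree=2500, mtry=88)."""
    _, (train_expr, train_ph, _), _ = recovery_world
    return run_discover(
        train_expr, train_ph,
        rf_config=RFConfig(ntree=2500, mtry=88, seed=RECOVERY_SEED),
    )


@pytest.fixture(scope="session")
def validated(recovery_world, discovered):
    """The discovered signature applied to the held-out cohort after
    per-sample monotone distortion (batch surrogate)."""
    _, _, (test_expr, test_ph, _) = recovery_world
    distorted = apply_batch_transforms(test_expr, "mixed", seed=RECOVERY_SEED + 1)
    return run_validate(distorted, discovered.signature, test_ph,
                        survival=True, cox_covariates=("stage", "age", "gender"))


@pytest.fixture
def tiny_expr():
    """4 genes x 4 samples with hand-pickable orderings."""
    values = np.array([
        [5.0, 1.0, 3.0, 7.0],
        [3.0, 2.0, 4.0, 6.0],
        [1.0, 8.0, 2.0, 5.0],
        [2.0, 4.0, 9.0, 1.0],
    ])
    return ExpressionMatrix(("gA", "gB", "gC", "gD"), ("s1", "s2", "s3", "s4"), values)


def make_labeled_expr(k_resp, n_resp, k_nonresp, n_nonresp, seed=0):
    """Two-gene matrix where the pair (gA, gB) is FORWARD in exactly k_resp
    responders and k_nonresp non-responders, embedded in noise genes."""
    rng = np.random.default_rng(seed)
    n = n_resp + n_nonresp
    labels = np.array([1] * n_resp + [0] * n_nonresp)
    values = rng.normal(8.0, 1.0, size=(4, n))
    forward = np.concatenate([
        np.arange(n_resp) < k_resp, np.arange(n_nonresp) < k_nonresp
    ])
    a, b = values[0].copy(), values[1].copy()
    swap = forward != (a > b)
    values[0] = np.where(swap, b, a)
    values[1] = np.where(swap, a, b)
    expr = ExpressionMatrix(
        ("gA", "gB", "gC", "gD"),
        tuple(f"s{i}" for i in range(n)),
        values,
    )
    pheno = PhenotypeTable.from_records(expr.sample_ids, response=labels)
    return expr, pheno
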