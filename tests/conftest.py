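import warnings

import numpy as np
import pytest

import fsnorm as fn

# the heavy simulation artefacts are session-scoped and shared across tests


@pytest.fixture(scope="session")
def default_cohort():
    """The default stated world: strong platform distortion, 4 subtypes."""
    return fn.simulate_paired_cohort(fn.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    """Four-condition nested-CV records on the default cohort (SVM, no FS)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recs = fn.nested_cv_experiment(
            default_cohort, "A_trains", "svm_linear", "full", fn.CVConfig(seed=7)
        )
    return fn.records_to_frame(recs)


@pytest.fixture()
def small_cohort():
    """A fast two-class cohort for unit tests of the harness plumbing."""
    cfg = fn.SimulationConfig(
        n_samples=40,
        p_genes=60,
        k_classes=2,
        class_proportions=(0.6, 0.4),
        seed=42,
    )
    return fn.simulate_paired_cohort(cfg)


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(3)
    vals = rng.normal(5.0, 2.0, size=(6, 4))
    return fn.ExpressionMatrix(vals, [f"s{i}" for i in range(6)], [f"g{j}" for j in range(4)])
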