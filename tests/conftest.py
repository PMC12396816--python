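import numpy as np
import pytest

import shmconv as sc

# The parameter-recovery experiment: a K=1 convolutional model (context
# exactly one 3-mer) fit to 50,000 sites simulated from a seeded random
# 3-mer truth.  The fixed branch length 0.4 is a power choice: it yields
# roughly 200+ mutations per 3-mer context, putting the sampling-noise
# floor of the per-context CSP estimates below the recovery tolerances.
RECOVERY_TRUTH_SEED = 101
RECOVERY_DATA_SEED = 102
RECOVERY_MODEL_SEED = 103
RECOVERY_TRAIN_SEED = 104


@pytest.fixture(scope="session")
def recovery_experiment():
    truth = sc.random_true_model(3, seed=RECOVERY_TRUTH_SEED)
    data = sc.simulate_dataset(
        sc.SimConfig(
            n_pairs=250,
            length=200,
            branch_length_law=("fixed", 0.4),
            seed=RECOVERY_DATA_SEED,
        ),
        truth,
    )
    model = sc.build_model(
        sc.ConvConfig(kernel=1, embed=16, filters=64, dropout=0.0, wiring="joined"),
        seed=RECOVERY_MODEL_SEED,
    )
    sc.train(
        model,
        data,
        None,
        sc.TrainingConfig(
            epochs=100,
            learning_rate=0.01,
            csp_weight=0.01,
            batch_size=32,
            seed=RECOVERY_TRAIN_SEED,
        ),
    )
    probes = [sc.random_parent(500, s) for s in range(200, 206)]
    report = sc.parameter_recovery_report(truth, model, probes)
    return truth, model, report


@pytest.fixture()
def tiny_dataset():
    """A small simulated PCP dataset under the default branch-length law."""
    truth = sc.random_true_model(3, seed=11)
    return truth, sc.simulate_dataset(
        sc.SimConfig(n_pairs=12, length=120, seed=12), truth
    )


@pytest.fixture()
def small_model():
    return sc.build_model(
        sc.ConvConfig(kernel=5, embed=4, filters=6, dropout=0.2, wiring="hybrid"),
        seed=3,
    )
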