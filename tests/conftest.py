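import numpy as np
import pytest

from regdesign.ann import (
    TrainedModel,
    TrainingConfig,
    predict_strength,
    train_network,
)
from regdesign.encoding import BASE_ORDER, encode_library
from regdesign.model_selection import pearson_r, split_library
from regdesign.simulate import generate_library, make_ground_truth


@pytest.fixture(scope="session")
def tiny_library():
    """4 sequences of 8 nt with separable strengths, for fast training tests."""
    seqs = ["AAAAAAAA", "AAAATTTT", "TTTTAAAA", "TTTTTTTT"]
    strengths = np.array([0.0, 0.2, 0.8, 1.0])
    return seqs, strengths


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_library):
    seqs, strengths = tiny_library
    X = encode_library(seqs)
    # trained well past the default goal so per-point errors are small
    config = TrainingConfig(hidden_neurons=4, seed=7, sse_goal=0.01)
    return train_network(X, strengths, config)


def model_from_ground_truth(gt, eps: float = 1e-4) -> TrainedModel:
    """Build a network that implements a planted ground truth exactly.

    A single hidden unit operated in its linear regime turns the network
    into ``s_max * logsig(latent_score + offset)`` up to O(eps^2), i.e. the
    ground-truth map itself. This gives an oracle model whose per-site
    scan effects equal the planted relative effects.
    """
    L = len(gt.wt_seq)
    W1 = np.zeros((1, 4 * L))
    for (pos, base), effect in gt.site_effects.items():
        W1[0, 4 * (pos - 1) + BASE_ORDER.index(base)] = eps * effect
    b1 = np.zeros(1)
    W2 = np.array([[4.0 / eps]])
    b2 = np.array([gt.offset - 2.0 / eps])
    return TrainedModel(
        hidden_weights=W1, hidden_bias=b1, output_weights=W2, output_bias=b2,
        normalization_max=gt.s_max, config=TrainingConfig(hidden_neurons=1),
        training_log=[0.0],
    )


@pytest.fixture(scope="session")
def planted_model_factory():
    return model_from_ground_truth


@pytest.fixture(scope="session")
def paper_scale_run():
    """The scaled-down flagship experiment shared by several acceptance tests.

    Synthetic 100-member library (224 nt, planted ground truth, noise_sd
    0.05), 90/10 split, 19 hidden neurons, stated optimizer settings,
    best of 20 random restarts.
    """
    seed = 1
    gt = make_ground_truth(seed=seed * 1000 + 1)
    lib = generate_library(gt, n=100, mutation_rate=0.20, seed=seed * 1000 + 2)
    train_lib, test_lib = split_library(lib, 90, seed=seed * 1000 + 3)
    X_train = encode_library(train_lib.sequences())
    y_train = train_lib.strengths()
    models = []
    for r in range(20):
        config = TrainingConfig(hidden_neurons=19, seed=seed * 1000 + 100 + r)
        models.append(train_network(X_train, y_train, config))
    finals = np.array([m.final_sse for m in models])
    converged = [m for m in models if m.final_sse <= m.config.sse_goal]
    r_train = np.array(
        [pearson_r(predict_strength(m, X_train), y_train) for m in converged]
    )
    return {
        "ground_truth": gt,
        "library": lib,
        "train_lib": train_lib,
        "test_lib": test_lib,
        "X_train": X_train,
        "y_train": y_train,
        "models": models,
        "min_final_sse": float(finals.min()),
        "best_by_sse": models[int(np.argmin(finals))],
        "best_r_train": float(r_train.max()) if len(converged) else float("nan"),
        "best_by_r": converged[int(np.argmax(r_train))] if len(converged) else None,
    }
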