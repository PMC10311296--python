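"""Shared fixtures.

The two training experiments (masked-residue overfit, ΔΔG parameter
recovery) are session-scoped because they are the slow parts of the
suite; their results are shared between the unit tests and the
acceptance checks.
"""

import numpy as np
import pytest
from scipy import stats

from ppicube.nn import SsdlaModel, TrunkConfig, train_ddg, train_ssdla
from ppicube.regions import compute_accessibility
from ppicube.structure import build_channel_scheme
from ppicube.synthetic import (ToyComplexSpec, make_labeled_cubes,
                               make_synthetic_ddg, make_toy_complex)

try:  # derandomize property tests when hypothesis is present
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def element_scheme():
    return build_channel_scheme("element4")


@pytest.fixture(scope="session")
def full_scheme():
    return build_channel_scheme("full167")


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_accessibility(toy):
    return compute_accessibility(toy.structure)


@pytest.fixture(scope="session")
def labeled_cubes(element_scheme):
    return make_labeled_cubes(40, scheme=element_scheme, seed=0)


@pytest.fixture(scope="session")
def overfit(labeled_cubes):
    """Masked-residue model trained to convergence on 40 labeled cubes."""
    model = SsdlaModel(TrunkConfig.desk(4), seed=0)
    result = train_ssdla(
        labeled_cubes.cubes, labeled_cubes.labels, model,
        epochs=200, lr=1e-3, batch_size=40, seed=0,
        stop_at_train_accuracy=0.95,
    )
    probs = model.forward(labeled_cubes.cubes)
    accuracy = float((probs.argmax(axis=1) == labeled_cubes.labels).mean())
    return {"model": model, "result": result, "accuracy": accuracy,
            "epochs_run": len(result.loss_history)}


@pytest.fixture(scope="session")
def ddg_data():
    return make_synthetic_ddg(200, noise_sd=0.3, seed=0)


@pytest.fixture(scope="session")
def recovery(ddg_data):
    """Siamese model trained on 150 synthetic pairs, tested on 50 held out."""
    tr, te = slice(0, 150), slice(150, 200)
    model, result = train_ddg(
        ddg_data.wt_cubes[tr], ddg_data.mu_cubes[tr], ddg_data.aux[tr],
        ddg_data.targets[tr], config=TrunkConfig.desk(4),
        epochs=80, lr=1e-3, batch_size=32, seed=0)
    pred = model.forward(ddg_data.wt_cubes[te], ddg_data.mu_cubes[te],
                         ddg_data.aux[te])
    pcc = float(stats.pearsonr(pred, ddg_data.targets[te]).statistic)
    return {"model": model, "result": result, "heldout_pcc": pcc,
            "n_test": 50}
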