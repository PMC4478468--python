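import numpy as np
import pytest

from ompscan.alignment import AlignedEntry, AlignmentParams
from ompscan.omp_id import OMPLibrary, search
from ompscan.predictors import TrainingConfig, train_bundle
from ompscan.synthetic import generate_benchmark, generate_families

# One small but real training run shared by the predictor, pipeline and
# benchmark tests.  Sizes keep the whole suite fast while leaving the
# learning problem honest (held-out families from the same generator).
SMALL_CONFIG = TrainingConfig(
    seed=5,
    hidden={"SS": (20, 10), "RD": (14,), "Phi": (14,), "RSA": (14,)},
    stage2_hidden={"SS": (10,), "RD": (6,), "RSA": (6,)},
    epochs_stage1=25,
    epochs_stage2=15,
)


@pytest.fixture(scope="session")
def train_families():
    return generate_families(101, 16, length=60)


@pytest.fixture(scope="session")
def heldout_families():
    return generate_families(202, 6, length=60)


@pytest.fixture(scope="session")
def trained_bundle(train_families):
    return train_bundle(train_families, SMALL_CONFIG)


def _to_entry(bundle, item):
    entry_id, profile, _truth = item
    features, ss_ri = bundle.predict_all(profile)
    return AlignedEntry(id=entry_id, profile=profile, features=features,
                        ss_ri=ss_ri)


@pytest.fixture(scope="session")
def benchmark_scores(trained_bundle):
    """Best-hit scores for every benchmark query under the full scoring
    function and the property-ablated control, with labels."""
    library, positives, decoys = generate_benchmark(
        seed=77, n_omp_families=8, n_decoys=24, length=60,
    )
    lib = OMPLibrary(
        entries=[_to_entry(trained_bundle, x) for x in library]
    )
    queries = [(_to_entry(trained_bundle, x), 1) for x in positives]
    queries += [(_to_entry(trained_bundle, x), 0) for x in decoys]
    out = {"labels": np.array([lab for _, lab in queries])}
    for name, params in (("full", AlignmentParams()),
                         ("control", AlignmentParams().control())):
        out[name] = np.array(
            [search(e, lib, params)[0][1] for e, _ in queries]
        )
    return out
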