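import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neoclust.affinity_dai import points_to_array
from neoclust.io import affinity_pairs_from_frame
from neoclust import affinity_dai, mixture_model, synthetic_data


@pytest.fixture(scope="session")
def fabf_landscape():
    """One deterministic draw of the default synthetic affinity landscape."""
    return synthetic_data.gen_landscape(synthetic_data.fabf_like_spec(seed=7))


@pytest.fixture(scope="session")
def fitted_pipeline(fabf_landscape):
    """Scaling + BIC-selected mixture fit on the default landscape.

    Session-scoped: several test modules inspect the same fit.
    """
    t = fabf_landscape
    pairs = affinity_pairs_from_frame(t)
    params = affinity_dai.fit_scaling(pairs)
    labels = dict(zip(t["snv_id"], t["label"]))
    points = affinity_dai.apply_scaling(params, pairs, labels=labels)
    X = points_to_array(points)
    best, table = mixture_model.select_model(X, seed=7, n_restarts=10)
    return {
        "table": t,
        "pairs": pairs,
        "scaling": params,
        "labels": labels,
        "points": points,
        "X": X,
        "fit": best,
        "bic_table": table,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
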