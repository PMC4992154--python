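import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from islex.preprocess import FINAL_MODEL_SPEC, build_design
from islex.gee import fit_gee
from islex.simulate import make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_ds():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def paper_like_ds():
    return make_fixture("paper_like")


@pytest.fixture(scope="session")
def paper_like_design(paper_like_ds):
    return build_design(paper_like_ds, FINAL_MODEL_SPEC)


@pytest.fixture(scope="session")
def paper_like_fit(paper_like_design):
    return fit_gee(paper_like_design, warn=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def singleton_design(n=300, seed=0, beta=(-1.0, 0.8)):
    """A simple one-covariate dataset with every row its own cluster."""
    from islex.preprocess import DesignMatrix, ModelSpec

    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    eta = beta[0] + beta[1] * X[:, 1]
    p = 1 - np.exp(-np.exp(eta))
    y = (rng.random(n) < p).astype(int)
    return DesignMatrix(
        y=y,
        X=pd.DataFrame(X, columns=["intercept", "x"]),
        cluster_index=np.arange(n),
        term_map={"intercept": "intercept", "x": "x"},
        spec=ModelSpec(("x",)),
    )
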