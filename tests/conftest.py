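import numpy as np
import pandas as pd
import pytest

from yeastclim import glm, synthetic
from yeastclim.raster import RasterGrid


@pytest.fixture(scope="session")
def default_survey():
    """One default-condition survey: 126 trees, 13 sites, 22 missing girths."""
    return synthetic.simulate_survey(synthetic.SurveyParams(seed=11))


@pytest.fixture(scope="session")
def final_model_spec():
    return glm.ModelSpec.from_formula(
        "n_sp_positive/n_samples ~ girth_m * region + tmax_c * region")


@pytest.fixture(scope="session")
def fitted_final_model(default_survey, final_model_spec):
    frame = default_survey.dropna(subset=["girth_m"])
    return glm.BinomialGLM(spec=final_model_spec).fit(frame)


@pytest.fixture()
def small_grid():
    """5x6 grid over the equator, cell 0.5 deg, values 20.0..34.5 C in rows."""
    vals = (200 + 10 * np.arange(30).reshape(5, 6)).astype(float) / 2 + 100
    return RasterGrid(values=vals, lat_nw=2.5, lon_nw=0.0, cell_size=0.5)


def random_small_glm_dataset(rng, n_obs=10):
    """Small one-covariate binomial dataset, guarded against separation."""
    while True:
        x = rng.normal(size=n_obs)
        n = rng.integers(4, 9, size=n_obs)
        beta = rng.uniform(-1.0, 1.0, size=2)
        p = 1 / (1 + np.exp(-(beta[0] + beta[1] * x)))
        y = rng.binomial(n, p)
        # both outcome classes present overall and not perfectly aligned
        if 0 < y.sum() < n.sum():
            return pd.DataFrame(
                {"x": x, "n_samples": n, "n_sp_positive": y})
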