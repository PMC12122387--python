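import numpy as np
import pandas as pd
import pytest

from mfdiv import morphospace, preprocess, simulate


@pytest.fixture(scope="session")
def small_config():
    """Fast survey: study site layout but 12 fish per site."""
    return simulate.SimConfig(n_per_site=12, seed=7)


@pytest.fixture(scope="session")
def survey(small_config):
    specimens, metadata, truth = simulate.generate_specimens(small_config)
    return {"specimens": specimens, "metadata": metadata, "truth": truth}


@pytest.fixture(scope="session")
def corrected(survey):
    fits = preprocess.fit_all_allometries(survey["specimens"])
    return preprocess.size_correct(survey["specimens"], fits)


@pytest.fixture(scope="session")
def pca(corrected):
    return morphospace.run_pca(corrected)


@pytest.fixture(scope="session")
def centroids(pca):
    return morphospace.site_centroids(pca)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_centroids(points: dict, axes=("PC1", "PC2")) -> pd.DataFrame:
    """Centroid table from a dict site -> coordinate tuple."""
    df = pd.DataFrame.from_dict(points, orient="index", columns=list(axes))
    df.index.name = "site"
    df["n"] = 1
    return df
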