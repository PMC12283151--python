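import numpy as np
import pandas as pd
import pytest

import songcorpus as sc


@pytest.fixture
def tiny_metadata(tmp_path):
    """3-song metadata CSV with valid vocabulary tokens."""
    path = tmp_path / "meta.csv"
    pd.DataFrame({
        "song": ["s1", "s2", "s3"],
        "region": ["Polynesia", "Scandinavia", "Western Africa"],
        "glottocode": ["abcd1234", "efgh5678", "ijkl9012"],
        "type": ["dance", "lullaby", "healing"],
        "note": ["x", "y", "z"],  # extra column, must be preserved
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def tiny_corpus(tiny_metadata):
    return sc.load_metadata(tiny_metadata)


@pytest.fixture
def tiny_features(tmp_path, tiny_corpus):
    path = tmp_path / "feat.csv"
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.standard_normal((3, 38)),
                      columns=[f"f{i:02d}" for i in range(38)])
    df.insert(0, "song", ["s1", "s2", "s3"])
    df.to_csv(path, index=False)
    return sc.load_feature_table(path, tiny_corpus)


@pytest.fixture(scope="session")
def balanced_synth():
    """Small corpus with a strong planted context effect (4 contexts)."""
    return sc.simulate_corpus(sc.SynthConfig(
        n_languages=10, songs_per_language=8, n_contexts=4, n_features=6,
        sigma2_behavior=2.0, sigma2_culture=0.2, sigma2_phylo=0.0,
        sigma2_geo=0.0, sigma2_resid=0.3, seed=11,
    ))


@pytest.fixture(scope="session")
def null_synth():
    """Corpus with no context effect at all (residual-only features)."""
    return sc.simulate_corpus(sc.SynthConfig(
        n_languages=10, songs_per_language=4, n_contexts=4, n_features=4,
        sigma2_behavior=0.0, sigma2_culture=0.0, sigma2_phylo=0.0,
        sigma2_geo=0.0, sigma2_resid=1.0, seed=7,
    ))
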