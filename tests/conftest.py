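import numpy as np
import pandas as pd
import pytest

from speechstate.corpus_io import CategoryLexicon, NormLexicon, NORM_NAMES
from speechstate.feature_assembly import default_manifest
from speechstate.synthetic_cohort import demo_lexicons


@pytest.fixture(scope="session")
def norm_lexicon() -> NormLexicon:
    return demo_lexicons()[0]


@pytest.fixture(scope="session")
def category_lexicon() -> CategoryLexicon:
    return demo_lexicons()[1]


@pytest.fixture
def tiny_norm_lexicon() -> NormLexicon:
    """Hand-sized lexicon with known norm values for oracle tests."""
    base = {n: 0.5 for n in NORM_NAMES}
    return NormLexicon(
        {
            "happy": [{**base, "valence": 0.8}[n] for n in NORM_NAMES],
            "sad": [{**base, "valence": 0.2}[n] for n in NORM_NAMES],
            "table": [{**base, "valence": 0.4}[n] for n in NORM_NAMES],
        }
    )


@pytest.fixture
def tiny_category_lexicon() -> CategoryLexicon:
    return CategoryLexicon({"posemo": ["happy", "joy*"], "negemo": ["sad"]})


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


def make_windowed_frame(
    n_participants: int,
    n_windows: int,
    n_features: int = 20,
    loading_mode: str = "shared",
    noise_sd: float = 0.3,
    seed: int = 0,
    phi: float = 0.8,
) -> pd.DataFrame:
    """Directly synthesize a windowed feature table for model-layer tests.

    Latent AR(1) state per participant; the first half of the features
    load on the state (with per-participant random signs in heterogeneous
    mode), the rest are pure noise.
    """
    rng = np.random.default_rng(seed)
    records = []
    feature_names = [f"q1__f{i:02d}" for i in range(n_features)]
    for p in range(n_participants):
        state = np.empty(n_windows)
        state[0] = rng.normal(5.5, 1.0)
        for t in range(1, n_windows):
            state[t] = 5.5 + phi * (state[t - 1] - 5.5) + rng.normal(0, 0.8)
        if loading_mode == "shared":
            signs = np.ones(n_features // 2)
        else:
            signs = rng.choice([-1.0, 1.0], size=n_features // 2)
        for t in range(n_windows):
            feats = np.empty(n_features)
            feats[: n_features // 2] = signs * state[t] + rng.normal(
                0, noise_sd, n_features // 2
            )
            feats[n_features // 2 :] = rng.normal(0, 1.0, n_features - n_features // 2)
            rec = {
                "participant_id": f"P{p:02d}",
                "window_index": t,
                "rating": float(np.clip(state[t] + rng.normal(0, 0.3), 1, 10)),
                "n_calls": 4,
            }
            rec.update(zip(feature_names, feats))
            records.append(rec)
    return pd.DataFrame(records)
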