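import numpy as np
import pandas as pd
import pytest

from bct_texture.phantom import PhantomConfig, generate_cohort
from bct_texture.pipeline import extract_feature_table
from bct_texture.texture import QuantizedRoi


@pytest.fixture
def small_config() -> PhantomConfig:
    """Fast phantom geometry for unit tests (full stacks live in acceptance)."""
    return PhantomConfig(n_slices=4, slice_shape=(96, 96), correlation_length_px=6.0)


@pytest.fixture
def qroi_factory():
    """Build a QuantizedRoi directly from explicit levels (and mask)."""

    def make(levels, mask=None, n_g=None):
        levels = np.atleast_2d(np.asarray(levels, dtype=np.int32))
        if levels.ndim == 2:
            levels = levels[np.newaxis]
        if mask is None:
            mask = np.ones_like(levels, dtype=bool)
        else:
            mask = np.atleast_2d(np.asarray(mask, dtype=bool))
            if mask.ndim == 2:
                mask = mask[np.newaxis]
        return QuantizedRoi(levels=levels, n_g=n_g or int(levels.max()), mask=mask)

    return make


def _random_feature_table(rng: np.random.Generator, n_per_class: int = 10) -> pd.DataFrame:
    """Synthetic feature table whose features track density to varying degree."""
    from bct_texture.texture import FEATURE_NAMES

    rows = []
    for k, cls in enumerate("abcd"):
        for _ in range(n_per_class):
            base = {"density": cls}
            for i, f in enumerate(FEATURE_NAMES):
                slope = (i % 5) - 2  # mix of increasing/decreasing/flat features
                base[f] = slope * k + rng.normal(0, 1.0)
            rows.append(base)
    return pd.DataFrame(rows)


@pytest.fixture
def random_feature_table() -> pd.DataFrame:
    return _random_feature_table(np.random.default_rng(42))


@pytest.fixture(scope="session")
def cohort10_features() -> pd.DataFrame:
    """Default-geometry phantom cohort, 10 exams per class (40 stacks)."""
    exams = generate_cohort(PhantomConfig(), n_per_class=10, seed=101)
    return extract_feature_table(exams)


@pytest.fixture(scope="session")
def cohort50_features() -> pd.DataFrame:
    """Default-geometry phantom cohort at the study size: 50 per class."""
    exams = generate_cohort(PhantomConfig(), n_per_class=50, seed=202)
    return extract_feature_table(exams)
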