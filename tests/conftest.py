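import numpy as np
import pytest

from peptox.fegs import FegsEncoder, PropertyTable
from peptox.models import EncoderConfig


@pytest.fixture(scope="session")
def packaged_encoder() -> FegsEncoder:
    """The full 158-property graphical encoder (578-dim output)."""
    return FegsEncoder()


@pytest.fixture(scope="session")
def small_table() -> PropertyTable:
    """A 5-property table for fast unit tests of the graphical encoder."""
    rng = np.random.default_rng(42)
    values = rng.normal(2.0, 1.5, size=(5, 20))
    return PropertyTable(tuple(f"P{i}" for i in range(5)), values)


@pytest.fixture(scope="session")
def small_fegs(small_table) -> FegsEncoder:
    return FegsEncoder(table=small_table)


@pytest.fixture()
def tiny_config() -> EncoderConfig:
    """A miniature encoder config for fast forward/backward tests."""
    return EncoderConfig(
        max_len=24,
        cnn_filters=8,
        cnn_kernel=5,
        cnn_stride=2,
        gru_hidden=6,
        gru_layers=2,
        d_model=8,
        n_heads=2,
        n_encoder_layers=2,
        ffn_dim=16,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
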