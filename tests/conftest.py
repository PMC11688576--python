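import numpy as np
import pytest

from ordimpute import ScaleSpec, apply_mask, generate_scale_data, mcar_mask

# reduced transformer configuration used wherever many fits are needed;
# the full-size default (embed 32, depth 4/2, 300 epochs) trains the same
# architecture, just wider and longer
FAST_REMASKER = dict(
    embed_dim=16, encoder_depth=2, decoder_depth=1, n_heads=2, ff_mult=2,
    epochs=150,
)


@pytest.fixture(scope="session")
def likert_500():
    """One-factor synthetic scale data, n=500, default spec."""
    return generate_scale_data(ScaleSpec(), 500, seed=101)


@pytest.fixture(scope="session")
def incomplete_500(likert_500):
    """likert_500 with a 10% MCAR mask applied."""
    mask = mcar_mask(*likert_500.shape, rate=0.10, seed=202)
    return likert_500, mask, apply_mask(likert_500, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
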