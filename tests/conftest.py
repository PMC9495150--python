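import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from birdcall import synth


@pytest.fixture(scope="session")
def specs8():
    return synth.make_species_specs(8, seed=1)


@pytest.fixture(scope="session")
def clean_clip(specs8):
    """One noise-free 10 s call (deterministic)."""
    return synth.synthesize_call(specs8[0], 10.0, float("-inf"), seed=3)


@pytest.fixture(scope="session")
def standardized_clip(specs8):
    """A clip pushed through the full cleaning chain (accepted)."""
    from birdcall.preprocess import preprocess_clip

    clip = synth.synthesize_call(specs8[2], 8.0, -25.0, seed=11)
    result = preprocess_clip(clip, gate_db=-30.0)
    assert result.accepted
    return result.clip


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """4 species x 4 clips, written to disk once per session."""
    out = tmp_path_factory.mktemp("tiny_corpus")
    specs = synth.make_species_specs(4, seed=5)
    manifest = synth.build_dataset(specs, 4, out, seed=5, noise_db=-25.0,
                                   clip_dur_range=(4.0, 7.0))
    return specs, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
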