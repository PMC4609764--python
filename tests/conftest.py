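import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pcurve_meta import GeneratorConfig, generate_trials


@pytest.fixture
def default_corpus():
    """A reproducible 10-study corpus from the default generator."""
    return generate_trials(GeneratorConfig(seed=12345))


@pytest.fixture
def null_corpus():
    """A reproducible corpus with no true effect and no heterogeneity."""
    return generate_trials(GeneratorConfig(theta=0.0, tau=0.0, seed=54321))
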