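import numpy as np
import pytest

from metapatterns import MOTIF_NAMES, build_motif, draw_local_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(params=MOTIF_NAMES)
def motif(request):
    return build_motif(request.param)


@pytest.fixture(scope="session")
def small_ensembles():
    """One small feasible local ensemble per motif, shared across tests."""
    out = {}
    for k, name in enumerate(MOTIF_NAMES):
        out[name] = draw_local_ensemble(name, 40, np.random.default_rng([99, k]))
    return out
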