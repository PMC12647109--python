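import numpy as np
import pytest

from drugswarm.data import SeverityLexicon
from drugswarm.objective import brute_force_optimum
from drugswarm.synth import generate_frame, preset_spec, _normalized_table


@pytest.fixture(scope="session")
def lexicon():
    return SeverityLexicon.toy()


@pytest.fixture(scope="session")
def small_planted(lexicon):
    """Planted-optimum instance D=12, k=3 with its normalized table and oracle."""
    spec = preset_spec("planted-small", seed=7)
    frame, planted = generate_frame(spec, lexicon)
    table = _normalized_table(frame, lexicon)
    sel, val = brute_force_optimum(table, spec.k)
    return {
        "spec": spec,
        "frame": frame,
        "table": table,
        "planted": np.sort(planted),
        "optimum": sel,
        "optimum_value": val,
    }


@pytest.fixture(scope="session")
def small_csv(tmp_path_factory, small_planted):
    path = tmp_path_factory.mktemp("synth") / "planted-small.csv"
    small_planted["frame"].to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
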