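import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hairpin_ct(tmp_path):
    """5-nt hairpin: positions 1-5 pair 1<->5 and 2<->4, loop at 3."""
    text = (
        "5 hairpin\n"
        "1 G 0 2 5 1\n"
        "2 C 1 3 4 2\n"
        "3 A 2 4 0 3\n"
        "4 G 3 5 2 4\n"
        "5 C 4 0 1 5\n"
    )
    path = tmp_path / "hairpin.ct"
    path.write_text(text)
    return path
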