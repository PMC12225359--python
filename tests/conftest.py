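import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240620)


@pytest.fixture
def rr_file(tmp_path):
    """Write an RR text file and return its path."""

    def _write(lines, name="rr.txt"):
        path = tmp_path / name
        path.write_text("\n".join(str(x) for x in lines) + "\n", encoding="utf-8")
        return path

    return _write
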