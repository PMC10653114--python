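import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def gaussian_workset():
    """A well-overlapping Gaussian CFT pair with known ΔG = 10 kJ/mol."""
    from neqpka.synthetic import GeneratorSpec, gaussian_cft_pair

    spec = GeneratorSpec(dg_true=10.0, sigma=5.0, n_forward=2000, n_reverse=2000, seed=42)
    return gaussian_cft_pair(spec)


@pytest.fixture
def write_xvg(tmp_path):
    """Factory writing a minimal XVG file and returning its path."""

    def _write(rows, name="curve.xvg", header=("# test file", "@ xaxis label")):
        path = tmp_path / name
        lines = list(header) + [f"{x} {y}" for x, y in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
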