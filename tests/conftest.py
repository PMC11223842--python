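import numpy as np
import pytest

from calibrt.data_io import CalibrationPoints


@pytest.fixture
def rng():
    return np.random.default_rng(20240703)


@pytest.fixture
def linear_points():
    """10k points on y = 0.5x + 3 over x in [0, 100], no noise."""
    x = np.linspace(0.0, 100.0, 10_000)
    return CalibrationPoints(x, 0.5 * x + 3.0)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, header, rows):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
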