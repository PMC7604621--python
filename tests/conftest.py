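import numpy as np
import pytest

from mrnapolar.motifs import estimate_pwm
from mrnapolar.spots import cell_geometry


@pytest.fixture(scope="session")
def informative_pwm():
    """Width-10 near-consensus PWM, recoverable at p < 1e-5 on uniform background."""
    return estimate_pwm(["ACGTACGTAC"] * 10, pseudocount=0.1)


@pytest.fixture()
def disk_geometry():
    """Rasterised disk of radius 10 um at 0.1 um/px."""
    r_um, px = 10.0, 0.1
    n = int(2 * r_um / px) + 4
    c = n / 2 * px
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = (cols + 0.5) * px
    y = (rows + 0.5) * px
    mask = (x - c) ** 2 + (y - c) ** 2 <= r_um**2
    return cell_geometry(mask, px)
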