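import numpy as np
import pytest

from dixonquant import leg_phantom_spec, render_multiecho

#: 2D three-point protocol echo times (s); at 434.78 Hz fat-water shift the
#: fat phase advances 1.5 / 2.0 / 2.5 cycles (opposed / in / opposed phase).
ECHO_TIMES = np.array([3.45e-3, 4.6e-3, 5.75e-3])

#: Fat-water shift that makes those TEs exactly opposed/in/opposed phase.
FAT_FREQ = 1.0 / (2.0 * 1.15e-3)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless 14-muscle leg phantom, no off-resonance."""
    spec = leg_phantom_spec(fat_freq_hz=FAT_FREQ)
    img, truth = render_multiecho(spec, ECHO_TIMES)
    return spec, img, truth


@pytest.fixture(scope="session")
def ramp_field_phantom():
    """Noiseless phantom under a smooth -100..+100 Hz off-resonance ramp."""
    coeffs = np.zeros((2, 2))
    coeffs[0, 1] = 100.0  # left-right ramp over the FOV
    coeffs[1, 0] = 30.0
    coeffs[0, 0] = 15.0
    spec = leg_phantom_spec(field_coeffs=coeffs, fat_freq_hz=FAT_FREQ)
    img, truth = render_multiecho(spec, ECHO_TIMES)
    return spec, img, truth
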