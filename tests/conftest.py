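import numpy as np
import pytest

from biofilmmech import DiscGeometry, FluidProperties, ProbeGeometry


@pytest.fixture(scope="session")
def geometry():
    return DiscGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture
def bilinear_curve():
    """Noiseless bilinear indentation fixture factory.

    Zero force to delta_c, slope k through thickness h, then k*ratio beyond.
    """
    from biofilmmech import ForceDisplacementCurve

    def make(k=0.5, delta_c=50e-6, h=200e-6, ratio=200.0, span=350e-6, n=701):
        disp = np.linspace(0.0, span, n)
        delta_s = delta_c + h
        force = np.where(
            disp < delta_c,
            0.0,
            np.where(disp < delta_s, k * (disp - delta_c),
                     k * h + ratio * k * (disp - delta_s)),
        )
        return ForceDisplacementCurve(displacement=disp, force=force)

    return make
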