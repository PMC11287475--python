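import numpy as np
import pytest

from rankcast.growth import GrowthCurve, fit_plate, gompertz
from rankcast.synth import generate_plate, gim_like_spec


@pytest.fixture(scope="session")
def gim_spec():
    return gim_like_spec(seed=11)


@pytest.fixture(scope="session")
def gim_plate(gim_spec):
    return generate_plate(gim_spec)


@pytest.fixture(scope="session")
def gim_params(gim_plate):
    """Fitted growth parameters for the default synthetic community plate."""
    from rankcast.growth import read_plate_csv
    import io

    buf = io.StringIO()
    gim_plate.to_csv(buf, index=False)
    buf.seek(0)
    return fit_plate(read_plate_csv(buf))


def make_curve(A=1.2, mu=0.3, lam=3.0, dt=0.25, t_max=36.0, noise=0.0, seed=0,
               species="X", blank=0.0):
    """Synthetic Gompertz curve on a regular grid, optional Gaussian noise."""
    t = np.arange(0.0, t_max + 1e-9, dt)
    od = blank + gompertz(t, A, mu, lam)
    if noise:
        od = od + np.random.default_rng(seed).normal(0.0, noise, size=t.size)
    return GrowthCurve(species=species, replicate="r1", times=t, od=np.maximum(od, 0.0))


@pytest.fixture
def curve_factory():
    return make_curve
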