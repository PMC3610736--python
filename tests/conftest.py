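import numpy as np
import pytest

from meiox import BodyModelParams, MonodParams
from meiox.datasets import monod_coefficients


@pytest.fixture(scope="session")
def coeffs():
    """Published Monod coefficient table, indexed by treatment."""
    return monod_coefficients().set_index("treatment")


@pytest.fixture
def standard_body():
    """Oxic pore water, literature tissue respiration and diffusivity."""
    return BodyModelParams(aw=230.0, q=0.5, d=1.0e-9)


@pytest.fixture
def nematode1_params(coeffs):
    """Drawdown parameters rebuilt from the Nematode1 coefficient row.

    The volumetric R_max is recovered from the biomass-specific daily rate
    through the chamber geometry (300 µl, measured biomass).
    """
    row = coeffs.loc["Nematode1"]
    r_max_vol = row.r_100 * row.biomass_ugC / (3.0e-4 * 24.0 * 12.0)
    return MonodParams(
        r_max_vol=r_max_vol, k_s=row.k_s, o2_init=row.o2_init, o2_min=row.o2_min
    )


def monod_oracle(params: MonodParams, times_h) -> np.ndarray:
    """Independent drawdown solution via root-finding on the implicit form.

    Separation of variables gives k_s·ln(u/u0) + (u−u0) = −R_max·t with
    u = C − O2_min; brentq solves it per time point. Deliberately avoids
    both the package's ODE integrator and its closed-form path.
    """
    from scipy.optimize import brentq

    u0 = params.o2_init - params.o2_min
    out = np.empty(len(times_h))
    for i, t in enumerate(np.asarray(times_h, dtype=float)):
        f = lambda u: params.k_s * np.log(u / u0) + (u - u0) + params.r_max_vol * t
        out[i] = brentq(f, 1e-300, u0, xtol=1e-14, rtol=1e-15)
    return params.o2_min + out
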