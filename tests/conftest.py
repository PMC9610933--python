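import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sedsim import default_config, load_fixtures


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def fx():
    return load_fixtures()


def ode_effect_site(pk, ts):
    """Independent oracle: integrate the full compartment system stiffly."""

    def rhs(t, y):
        a1, a2, a3, ce = y
        da1 = -(pk.k10 + pk.k12 + pk.k13) * a1 + pk.k21 * a2 + pk.k31 * a3
        da2 = pk.k12 * a1 - pk.k21 * a2
        da3 = pk.k13 * a1 - pk.k31 * a3
        dce = pk.ke0 * (a1 / pk.V1 - ce)
        return [da1, da2, da3, dce]

    sol = solve_ivp(
        rhs,
        (0.0, ts[-1]),
        [1.0, 0.0, 0.0, 0.0],
        t_eval=ts,
        rtol=1e-11,
        atol=1e-14,
        method="LSODA",
    )
    return sol.y[3]


def random_pk(rng):
    """A random log-uniform positive parameter set (2 or 3 compartments)."""
    from sedsim import PKParameters

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    n = int(rng.integers(2, 4))
    k13 = lu(1e-3, 0.3) if n == 3 else 0.0
    k31 = lu(1e-3, 0.1) if n == 3 else 0.0
    return PKParameters(
        drug_name="random",
        n_compartments=n,
        V1=lu(1.0, 50.0),
        k10=lu(5e-3, 0.5),
        k12=lu(1e-2, 1.0),
        k21=lu(1e-2, 0.5),
        k13=k13,
        k31=k31,
        ke0=lu(0.05, 2.0),
    )
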