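import numpy as np
import pytest

from grnsim.dynamics import default_kinetic_params, default_regulatory_params
from grnsim.genotypes import CoreGenes, simulate_genotypes
from grnsim.network import BasalGeometrySpec, RegulatoryNetwork, generate_network


@pytest.fixture(scope="session")
def net5():
    """Small generated 5-gene network used by solver tests."""
    return generate_network(
        5, [BasalGeometrySpec(1, 1.0, (1.0, 0.0))], seed=1, n_core=2
    )


@pytest.fixture(scope="session")
def net50():
    """50-gene, 12-core network matching the case-study shape."""
    return generate_network(
        50, [BasalGeometrySpec(1, 1.0, (1.0, 0.0))], seed=7, n_core=12
    )


@pytest.fixture(scope="session")
def core50(net50):
    return CoreGenes(indices=net50.core_indices, weights=net50.core_weights)


@pytest.fixture
def motif3():
    """Gene 0 activates gene 2; gene 1 represses gene 2."""
    A = np.zeros((3, 3), dtype=int)
    R = np.zeros((3, 3), dtype=int)
    A[0, 2] = 1
    R[1, 2] = 1
    return RegulatoryNetwork(A=A, R=R)


@pytest.fixture(scope="session")
def gentle_system(net5):
    """5-gene parameters mild enough for fixed-step Euler accuracy checks."""
    n = 5
    reg = default_regulatory_params(n, exponent_base=n)
    kin = default_kinetic_params(n, Kx=0.5, Ks=0.2, Zx=0.05, Zs=0.05, Tmax=20.0)
    return net5, reg, kin


@pytest.fixture(scope="session")
def pop200():
    return simulate_genotypes(200, 50, seed=3)


def scipy_reference(net, reg, kin, y0, t_eval=None, rtol=1e-11, atol=1e-13):
    """High-accuracy adaptive ODE oracle for the deterministic system."""
    from scipy.integrate import solve_ivp

    import grnsim.dynamics as dyn

    n = kin.n_genes
    AT = net.A.T.astype(float)
    RT = net.R.T.astype(float)
    expo = dyn._exponents(reg, net)

    def f(t, y):
        x, s = y[:n], y[n:]
        p = dyn._binding_probabilities_fast(s, reg, AT, RT, expo)
        return np.concatenate([kin.Kx * p - kin.Zx * x, kin.Ks * x - kin.Zs * s])

    return solve_ivp(
        f, (0.0, kin.Tmax), y0, rtol=rtol, atol=atol, dense_output=True, t_eval=t_eval
    )
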