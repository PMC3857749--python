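import numpy as np
import pytest

from sirstreat import find_equilibria, section3_params, subcritical_hopf_params


@pytest.fixture(scope="session")
def sec3():
    """The bundled worked-example parameter set."""
    return section3_params()


@pytest.fixture(scope="session")
def sec3_report(sec3):
    return find_equilibria(sec3)


@pytest.fixture(scope="session")
def sec3_inside(sec3_report):
    inside = sec3_report.in_domain_equilibria
    assert len(inside) == 2
    return inside


@pytest.fixture(scope="session")
def hopf_params():
    """Synthetic parameter set with a genuine subcritical Hopf point nearby."""
    return subcritical_hopf_params()


@pytest.fixture(scope="session")
def hopf_focus(hopf_params):
    """The weakly stable focus of the synthetic Hopf fixture (I near 1)."""
    inside = find_equilibria(hopf_params).in_domain_equilibria
    return min(inside, key=lambda e: abs(e.I - 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20131121)


def fd_jacobian(fun, point, eps=1e-6):
    """Central-difference Jacobian of a planar vector field."""
    point = np.asarray(point, dtype=float)
    J = np.zeros((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = eps * max(1.0, abs(point[j]))
        hi = np.asarray(fun(point + step))
        lo = np.asarray(fun(point - step))
        J[:, j] = (hi - lo) / (2.0 * step[j])
    return J
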