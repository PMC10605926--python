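import numpy as np
import pytest

from fedssvm import CohortSpec, Hyperparams, generate_dataset


# ---------------------------------------------------------------------------
# independent 1-D prox oracles: bisection on the (analytic, monotone)
# subgradient of the 1-D prox objective. These never touch the closed forms
# under test; they only use the objective's calculus.
# ---------------------------------------------------------------------------

def _bisect_monotone(phi, lo, hi, iters=200):
    """Root of a monotone nondecreasing (possibly jumping) function."""
    flo, fhi = phi(lo), phi(hi)
    if flo >= 0:
        return lo
    if fhi <= 0:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if phi(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def numeric_prox_regularizer_1d(u, tau, psi, rho):
    """argmin_z tau*(rho*|z| + 0.5*psi*z^2) + 0.5*(z-u)^2 by bisection on
    phi(z) = tau*rho*sign(z) + tau*psi*z + z - u."""

    def phi(z):
        return tau * rho * np.sign(z) + tau * psi * z + z - u

    bound = abs(u) + 1.0
    return _bisect_monotone(phi, -bound, bound)


def numeric_prox_hinge_conjugate_1d(v, sigma):
    """argmin_{z in [-1, 0]} sigma*z + 0.5*(z-v)^2."""

    def phi(z):
        return sigma + z - v

    return _bisect_monotone(phi, -1.0, 0.0)


def numeric_prox_hinge_1d(w, scale):
    """argmin_z max(0, 1-z)/scale + 0.5*(z-w)^2 (prox of h/scale)."""

    def phi(z):
        return (-1.0 / scale if z < 1.0 else 0.0) + z - w

    lo = min(w, 1.0) - 2.0 / scale - 2.0
    hi = max(w, 1.0) + 2.0
    return _bisect_monotone(phi, lo, hi)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    """n=80, d=8, noisy — the workhorse instance."""
    return generate_dataset(CohortSpec(80, 4, 4, 3, label_noise=0.1, seed=11))


@pytest.fixture(scope="session")
def separable_cohort():
    """Noiseless cohort: labels exactly sign of the ground-truth score."""
    return generate_dataset(CohortSpec(120, 5, 5, 4, signal_scale=2.0,
                                       label_noise=0.0, seed=3))


@pytest.fixture(scope="session")
def default_hp():
    return Hyperparams(psi=0.5, rho=0.2)
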