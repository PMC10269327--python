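import math

import numpy as np
import pytest

from conikit.diabatization import AdiabaticPoint, Gauge
from conikit.models import analytic_backend


@pytest.fixture
def rng():
    return np.random.default_rng(20230516)


def random_adiabatic_point(rng, m=6, scale=1.0):
    """A physically consistent random adiabatic point (E_A >= E_B)."""
    e_b = -78.0 + rng.normal() * 0.1
    gap = abs(rng.normal()) * scale + 1e-3
    return AdiabaticPoint(
        q=rng.normal(size=m), E_A=e_b + gap, E_B=e_b,
        s=rng.normal(size=m), g=rng.normal(size=m), h=rng.normal(size=m))


def random_gauge(rng, m=6):
    return Gauge(q_ref=rng.normal(size=m), k_delta=rng.normal(size=m),
                 k_gamma=rng.normal(size=m))


class LinearTwoState:
    """Exact linear diabatic model: alpha, beta, gamma linear in q.

    Serves as the independent oracle for the gauge-angle fit: on data drawn
    from this model the fitted omega must coincide with the Moore-Penrose
    solve of the 2x2 rotation extraction.
    """

    def __init__(self, rng, m=4):
        self.m = m
        self.k_tau = rng.normal(size=m) * 0.1
        self.k_delta = rng.normal(size=m)
        self.k_gamma = rng.normal(size=m)
        # keep the two directions clearly non-parallel
        while abs(self.k_delta @ self.k_gamma) > 0.8 * np.linalg.norm(
                self.k_delta) * np.linalg.norm(self.k_gamma):
            self.k_gamma = rng.normal(size=m)
        self.tau0 = -78.0

    def adiabatic(self, q):
        q = np.asarray(q, dtype=float)
        tau = self.tau0 + self.k_tau @ q
        delta = self.k_delta @ q
        gamma = self.k_gamma @ q
        lam = math.hypot(delta, gamma)
        omega = math.atan2(gamma, delta) if lam > 1e-12 else 0.0
        c, s = math.cos(omega), math.sin(omega)
        return AdiabaticPoint(
            q=q, E_A=tau + lam, E_B=tau - lam, s=self.k_tau.copy(),
            g=c * self.k_delta + s * self.k_gamma,
            h=-s * self.k_delta + c * self.k_gamma)


@pytest.fixture
def linear_model(rng):
    return LinearTwoState(rng)


@pytest.fixture
def quadratic_ci():
    """A fixed quadratic conical-intersection model plus its backend."""
    return analytic_backend("quadratic_cone", seed=7)


@pytest.fixture
def spin_model():
    return analytic_backend("spin_harmonic", {"m": 2})
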