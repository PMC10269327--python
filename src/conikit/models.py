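"""Analytic two-state model Hamiltonians with known diabats, seams and MECPs.

These stand in for an electronic-structure program: each model defines smooth
diabatic surfaces alpha(q), beta(q), gamma(q) (polynomials with analytic
gradients and Hessians), and the backend callable diagonalizes the 2x2
Hamiltonian to return adiabatic energies, gradients and the coupling vector
at any geometry — optionally with a random per-call sign on h, mimicking the
arbitrary wavefunction phase of a real calculation.

Families
--------
linear_cone     linear diabats; in 2-D the whole seam is the cone apex.
quadratic_cone  quadratic diabats; the linear picture fails away from the
                MECP (curved seam / curved gap growth), exercising the
                surrogate beyond first order.
spin_harmonic   two isotropic paraboloids with gamma = 0 everywhere
                (different spin multiplicities); the MECP has a closed-form
                Lagrange solution.
random_poly     randomly drawn quadratic diabats for property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml
from scipy.optimize import minimize

from .constants import DEGENERACY_TOL
from .diabatization import AdiabaticPoint

__all__ = [
    "TwoStateModel",
    "Quadratic",
    "analytic_backend",
    "make_backend",
    "brute_force_mecp",
    "generate_history",
    "load_model_yaml",
    "MODEL_FAMILIES",
    "get_backend",
]


@dataclass
class Quadratic:
    """c0 + c1.(q-q0) + 1/2 (q-q0)^T C2 (q-q0), with gradient and Hessian."""

    q0: np.ndarray
    c0: float
    c1: np.ndarray
    C2: np.ndarray

    def __post_init__(self) -> None:
        self.q0 = np.asarray(self.q0, dtype=float)
        self.c1 = np.asarray(self.c1, dtype=float)
        self.C2 = np.asarray(self.C2, dtype=float)

    def value(self, q: np.ndarray) -> float:
        dq = np.asarray(q, dtype=float) - self.q0
        return float(self.c0 + self.c1 @ dq + 0.5 * dq @ self.C2 @ dq)

    def gradient(self, q: np.ndarray) -> np.ndarray:
        dq = np.asarray(q, dtype=float) - self.q0
        return self.c1 + self.C2 @ dq

    def hessian(self, _q: np.ndarray | None = None) -> np.ndarray:
        return self.C2


@dataclass
class TwoStateModel:
    """Two smooth diabats plus coupling, with every derivative analytic."""

    m: int
    alpha: Quadratic
    beta: Quadratic
    gamma: Quadratic
    spin: bool = False
    known_mecp: np.ndarray | None = None
    description: str = ""

    def diabats(self, q):
        """(alpha, beta, gamma) values and gradients at q."""
        return (self.alpha.value(q), self.beta.value(q), self.gamma.value(q),
                self.alpha.gradient(q), self.beta.gradient(q),
                self.gamma.gradient(q))

    def tau_delta_gamma(self, q):
        a, b, c, ga, gb, gc = self.diabats(q)
        return (0.5 * (a + b), 0.5 * (a - b), c,
                0.5 * (ga + gb), 0.5 * (ga - gb), gc)

    def gap(self, q) -> float:
        """Adiabatic gap E_A - E_B = 2 sqrt(delta^2 + gamma^2)."""
        _t, d, c, *_ = self.tau_delta_gamma(q)
        return 2.0 * math.hypot(d, c)

    def adiabatic(self, q) -> AdiabaticPoint:
        """Diagonalize the model Hamiltonian at q (deterministic h phase)."""
        tau, delta, gam, gt, gd, gc = self.tau_delta_gamma(q)
        if self.spin:
            # no coupling: keep diabatic labels, surfaces may cross
            return AdiabaticPoint(
                q=np.asarray(q, dtype=float), E_A=tau + delta, E_B=tau - delta,
                s=gt, g=gd, h=np.zeros(self.m), h_defined=False,
                degenerate=abs(delta) < DEGENERACY_TOL)
        lam = math.hypot(delta, gam)
        degenerate = lam < DEGENERACY_TOL
        omega = 0.0 if degenerate else math.atan2(gam, delta)
        c, s = math.cos(omega), math.sin(omega)
        return AdiabaticPoint(
            q=np.asarray(q, dtype=float), E_A=tau + lam, E_B=tau - lam, s=gt,
            g=c * gd + s * gc, h=-s * gd + c * gc,
            h_defined=True, degenerate=degenerate)


def make_backend(model: TwoStateModel, random_phase: bool = False,
                 seed: int | None = None) -> Callable[[np.ndarray], AdiabaticPoint]:
    """Wrap a model as a backend callable q -> AdiabaticPoint.

    With ``random_phase`` the sign of h is randomized per call (but
    deterministically in the call sequence for a fixed seed), exercising the
    diabatization sign-flip rule.
    """
    rng = np.random.default_rng(seed)

    def backend(q: np.ndarray) -> AdiabaticPoint:
        p = model.adiabatic(q)
        if random_phase and p.h_defined and rng.random() < 0.5:
            p = AdiabaticPoint(q=p.q, E_A=p.E_A, E_B=p.E_B, s=p.s, g=p.g,
                               h=-p.h, h_defined=True, degenerate=p.degenerate)
        return p

    return backend


def _sym(rng: np.random.Generator, m: int, scale: float) -> np.ndarray:
    a = rng.uniform(-scale, scale, (m, m))
    return 0.5 * (a + a.T)


def _spd(rng: np.random.Generator, m: int, lo: float, hi: float) -> np.ndarray:
    evals = rng.uniform(lo, hi, m)
    qmat, _ = np.linalg.qr(rng.standard_normal((m, m)))
    return qmat @ np.diag(evals) @ qmat.T


def _linear_cone(params: dict, rng: np.random.Generator) -> TwoStateModel:
    m = int(params.get("m", 2))
    apex = np.asarray(params.get("apex", [0.3, -0.2][:m] + [0.0] * max(0, m - 2)),
                      dtype=float)
    u = np.asarray(params.get("g_slope", [0.9, 0.15][:m] + [0.1] * max(0, m - 2)),
                   dtype=float)
    v = np.asarray(params.get("h_slope", [0.2, 0.8][:m] + [-0.1] * max(0, m - 2)),
                   dtype=float)
    t = np.asarray(params.get("s_slope", [0.05, -0.03][:m] + [0.02] * max(0, m - 2)),
                   dtype=float)
    e0 = float(params.get("e0", -78.0))
    zero = np.zeros((m, m))
    tau = Quadratic(apex, e0, t, zero)
    delta = Quadratic(apex, 0.0, u, zero)
    gam = Quadratic(apex, 0.0, v, zero)
    alpha = Quadratic(apex, tau.c0 + delta.c0, t + u, zero)
    beta = Quadratic(apex, tau.c0 - delta.c0, t - u, zero)
    mecp = apex if m == 2 else None  # in 2-D the seam is the apex itself
    return TwoStateModel(m=m, alpha=alpha, beta=beta, gamma=gam,
                         known_mecp=mecp, description="linear double cone")


def _quadratic_cone(params: dict, rng: np.random.Generator) -> TwoStateModel:
    m = int(params.get("m", 2))
    apex = np.asarray(params.get("apex", rng.uniform(-0.5, 0.5, m)), dtype=float)
    # delta and gamma: linear slopes with a guaranteed opening angle, plus
    # mild curvature so the linear picture degrades away from the seam
    # delta/gamma slopes with a guaranteed branching-plane opening angle of
    # at least ~35 degrees, so the gap grows healthily in every direction
    u = rng.uniform(0.4, 1.0) * _random_unit(rng, m)
    uhat = u / np.linalg.norm(u)
    w = _random_unit(rng, m)
    w -= (w @ uhat) * uhat
    what = w / np.linalg.norm(w)
    phi = rng.uniform(np.radians(35.0), np.radians(90.0))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    v = rng.uniform(0.4, 1.0) * (np.cos(phi) * uhat + sign * np.sin(phi) * what)
    # curvature kept moderate relative to the slopes: strong enough that a
    # linear picture degrades visibly within ~0.1 a0 of the seam, small
    # enough that the gap has no spurious (non-crossing) local minima inside
    # the optimization basin
    qd = _sym(rng, m, float(params.get("delta_curv", 0.12)))
    qg = _sym(rng, m, float(params.get("gamma_curv", 0.08)))
    t = rng.uniform(0.05, 0.15) * _random_unit(rng, m)
    qt = _spd(rng, m, 0.6, 1.4)
    e0 = float(params.get("e0", -78.0))
    tau = Quadratic(apex, e0, t, qt)
    delta = Quadratic(apex, 0.0, u, qd)
    gam = Quadratic(apex, 0.0, v, qg)
    alpha = Quadratic(apex, e0, t + u, qt + qd)
    beta = Quadratic(apex, e0, t - u, qt - qd)
    return TwoStateModel(m=m, alpha=alpha, beta=beta, gamma=gam,
                         known_mecp=None,
                         description="quadratic (asymmetric) double cone")


def _spin_harmonic(params: dict, rng: np.random.Generator) -> TwoStateModel:
    m = int(params.get("m", 2))
    a = np.asarray(params.get("center_a", [0.0] * m), dtype=float)
    b = np.asarray(params.get("center_b", [1.0] + [0.0] * (m - 1)), dtype=float)
    k = float(params.get("force_constant", 0.8))
    ea = float(params.get("e_a", -78.0))
    eb = float(params.get("e_b", -78.05))
    eye = np.eye(m)
    alpha = Quadratic(a, ea, np.zeros(m), k * eye)
    beta = Quadratic(b, eb, np.zeros(m), k * eye)
    gam = Quadratic(np.zeros(m), 0.0, np.zeros(m), np.zeros((m, m)))
    # closed-form constrained minimum: minimize the average energy on the
    # hyperplane alpha = beta (a Lagrange problem with linear constraint)
    # alpha - beta = k(b-a).q + 0.5k(|a|^2-|b|^2) + ea-eb = 0 is a hyperplane
    nvec = k * (b - a)
    cval = -(0.5 * k * (a @ a - b @ b) + ea - eb)
    mid = 0.5 * (a + b)
    mecp = mid + (cval - nvec @ mid) / (nvec @ nvec) * nvec
    return TwoStateModel(m=m, alpha=alpha, beta=beta, gamma=gam, spin=True,
                         known_mecp=mecp,
                         description="two isotropic paraboloids, gamma = 0")


def _random_poly(params: dict, rng: np.random.Generator) -> TwoStateModel:
    m = int(params.get("m", 3))
    scale = float(params.get("scale", 0.5))
    e0 = float(params.get("e0", -10.0))

    def rand_quad(c0):
        return Quadratic(rng.uniform(-0.5, 0.5, m), c0,
                         rng.uniform(-scale, scale, m), _sym(rng, m, scale))

    return TwoStateModel(m=m, alpha=rand_quad(e0 + rng.uniform(-0.2, 0.2)),
                         beta=rand_quad(e0 + rng.uniform(-0.2, 0.2)),
                         gamma=rand_quad(0.0),
                         description="random quadratic diabats")


def _random_unit(rng: np.random.Generator, m: int) -> np.ndarray:
    v = rng.standard_normal(m)
    return v / np.linalg.norm(v)


MODEL_FAMILIES: dict[str, Callable] = {
    "linear_cone": _linear_cone,
    "quadratic_cone": _quadratic_cone,
    "spin_harmonic": _spin_harmonic,
    "random_poly": _random_poly,
}


def analytic_backend(family: str, params: dict | None = None,
                     seed: int | None = None,
                     random_phase: bool = False):
    """Build a model of the given family and its backend callable.

    The same (family, params, seed) always yields an identical model.
    Returns (TwoStateModel, backend).
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; "
                         f"known: {sorted(MODEL_FAMILIES)}")
    rng = np.random.default_rng(seed)
    model = MODEL_FAMILIES[family](params or {}, rng)
    backend = make_backend(model, random_phase=random_phase,
                           seed=None if seed is None else seed + 1)
    return model, backend


def get_backend(name: str, params: dict | None = None, seed: int | None = None,
                random_phase: bool = False):
    """Resolve a backend by family name or plugin entry point.

    Third-party backends can register a factory under the entry-point group
    ``conikit.backends``; the factory receives (params, seed) and must return
    (model_or_None, backend_callable).
    """
    if name in MODEL_FAMILIES:
        return analytic_backend(name, params, seed, random_phase)
    from importlib.metadata import entry_points
    for ep in entry_points(group="conikit.backends"):
        if ep.name == name:
            return ep.load()(params, seed)
    raise ValueError(f"no backend named {name!r}")


def brute_force_mecp(model: TwoStateModel, bounds, resolution: int = 101,
                     c_final: float = 1e10, gap_tol: float = 0.05) -> np.ndarray:
    """Oracle MECP by grid scan plus increasing-penalty minimization.

    A grid over ``bounds`` locates the neighborhood of the seam (smallest
    adiabatic gap, lowest average energy among near-degenerate candidates);
    from there the smooth penalty function

        F_c(q) = tau(q) + c (delta(q)^2 + gamma(q)^2)

    is minimized with analytic gradients/Hessians for an increasing sequence
    of c up to ``c_final``.  The minimizer converges to the constrained
    minimum of the average energy on the seam as c grows (error ~ 1/c).
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != model.m:
        raise ValueError("bounds must have one (lo, hi) pair per dimension")
    axes = [np.linspace(lo, hi, resolution) for lo, hi in bounds]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    gaps = np.array([model.gap(p) for p in pts])
    if gaps.min() > gap_tol:
        raise ValueError(
            f"no seam inside bounds (min gap {gaps.min():.3g} > {gap_tol})")
    near = gaps <= max(2.0 * gaps.min(), 1e-3)
    taus = np.array([model.tau_delta_gamma(p)[0] for p in pts[near]])
    q = pts[near][int(np.argmin(taus))].copy()

    def fg(qv, c):
        tau, d, g, gt, gd, gg = model.tau_delta_gamma(qv)
        val = tau + c * (d * d + g * g)
        grad = gt + 2.0 * c * (d * gd + g * gg)
        return val, grad

    def hess(qv, c):
        _tau, d, g, _gt, gd, gg = model.tau_delta_gamma(qv)
        ht = 0.5 * (model.alpha.hessian() + model.beta.hessian())
        hd = 0.5 * (model.alpha.hessian() - model.beta.hessian())
        hg = model.gamma.hessian()
        return (ht + 2.0 * c * (np.outer(gd, gd) + d * hd
                                + np.outer(gg, gg) + g * hg))

    c = 1e2
    while c <= c_final:
        res = minimize(lambda x: fg(x, c), q, jac=True,
                       hess=lambda x: hess(x, c), method="trust-exact",
                       options={"gtol": 1e-12, "initial_trust_radius": 0.1,
                                "max_trust_radius": 1.0})
        q = res.x
        c *= 100.0
    return q


def generate_history(model: TwoStateModel, around: np.ndarray, n_points: int,
                     spread: float, seed: int | None = None,
                     random_phase: bool = False) -> list[AdiabaticPoint]:
    """Deterministic pseudo-random fixture history near a geometry.

    Draws ``n_points`` geometries uniformly within ``spread`` (bohr, per
    component) of ``around`` and evaluates them through the backend.  Points
    are guaranteed pairwise distinct.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    around = np.asarray(around, dtype=float)
    rng = np.random.default_rng(seed)
    backend = make_backend(model, random_phase=random_phase,
                           seed=None if seed is None else seed + 1)
    geoms: list[np.ndarray] = []
    while len(geoms) < n_points:
        q = around + rng.uniform(-spread, spread, model.m)
        if all(np.linalg.norm(q - g) > 1e-6 for g in geoms):
            geoms.append(q)
    return [backend(q) for q in geoms]


def load_model_yaml(path):
    """Load a model definition (family, params, seed) from a YAML file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "family" not in spec:
        raise ValueError(f"{path}: expected a mapping with a 'family' key")
    return analytic_backend(spec["family"], spec.get("params"),
                            spec.get("seed"),
                            bool(spec.get("random_phase", False)))
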