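"""Two-state diabatic <-> adiabatic transforms and gauge-fixed pseudodiabatization.

A crossing between two electronic states is described locally by a 2x2
symmetric Hamiltonian

    H(q) = [[alpha(q), gamma(q)],
            [gamma(q), beta(q)]]

whose eigenvalues are the adiabatic energies.  Writing tau = (alpha+beta)/2,
delta = (alpha-beta)/2 and interpreting (delta, gamma) as a 2-vector with
modulus lambda = sqrt(delta^2 + gamma^2) and argument omega = atan2(gamma,
delta), the adiabats are E_A = tau + lambda and E_B = tau - lambda.  The
average gradient s, half gradient-difference g and (difference-scaled)
nonadiabatic coupling h follow from the diabatic gradients by an in-plane
rotation by omega:

    s = grad tau
    g = cos(omega) grad delta + sin(omega) grad gamma     ( = grad lambda )
    h = -sin(omega) grad delta + cos(omega) grad gamma

The reverse direction (pseudodiabatization) is not unique: every choice of
omega gives valid smooth surfaces.  The gauge is fixed by declaring
omega(q_ref) = 0 at a reference geometry, i.e. k_delta = g(q_ref) and
k_gamma = h(q_ref).  At any other geometry the local {g, h} plane is first
rotated minimally (via the SVD of the inter-plane inner-product matrix) onto
span{k_delta, k_gamma}; the angle of the rotated pair in the reference frame,
averaged circularly between the g-based and h-based estimates, defines omega.
Because the electronic-structure phase of h is arbitrary, h is replaced by -h
whenever the two angle estimates disagree by more than pi/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CONDITIONING_MIN, DEGENERACY_TOL

__all__ = [
    "AdiabaticPoint",
    "DiabaticPoint",
    "Gauge",
    "PlaneRotationResult",
    "DegenerateBranchingPlaneError",
    "adiabatic_from_diabatic",
    "minimal_plane_rotation",
    "circular_mean",
    "fit_omega",
    "resolve_h_sign",
    "diabatize_point",
    "diabatize_history",
]

TWO_PI = 2.0 * math.pi


class DegenerateBranchingPlaneError(ValueError):
    """Raised when g and/or h vanish so no branching plane can be defined."""


def _wrap_angle(a: float) -> float:
    """Map an angle to (-pi, pi]."""
    w = math.remainder(a, TWO_PI)
    # math.remainder may return -pi for odd half-turns; normalize to +pi
    return math.pi if w == -math.pi else w


def _circ_dist(a: float, b: float) -> float:
    """Arc distance between two angles, in [0, pi]."""
    return abs(math.remainder(a - b, TWO_PI))


@dataclass
class AdiabaticPoint:
    """Adiabatic data at one geometry.

    q : geometry (bohr); E_A, E_B : upper/lower state energies (hartree);
    s : average gradient; g : half gradient-difference, g = (grad E_A - grad E_B)/2;
    h : difference-scaled nonadiabatic coupling, finite on the seam.
    All gradients in hartree/bohr.  ``h_defined`` is False in spin mode
    (different multiplicities: no coupling, h unused).  ``degenerate`` marks
    points where E_A - E_B is below the degeneracy tolerance.
    """

    q: np.ndarray
    E_A: float
    E_B: float
    s: np.ndarray
    g: np.ndarray
    h: np.ndarray
    h_defined: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        m = self.q.size
        for name in ("s", "g", "h"):
            v = getattr(self, name)
            if v.size != m:
                raise ValueError(f"{name} has length {v.size}, expected {m}")
        if not (np.isfinite(self.q).all() and np.isfinite(self.s).all()
                and np.isfinite(self.g).all() and math.isfinite(self.E_A)
                and math.isfinite(self.E_B)):
            raise ValueError("non-finite adiabatic data")
        if self.h_defined:
            if not np.isfinite(self.h).all():
                raise ValueError("non-finite coupling vector h")
            # adiabatic labelling: A is the upper state (spin mode may cross)
            if self.E_A < self.E_B - 1e-12:
                raise ValueError("E_A < E_B for a same-symmetry crossing")


@dataclass
class DiabaticPoint:
    """Gauge-fixed diabatic data at one geometry.

    alpha >= beta is *not* required: diabats are allowed to cross.  The
    reconstructed gap 2*sqrt(delta^2+gamma^2) is non-negative by construction.
    ``omega`` is the fitted mixing angle; ``h_flipped`` records whether the
    input coupling's sign was reversed during the fit.
    """

    q: np.ndarray
    alpha: float
    beta: float
    gamma: float
    grad_alpha: np.ndarray
    grad_beta: np.ndarray
    grad_gamma: np.ndarray
    omega: float = 0.0
    h_flipped: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.grad_alpha = np.asarray(self.grad_alpha, dtype=float)
        self.grad_beta = np.asarray(self.grad_beta, dtype=float)
        self.grad_gamma = np.asarray(self.grad_gamma, dtype=float)


@dataclass
class Gauge:
    """Reference gauge for the pseudodiabatization.

    k_delta = g(q_ref) and k_gamma = h(q_ref); the angle omega is measured in
    the (generally non-orthogonal) frame these two vectors define.
    """

    q_ref: np.ndarray
    k_delta: np.ndarray
    k_gamma: np.ndarray
    #: cached Moore-Penrose inverse of [k_delta k_gamma] (2 x m)
    _pinv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.q_ref = np.asarray(self.q_ref, dtype=float)
        self.k_delta = np.asarray(self.k_delta, dtype=float)
        self.k_gamma = np.asarray(self.k_gamma, dtype=float)
        nd = np.linalg.norm(self.k_delta)
        ng = np.linalg.norm(self.k_gamma)
        if nd < 1e-14 or ng < 1e-14:
            raise DegenerateBranchingPlaneError(
                "gauge vectors k_delta/k_gamma must be nonzero")
        cosang = abs(self.k_delta @ self.k_gamma) / (nd * ng)
        if cosang > 1.0 - 1e-10:
            raise ValueError("k_delta and k_gamma are (anti)parallel")
        self._pinv = np.linalg.pinv(
            np.column_stack([self.k_delta, self.k_gamma]))

    def frame_coordinates(self, v: np.ndarray) -> np.ndarray:
        """Coordinates (c_delta, c_gamma) of an in-plane vector v such that
        v = c_delta*k_delta + c_gamma*k_gamma (least squares if v is not
        exactly in the plane)."""
        return self._pinv @ v


@dataclass
class PlaneRotationResult:
    """g and h rotated minimally into the reference plane.

    ``singular_values`` are the cosines (phi1, phi2) of the principal angles
    between the local {g,h} plane and span{k_delta, k_gamma}; a small product
    phi1*phi2 means the planes are nearly orthogonal and the fitted omega may
    be unreliable (``conditioning_ok`` False).
    """

    g_prime: np.ndarray
    h_prime: np.ndarray
    singular_values: tuple[float, float]
    conditioning_ok: bool


def orth_mgs(a: np.ndarray) -> np.ndarray:
    """Orthonormalize the columns of ``a`` by modified Gram-Schmidt with one
    reorthogonalization pass (deterministic, no sign ambiguity)."""
    a = np.array(a, dtype=float)
    m, n = a.shape
    q = np.zeros((m, n))
    kept = 0
    for j in range(n):
        v = a[:, j].copy()
        for _ in range(2):  # reorthogonalize once for robustness
            for i in range(kept):
                v -= (q[:, i] @ v) * q[:, i]
        nv = np.linalg.norm(v)
        if nv < 1e-13 * max(1.0, np.linalg.norm(a[:, j])):
            raise np.linalg.LinAlgError("rank-deficient columns in orth")
        q[:, kept] = v / nv
        kept += 1
    return q[:, :kept]


def adiabatic_from_diabatic(d: DiabaticPoint) -> AdiabaticPoint:
    """Diagonalize the 2x2 diabatic Hamiltonian at one geometry.

    Returns the adiabatic energies E_A = tau + lambda, E_B = tau - lambda and
    the s, g, h vectors obtained by rotating (grad delta, grad gamma) by the
    local angle omega = atan2(gamma, delta).  At exact degeneracy
    (lambda below tolerance) omega is undefined; the omega -> 0 limit is
    returned and the point flagged degenerate.
    """
    tau = 0.5 * (d.alpha + d.beta)
    delta = 0.5 * (d.alpha - d.beta)
    lam = math.hypot(delta, d.gamma)
    grad_tau = 0.5 * (d.grad_alpha + d.grad_beta)
    grad_delta = 0.5 * (d.grad_alpha - d.grad_beta)
    grad_gamma = d.grad_gamma

    degenerate = lam < DEGENERACY_TOL
    omega = 0.0 if degenerate else math.atan2(d.gamma, delta)
    c, s_ = math.cos(omega), math.sin(omega)
    g = c * grad_delta + s_ * grad_gamma
    h = -s_ * grad_delta + c * grad_gamma
    return AdiabaticPoint(
        q=d.q, E_A=tau + lam, E_B=tau - lam, s=grad_tau, g=g, h=h,
        h_defined=True, degenerate=degenerate)


def minimal_plane_rotation(g: np.ndarray, h: np.ndarray,
                           gauge: Gauge) -> PlaneRotationResult:
    """Rotate {g, h} minimally onto span{k_delta, k_gamma}.

    The rotation is built from the SVD of the 2x2 inner-product matrix
    between orthonormal bases of the two planes; its singular values are the
    cosines of the principal angles.  Vectors already in the reference plane
    are returned unchanged (identity rotation).
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    try:
        gbasis = orth_mgs(np.column_stack([g, h]))
    except np.linalg.LinAlgError as exc:
        raise DegenerateBranchingPlaneError(
            "g and h are parallel: branching plane undefined") from exc
    if gbasis.shape[1] < 2:
        raise DegenerateBranchingPlaneError(
            "g and h are parallel: branching plane undefined")
    kbasis = orth_mgs(np.column_stack([gauge.k_delta, gauge.k_gamma]))

    inner = kbasis.T @ gbasis  # 2x2 inter-plane inner products
    u, sv, vt = np.linalg.svd(inner)
    phi1, phi2 = float(sv[0]), float(sv[1])
    ok = phi1 * phi2 >= CONDITIONING_MIN
    if not ok:
        warnings.warn(
            "branching plane nearly orthogonal to the reference plane "
            f"(phi1*phi2 = {phi1 * phi2:.3g}); fitted omega may be unreliable",
            RuntimeWarning, stacklevel=2)
    # for x in span{g,h}: rotated x = K U V^T (G^T x)
    rot = kbasis @ u @ vt @ gbasis.T
    return PlaneRotationResult(
        g_prime=rot @ g, h_prime=rot @ h,
        singular_values=(phi1, phi2), conditioning_ok=ok)


def circular_mean(x: float, y: float) -> float:
    """Angle equidistant from x and y along the shorter arc.

    Antipodal inputs (arc distance exactly pi) are broken deterministically
    toward x + pi/2.
    """
    d = math.remainder(y - x, TWO_PI)
    if abs(abs(d) - math.pi) < 1e-12:
        return _wrap_angle(x + 0.5 * math.pi)
    return _wrap_angle(x + 0.5 * d)


def fit_omega(pr: PlaneRotationResult, gauge: Gauge) -> tuple[float, float, float]:
    """Best-fit gauge angle from the rotated pair (g', h').

    omega_g is the frame angle of g' in the (k_delta, k_gamma) coordinates
    (Moore-Penrose solve, exact for in-plane vectors); omega_h is the frame
    angle of h' shifted by -pi/2, so that both estimate the same omega (in the
    reference gauge g' ~ k_delta, h' ~ k_gamma give omega_g = omega_h = 0).
    The returned omega is the circular mean of the two estimates, after
    rotating omega_h by pi when the raw estimates disagree by more than pi/2
    (the h-sign ambiguity; see :func:`resolve_h_sign`).

    Returns (omega, omega_g, omega_h_raw).
    """
    cg = gauge.frame_coordinates(pr.g_prime)
    ch = gauge.frame_coordinates(pr.h_prime)
    if np.linalg.norm(cg) < 1e-14 or np.linalg.norm(ch) < 1e-14:
        raise DegenerateBranchingPlaneError(
            "zero-length g' or h' in the reference frame")
    omega_g = math.atan2(cg[1], cg[0])
    omega_h = _wrap_angle(math.atan2(ch[1], ch[0]) - 0.5 * math.pi)
    omega_h_eff = (_wrap_angle(omega_h + math.pi)
                   if _circ_dist(omega_g, omega_h) > 0.5 * math.pi
                   else omega_h)
    return circular_mean(omega_g, omega_h_eff), omega_g, omega_h


def resolve_h_sign(omega_g: float, omega_h: float,
                   h: np.ndarray) -> tuple[np.ndarray, bool]:
    """Fix the arbitrary electronic-structure phase of h.

    If the two angle estimates differ by more than pi/2, h is replaced by -h
    (which shifts omega_h by pi, bringing the estimates into agreement).
    Applying the rule twice is the identity.
    """
    flipped = _circ_dist(omega_g, omega_h) > 0.5 * math.pi
    return (-h if flipped else np.asarray(h, dtype=float).copy()), flipped


def diabatize_point(p: AdiabaticPoint, gauge: Gauge) -> DiabaticPoint:
    """Gauge-fixed diabatization of a single adiabatic point.

    With lambda = (E_A - E_B)/2 and the fitted omega:

        delta = lambda cos(omega),  gamma = lambda sin(omega)
        grad delta = cos(omega) g - sin(omega) h
        grad gamma = sin(omega) g + cos(omega) h
        alpha = tau + delta, beta = tau - delta, grad tau = s

    The round trip through :func:`adiabatic_from_diabatic` reproduces
    (E_A, E_B, s, g, +/-h) exactly.
    """
    if not p.h_defined:
        raise ValueError("cannot diabatize a point without a coupling vector "
                         "(spin mode needs no diabatization)")
    ng, nh = np.linalg.norm(p.g), np.linalg.norm(p.h)
    if ng < 1e-14 or nh < 1e-14:
        if np.allclose(p.q, gauge.q_ref):
            raise DegenerateBranchingPlaneError(
                "reference point has a vanishing g or h")
        raise DegenerateBranchingPlaneError(
            "degenerate point with undefined branching plane")

    pr = minimal_plane_rotation(p.g, p.h, gauge)
    omega, omega_g, omega_h = fit_omega(pr, gauge)
    h_use, flipped = resolve_h_sign(omega_g, omega_h, p.h)

    lam = 0.5 * (p.E_A - p.E_B)
    tau = 0.5 * (p.E_A + p.E_B)
    c, s_ = math.cos(omega), math.sin(omega)
    delta = lam * c
    gamma = lam * s_
    grad_delta = c * p.g - s_ * h_use
    grad_gamma = s_ * p.g + c * h_use
    return DiabaticPoint(
        q=p.q, alpha=tau + delta, beta=tau - delta, gamma=gamma,
        grad_alpha=p.s + grad_delta, grad_beta=p.s - grad_delta,
        grad_gamma=grad_gamma, omega=omega, h_flipped=flipped)


def diabatize_history(points: list[AdiabaticPoint],
                      mode: str = "ci") -> tuple[list[DiabaticPoint], Gauge | None]:
    """Diabatize an optimization history against a gauge built from its last point.

    In ``ci`` mode the latest structure is the reference: k_delta = g(q_ref),
    k_gamma = h(q_ref), and every point is diabatized against that gauge.  In
    ``spin`` mode (different multiplicities) gamma is identically zero, so
    alpha = E_A, beta = E_B directly, with no gauge.
    """
    if not points:
        raise ValueError("empty history")
    if mode == "spin":
        out = []
        for p in points:
            zeros = np.zeros_like(p.q)
            out.append(DiabaticPoint(
                q=p.q, alpha=p.E_A, beta=p.E_B, gamma=0.0,
                grad_alpha=p.s + p.g, grad_beta=p.s - p.g,
                grad_gamma=zeros, omega=0.0, h_flipped=False))
        return out, None
    if mode != "ci":
        raise ValueError(f"unknown mode {mode!r}")
    ref = points[-1]
    if not ref.h_defined:
        raise ValueError("ci mode requires a coupling vector at the reference")
    if np.linalg.norm(ref.g) < 1e-14:
        raise DegenerateBranchingPlaneError(
            "reference point has a vanishing gradient difference g")
    gauge = Gauge(q_ref=ref.q, k_delta=ref.g, k_gamma=ref.h)
    return [diabatize_point(p, gauge) for p in points], gauge
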