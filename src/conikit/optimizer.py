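"""Restricted-variance optimization (RVO) of minimum-energy crossing points.

One *macroiteration* = one backend (electronic-structure or analytic model)
evaluation, a rebuild of the pseudodiabatic surrogate from the accumulated
history, and a sequence of *microiterations* on the surrogate.  Each
microiteration takes a projected constrained step:

* the constrained subspace is spanned by the branching-plane vectors — g and
  h for a conical intersection (the gap 2*sqrt(delta^2+gamma^2) vanishes only
  where both delta and gamma do), g alone for a spin crossing — and receives
  a first-order Newton restoration driving the gap to zero;
* the complementary subspace minimizes the average energy with a rational
  function (RFO) step under a trust radius, using a finite-difference Hessian
  of the surrogate's average-energy surface (the surrogate is analytic, so
  this is cheap and accurate).

Microiterations stop at surrogate stationarity, at the iteration cap, or —
the restricted-variance rule — when the surrogate's predicted variance
exceeds the configured limit, in which case the step is shortened by
bisection back onto the variance boundary.  The resulting geometry is handed
to the backend, completing the macroiteration.

Cartesian geometries of molecules carry six redundant rigid-body degrees of
freedom; with ``project_rigid`` enabled the translational/rotational modes
are projected out of gradients and steps (Eckart-style), so the optimization
is invariant under rigid motions of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .diabatization import AdiabaticPoint
from .gek import lengths_from_hessian
from .surrogate import PseudodiabaticSurrogate, build_surrogate, evaluate_adiabatic

__all__ = [
    "OptConfig",
    "OptState",
    "BackendError",
    "projected_constrained_step",
    "microiterate",
    "check_convergence",
    "optimize_mecp",
    "rigid_mode_projector",
]


class BackendError(RuntimeError):
    """Backend failure; carries the offending geometry."""

    def __init__(self, message: str, q: np.ndarray):
        super().__init__(message)
        self.q = np.asarray(q, dtype=float)


@dataclass
class OptConfig:
    """Optimization thresholds and model hyperparameters.

    Convergence follows the conventional quantum-chemistry defaults: rms
    step 1.2e-3 a0 and rms gradient 3.0e-4 E_h/a0, maximum components 1.5x
    those, plus the crossing condition |E_A - E_B| <= 1e-5 E_h.  The
    variance limit is expressed through the 95% confidence half-width
    1.96*sigma of the (unit-prior-variance) GEK prediction.
    """

    mode: str = "ci"
    conv_rms_step: float = 1.2e-3          # bohr
    conv_rms_grad: float = 3.0e-4          # hartree/bohr
    conv_max_factor: float = 1.5
    conv_ediff: float = 1.0e-5             # hartree
    max_macro: int = 50
    max_micro: int = 100
    #: largest allowed 95% half-width (1.96 sigma) of any surface prediction
    confidence_halfwidth: float = 0.3
    trust_radius_init: float = 0.3         # bohr
    hessian_diag: np.ndarray | None = None  # approximate Hessian for lengths
    mu_offset: float = 10.0                # baseline above data max (hartree)
    nugget: float = 1e-12
    #: microiteration thresholds = macro thresholds times this factor, so a
    #: macroiteration lands essentially on the surrogate's stationary point
    micro_factor: float = 1e-2
    #: data selection for surrogate conditioning: minimum pairwise distance
    #: in kernel-scaled coordinates, and maximum number of retained points
    min_scaled_spacing: float = 1e-3
    max_data_points: int = 20
    project_rigid: bool = False

    def __post_init__(self) -> None:
        for name in ("conv_rms_step", "conv_rms_grad", "conv_max_factor",
                     "conv_ediff", "confidence_halfwidth",
                     "trust_radius_init", "micro_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def variance_limit(self) -> float:
        return (self.confidence_halfwidth / 1.96) ** 2


@dataclass
class OptState:
    """Full record of one optimization run (one trace entry per macro)."""

    history: list[AdiabaticPoint] = field(default_factory=list)
    q: np.ndarray | None = None
    converged: bool = False
    trace: list[dict] = field(default_factory=list)

    @property
    def macroiterations(self) -> int:
        return len(self.trace)


def rigid_mode_projector(q: np.ndarray) -> np.ndarray:
    """Projector onto the complement of rigid translations/rotations.

    ``q`` is a flattened 3N Cartesian geometry (bohr).  Rotational modes that
    vanish (linear molecules, single atoms) are dropped automatically.
    """
    q = np.asarray(q, dtype=float)
    if q.size % 3 != 0:
        raise ValueError("rigid-mode projection needs 3N coordinates")
    coords = q.reshape(-1, 3)
    nat = coords.shape[0]
    com = coords.mean(axis=0)
    rel = coords - com
    modes = []
    for k in range(3):  # translations
        t = np.zeros((nat, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for k in range(3):  # infinitesimal rotations about the axes
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(np.broadcast_to(axis, rel.shape), rel).ravel())
    basis = []
    for v in modes:
        for b in basis:
            v = v - (b @ v) * b
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            basis.append(v / nv)
    proj = np.eye(q.size)
    for b in basis:
        proj -= np.outer(b, b)
    return proj


def _complement_basis(constrained: list[np.ndarray], m: int,
                      projector: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of the subspace orthogonal to the constrained
    directions (and, optionally, inside the range of ``projector``)."""
    cols = []
    span: list[np.ndarray] = []  # orthonormalized constrained directions
    for c in constrained:
        c = c.astype(float).copy()
        for b in span:
            c = c - (b @ c) * b
        nc = np.linalg.norm(c)
        if nc > 1e-12:
            span.append(c / nc)
    eye = np.eye(m)
    for k in range(m):
        v = eye[:, k] if projector is None else projector[:, k]
        for c in span:
            v = v - (c @ v) * c
        for b in cols:
            v = v - (b @ v) * b
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            cols.append(v / nv)
    return np.column_stack(cols) if cols else np.zeros((m, 0))


def _rfo_step(hess: np.ndarray, grad: np.ndarray, trust: float) -> np.ndarray:
    """Restricted-step rational function minimization step."""
    k = grad.size
    if k == 0:
        return grad
    aug = np.zeros((k + 1, k + 1))
    aug[:k, :k] = hess
    aug[:k, k] = grad
    aug[k, :k] = grad
    evals, evecs = np.linalg.eigh(aug)
    v = evecs[:, 0]
    if abs(v[k]) < 1e-12:
        nv = np.linalg.norm(grad)
        step = -grad / nv * trust if nv > 0 else np.zeros(k)
    else:
        step = v[:k] / v[k]
    nstep = np.linalg.norm(step)
    if nstep > trust:
        step *= trust / nstep
    return step


def projected_constrained_step(E_A: float, E_B: float, s: np.ndarray,
                               g: np.ndarray, approx_hessian: np.ndarray,
                               trust: float, h: np.ndarray | None = None,
                               projector: np.ndarray | None = None) -> np.ndarray:
    """One projected constrained optimization (PCO) step.

    The constrained subspace is span{g} (spin crossings) or span{g, h}
    (conical intersections, where the coupling must also be annihilated); it
    receives the minimum-norm Newton step restoring the degeneracy to first
    order.  The complement minimizes the average energy via an RFO step with
    ``approx_hessian``.  The total step norm never exceeds ``trust``.
    """
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    m = s.size
    ng = np.linalg.norm(g)
    if ng < 1e-14:
        raise ValueError("zero gradient-difference vector: "
                         "degenerate branching plane")
    lam = 0.5 * (E_A - E_B)

    constrained = [g]
    if h is not None and np.linalg.norm(h) > 1e-14:
        constrained.append(np.asarray(h, dtype=float))
    # local linearization: lambda + g.dq = 0 (and, for a CI, 0 + h.dq = 0);
    # minimum-norm solution inside the constrained span
    amat = np.column_stack(constrained)
    rhs = np.zeros(len(constrained))
    rhs[0] = -lam
    coef, *_ = np.linalg.lstsq(amat.T @ amat, rhs, rcond=None)
    step_c = amat @ coef
    nc = np.linalg.norm(step_c)
    if nc > trust:
        step_c *= trust / nc

    basis = _complement_basis(constrained, m, projector)
    if basis.shape[1] > 0:
        grad_b = basis.T @ s
        hess_b = basis.T @ approx_hessian @ basis
        step_m = basis @ _rfo_step(hess_b, grad_b, trust)
    else:
        step_m = np.zeros(m)

    step = step_c + step_m
    nstep = np.linalg.norm(step)
    if nstep > trust:
        step *= trust / nstep
    return step


def _fd_hessian_tau(surrogate: PseudodiabaticSurrogate, q: np.ndarray,
                    step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of the surrogate's average energy (the
    average gradient s is smooth through the seam, so this is well-defined
    everywhere)."""
    m = q.size
    hess = np.empty((m, m))
    for k in range(m):
        e = np.zeros(m)
        e[k] = step
        sp = evaluate_adiabatic(surrogate, q + e)[0].s
        sm = evaluate_adiabatic(surrogate, q - e)[0].s
        hess[:, k] = (sp - sm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


def _projected_grad(p: AdiabaticPoint, mode: str,
                    projector: np.ndarray | None) -> np.ndarray:
    """Average gradient with the constrained (and rigid) directions removed."""
    dirs = [p.g]
    if mode == "ci" and p.h_defined:
        dirs.append(p.h)
    v = p.s if projector is None else projector @ p.s
    span = []
    for c in dirs:
        c = c if projector is None else projector @ c
        for b in span:
            c = c - (b @ c) * b
        nc = np.linalg.norm(c)
        if nc > 1e-12:
            span.append(c / nc)
    for b in span:
        v = v - (b @ v) * b
    return v


def microiterate(surrogate: PseudodiabaticSurrogate, q_start: np.ndarray,
                 config: OptConfig) -> tuple[np.ndarray, str]:
    """Walk the surrogate to a constrained stationary point.

    Stops with reason ``stationary`` (surrogate gap and projected gradient
    below the tightened thresholds), ``variance`` (the predicted variance
    exceeded the limit; the step is bisected back onto the boundary) or
    ``max_iter``.  The returned geometry always satisfies
    variance <= variance_limit.
    """
    q = np.asarray(q_start, dtype=float).copy()
    m = q.size
    gtol = config.conv_rms_grad * config.micro_factor
    etol = config.conv_ediff * config.micro_factor
    stol = config.conv_rms_step * config.micro_factor
    limit = config.variance_limit
    projector = rigid_mode_projector(q) if config.project_rigid else None

    for _ in range(config.max_micro):
        p, _var = evaluate_adiabatic(surrogate, q)
        grad_p = _projected_grad(p, surrogate.mode, projector)
        ediff = abs(p.E_A - p.E_B)
        if (np.linalg.norm(grad_p) / math.sqrt(m) <= gtol
                and ediff <= etol):
            return q, "stationary"
        hess = _fd_hessian_tau(surrogate, q)
        step = projected_constrained_step(
            p.E_A, p.E_B, p.s, p.g, hess, config.trust_radius_init,
            h=p.h if surrogate.mode == "ci" else None, projector=projector)
        q_new = q + step
        last = np.linalg.norm(step) / math.sqrt(m) <= stol
        _, var_new = evaluate_adiabatic(surrogate, q_new)
        if last and var_new <= limit:
            # the walk has essentially landed; apply the final small step
            return q_new, "stationary"
        if var_new > limit:
            lo, hi = 0.0, 1.0
            for _b in range(60):
                mid = 0.5 * (lo + hi)
                if evaluate_adiabatic(surrogate, q + mid * step)[1] <= limit:
                    lo = mid
                else:
                    hi = mid
            return q + lo * step, "variance"
        q = q_new
    return q, "max_iter"


def check_convergence(state: OptState, config: OptConfig) -> bool:
    """Converged iff the last macro step, the projected gradient and the
    energy gap are all at or below their thresholds (max components within
    ``conv_max_factor`` times the rms thresholds)."""
    if len(state.history) < 2:
        return False
    p_prev, p = state.history[-2], state.history[-1]
    step = p.q - p_prev.q
    m = p.q.size
    projector = rigid_mode_projector(p.q) if config.project_rigid else None
    grad_p = _projected_grad(p, config.mode, projector)
    rms_step = np.linalg.norm(step) / math.sqrt(m)
    rms_grad = np.linalg.norm(grad_p) / math.sqrt(m)
    fac = config.conv_max_factor
    return (rms_step <= config.conv_rms_step
            and np.abs(step).max() <= fac * config.conv_rms_step
            and rms_grad <= config.conv_rms_grad
            and np.abs(grad_p).max() <= fac * config.conv_rms_grad
            and abs(p.E_A - p.E_B) <= config.conv_ediff)


def _select_data(history: list[AdiabaticPoint], lengths: np.ndarray,
                 config: OptConfig) -> list[AdiabaticPoint]:
    """Prune near-coincident geometries for surrogate conditioning.

    Scans newest to oldest, always keeping the newest point (the gauge
    reference), dropping any point closer than ``min_scaled_spacing`` (in
    kernel-scaled coordinates) to one already kept, and capping the count.
    Chronological order is preserved in the result.
    """
    kept: list[AdiabaticPoint] = []
    for p in reversed(history):
        qs = p.q / lengths
        if all(np.linalg.norm(qs - k.q / lengths) > config.min_scaled_spacing
               for k in kept):
            kept.append(p)
        if len(kept) >= config.max_data_points:
            break
    return list(reversed(kept))


def optimize_mecp(backend: Callable[[np.ndarray], AdiabaticPoint],
                  q0: np.ndarray, config: OptConfig) -> OptState:
    """Macro loop: backend evaluation, surrogate rebuild, microiterations.

    Non-convergence within ``max_macro`` returns ``converged = False`` with
    the full trace (no exception); backend failures raise
    :class:`BackendError` carrying the offending geometry.
    """
    q = np.asarray(q0, dtype=float).copy()
    m = q.size
    hdiag = (np.full(m, 1.0) if config.hessian_diag is None
             else np.broadcast_to(np.asarray(config.hessian_diag, dtype=float),
                                  (m,)).copy())
    lengths = lengths_from_hessian(hdiag, mu_offset=config.mu_offset)
    state = OptState()

    for macro in range(config.max_macro):
        try:
            p = backend(q)
        except Exception as exc:
            raise BackendError(f"backend failed at macroiteration {macro}: "
                               f"{exc}", q) from exc
        state.history.append(p)
        prev_q = state.history[-2].q if len(state.history) > 1 else None
        rec = {
            "macro": macro,
            "q": q.tolist(),
            "E_A": p.E_A,
            "E_B": p.E_B,
            "ediff": abs(p.E_A - p.E_B),
            "step_norm": (float(np.linalg.norm(q - prev_q))
                          if prev_q is not None else 0.0),
        }
        state.trace.append(rec)
        state.q = q
        if check_convergence(state, config):
            state.converged = True
            rec["converged"] = True
            break
        rec["converged"] = False

        data = _select_data(state.history, lengths, config)
        surrogate = build_surrogate(data, config.mode, lengths,
                                    nugget=config.nugget,
                                    mu_offset=config.mu_offset)
        q_new, reason = microiterate(surrogate, q, config)
        _, var_acc = evaluate_adiabatic(surrogate, q_new)
        rec["stop_reason"] = reason
        rec["variance_accepted"] = var_acc
        if np.linalg.norm(q_new - q) < 1e-13:
            # surrogate (exact at this data point) is stationary here: the
            # remaining step is identically zero, so judge convergence on
            # the gradient and gap criteria alone
            projector = (rigid_mode_projector(p.q) if config.project_rigid
                         else None)
            grad_p = _projected_grad(p, config.mode, projector)
            fac = config.conv_max_factor
            state.converged = (
                np.linalg.norm(grad_p) / math.sqrt(m) <= config.conv_rms_grad
                and (grad_p.size == 0
                     or np.abs(grad_p).max() <= fac * config.conv_rms_grad)
                and abs(p.E_A - p.E_B) <= config.conv_ediff)
            rec["converged"] = state.converged
            break
        q = q_new
    return state
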