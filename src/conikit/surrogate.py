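"""Assembly and evaluation of the pseudodiabatic surrogate model.

The surrogate is three independent GEK surfaces fitted to the gauge-fixed
diabatic data (alpha, beta, gamma and their gradients) of an optimization
history — or two surfaces in spin mode, where gamma vanishes identically.
Each surface is smooth and differentiable everywhere; the adiabatic energies
recover their conical (non-differentiable) topography only after
diagonalizing the 2x2 Hamiltonian assembled from the predictions.

Baseline policy: the alpha and beta trends sit a fixed offset (10 hartree by
default) above the maximum of their respective training values, which keeps
the surfaces repulsive away from the data; the gamma surface uses mu = 0 so
the coupling decays to zero far from the data.  All surfaces share one set of
characteristic lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .diabatization import (AdiabaticPoint, DiabaticPoint, Gauge,
                            adiabatic_from_diabatic, diabatize_history)
from .gek import GekDataset, GekSurface, fit_gek, predict

__all__ = ["PseudodiabaticSurrogate", "build_surrogate", "evaluate_adiabatic",
           "surrogate_to_json", "surrogate_from_json"]

MU_OFFSET_DEFAULT = 10.0  # hartree above the data maximum, for alpha and beta


@dataclass
class PseudodiabaticSurrogate:
    """Three (CI) or two (spin) GEK surfaces plus the reference gauge."""

    mode: str
    surf_alpha: GekSurface
    surf_beta: GekSurface
    surf_gamma: GekSurface | None
    gauge: Gauge | None
    lengths: np.ndarray
    diabatic_points: list[DiabaticPoint]

    @property
    def mu_policy(self) -> dict[str, float]:
        out = {"alpha": self.surf_alpha.mu, "beta": self.surf_beta.mu}
        if self.surf_gamma is not None:
            out["gamma"] = self.surf_gamma.mu
        return out


def build_surrogate(history: list[AdiabaticPoint], mode: str,
                    lengths: np.ndarray, nugget: float = 1e-12,
                    mu_offset: float = MU_OFFSET_DEFAULT) -> PseudodiabaticSurrogate:
    """Diabatize a history (gauge from its last point) and fit the surfaces.

    By the exact-interpolation property of GEK plus the round-trip property
    of the diabatization, the assembled surrogate reproduces every history
    point's E_A, E_B, s, g and h (the latter up to the recorded sign flip).
    """
    lengths = np.asarray(lengths, dtype=float)
    dpoints, gauge = diabatize_history(history, mode)

    def fit(values_grads, mu):
        ds = GekDataset([(d.q, v, g) for d, (v, g) in zip(dpoints, values_grads)])
        return fit_gek(ds, mu=mu, lengths=lengths, nugget=nugget)

    alphas = [(d.alpha, d.grad_alpha) for d in dpoints]
    betas = [(d.beta, d.grad_beta) for d in dpoints]
    surf_a = fit(alphas, mu=max(v for v, _ in alphas) + mu_offset)
    surf_b = fit(betas, mu=max(v for v, _ in betas) + mu_offset)
    surf_g = None
    if mode == "ci":
        surf_g = fit([(d.gamma, d.grad_gamma) for d in dpoints], mu=0.0)
    return PseudodiabaticSurrogate(
        mode=mode, surf_alpha=surf_a, surf_beta=surf_b, surf_gamma=surf_g,
        gauge=gauge, lengths=lengths, diabatic_points=dpoints)


def evaluate_adiabatic(surrogate: PseudodiabaticSurrogate,
                       q: np.ndarray) -> tuple[AdiabaticPoint, float]:
    """Predict the diabats at q and diagonalize.

    Returns the adiabatic point and the largest predicted variance among the
    component surfaces (the quantity the optimizer uses to restrict steps).
    In spin mode no diagonalization is performed: E_A = alpha, E_B = beta
    (the surfaces may cross) and h is undefined.
    """
    q = np.asarray(q, dtype=float)
    a, ga, va = predict(surrogate.surf_alpha, q)
    b, gb, vb = predict(surrogate.surf_beta, q)
    if surrogate.mode == "spin":
        return AdiabaticPoint(
            q=q, E_A=a, E_B=b, s=0.5 * (ga + gb), g=0.5 * (ga - gb),
            h=np.zeros(q.size), h_defined=False,
            degenerate=abs(a - b) < 2e-9), max(va, vb)
    c, gc, vc = predict(surrogate.surf_gamma, q)
    d = DiabaticPoint(q=q, alpha=a, beta=b, gamma=c, grad_alpha=ga,
                      grad_beta=gb, grad_gamma=gc)
    return adiabatic_from_diabatic(d), max(va, vb, vc)


# --- debugging / plotting snapshot -------------------------------------------

def surrogate_to_json(surrogate: PseudodiabaticSurrogate) -> str:
    """Serialize a surrogate snapshot (geometries, diabatic data, weights,
    gauge) to a JSON string."""

    def surf(s: GekSurface | None):
        if s is None:
            return None
        return {
            "mu": s.mu,
            "nugget": s.nugget,
            "points": [{"q": q.tolist(), "value": v, "gradient": g.tolist()}
                       for q, v, g in s.dataset.points],
            "weights": s.weights.tolist(),
        }

    gauge = surrogate.gauge
    doc = {
        "mode": surrogate.mode,
        "lengths": surrogate.lengths.tolist(),
        "gauge": None if gauge is None else {
            "q_ref": gauge.q_ref.tolist(),
            "k_delta": gauge.k_delta.tolist(),
            "k_gamma": gauge.k_gamma.tolist(),
        },
        "surfaces": {"alpha": surf(surrogate.surf_alpha),
                     "beta": surf(surrogate.surf_beta),
                     "gamma": surf(surrogate.surf_gamma)},
        "diabatic_points": [{
            "q": d.q.tolist(), "alpha": d.alpha, "beta": d.beta,
            "gamma": d.gamma, "omega": d.omega, "h_flipped": d.h_flipped,
            "grad_alpha": d.grad_alpha.tolist(),
            "grad_beta": d.grad_beta.tolist(),
            "grad_gamma": d.grad_gamma.tolist(),
        } for d in surrogate.diabatic_points],
    }
    return json.dumps(doc, indent=2)


def surrogate_from_json(text: str) -> PseudodiabaticSurrogate:
    """Rebuild a surrogate from a snapshot (weights re-solved from the data,
    so the reconstruction is exact up to the nugget)."""
    doc = json.loads(text)
    lengths = np.asarray(doc["lengths"], dtype=float)

    def refit(sd):
        if sd is None:
            return None
        ds = GekDataset([(np.asarray(p["q"]), p["value"],
                          np.asarray(p["gradient"])) for p in sd["points"]])
        return fit_gek(ds, mu=sd["mu"], lengths=lengths, nugget=sd["nugget"])

    gauge = None
    if doc["gauge"] is not None:
        gauge = Gauge(q_ref=np.asarray(doc["gauge"]["q_ref"]),
                      k_delta=np.asarray(doc["gauge"]["k_delta"]),
                      k_gamma=np.asarray(doc["gauge"]["k_gamma"]))
    dpoints = [DiabaticPoint(
        q=np.asarray(rec["q"]), alpha=rec["alpha"], beta=rec["beta"],
        gamma=rec["gamma"], grad_alpha=np.asarray(rec["grad_alpha"]),
        grad_beta=np.asarray(rec["grad_beta"]),
        grad_gamma=np.asarray(rec["grad_gamma"]), omega=rec["omega"],
        h_flipped=rec["h_flipped"]) for rec in doc["diabatic_points"]]
    return PseudodiabaticSurrogate(
        mode=doc["mode"], surf_alpha=refit(doc["surfaces"]["alpha"]),
        surf_beta=refit(doc["surfaces"]["beta"]),
        surf_gamma=refit(doc["surfaces"]["gamma"]), gauge=gauge,
        lengths=lengths, diabatic_points=dpoints)
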