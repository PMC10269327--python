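"""Gradient-enhanced Kriging on a 2-D test function.

Fits a GEK surface (Matérn-5/2 kernel, energies + gradients as data) to five
samples of a quartic function and reports interpolation exactness at the
data, the off-data error, and the predicted-variance behavior that the
optimizer uses to restrict its steps.
"""

import numpy as np

from conikit.gek import GekDataset, fit_gek, lengths_from_hessian, predict

rng = np.random.default_rng(3)


def f(q):
    return float(q[0] ** 4 + q[1] ** 2 + 0.3 * q[0] * q[1])


def fg(q):
    return np.array([4 * q[0] ** 3 + 0.3 * q[1], 2 * q[1] + 0.3 * q[0]])


pts = [rng.uniform(-1, 1, 2) for _ in range(5)]
lengths = lengths_from_hessian(np.array([1.0, 1.0]))
mu = max(f(q) for q in pts) + 10.0
surf = fit_gek(GekDataset([(q, f(q), fg(q)) for q in pts]), mu=mu,
               lengths=lengths)

print(f"characteristic lengths: {np.round(lengths, 3)} bohr "
      "(calibrated to a unit Hessian)")
err_data = max(abs(predict(surf, q)[0] - f(q)) for q in pts)
print(f"max |error| at the 5 data points: {err_data:.2e}  (exact interpolation)")

test = [rng.uniform(-0.8, 0.8, 2) for _ in range(50)]
rms = np.sqrt(np.mean([(predict(surf, q)[0] - f(q)) ** 2 for q in test]))
print(f"rms error at 50 off-data points: {rms:.3e}")

for dist in (0.0, 0.5, 2.0, 20.0):
    q = pts[0] + dist * np.array([1.0, 0.3]) / np.hypot(1.0, 0.3)
    _, _, var = predict(surf, q)
    print(f"predicted variance {dist:5.1f} bohr from a data point: {var:.3e}")
print("\nVariance is ~0 at the data and approaches the unit prior variance")
print("far away: the optimizer walks only where the model is trustworthy.")
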