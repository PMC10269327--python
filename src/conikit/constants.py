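"""Physical constants and shared numerical tolerances.

All internal quantities are in atomic units: bohr (a0) for geometries,
hartree (E_h) for energies.  XYZ files use angstrom, per convention.
"""

#: CODATA bohr radius in angstrom (files use angstrom, internals use bohr).
BOHR_PER_ANGSTROM = 1.8897259886

#: Energy half-gaps below this (hartree) are treated as exact degeneracy;
#: atan2(gamma, delta) is undefined there and the mixing angle is taken as 0.
DEGENERACY_TOL = 1e-9

#: Minimum product of principal-angle cosines (phi1*phi2) between the local
#: {g, h} plane and the reference {k_delta, k_gamma} plane before the plane
#: rotation is flagged as poorly conditioned.
CONDITIONING_MIN = 0.1
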