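"""Minimal standard-XYZ reader/writer.

Files follow the usual dialect — atom count line, free-form comment line,
then ``element x y z`` records in angstrom.  Internally coordinates are kept
in bohr, the unit every other part of the package works in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import BOHR_PER_ANGSTROM

__all__ = ["Structure", "XyzFormatError", "read_xyz", "write_xyz"]


class XyzFormatError(ValueError):
    """Malformed XYZ file; message names the offending line."""


@dataclass
class Structure:
    """Element symbols plus an N x 3 coordinate matrix in bohr."""

    symbols: list[str]
    coordinates: np.ndarray  # bohr
    comment: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates,
                                      dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coordinates.shape[0]:
            raise ValueError("symbol count does not match coordinate rows")

    def flat(self) -> np.ndarray:
        """Flattened 3N coordinate vector (bohr) for the optimizer."""
        return self.coordinates.ravel().copy()


def read_xyz(path) -> Structure:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XyzFormatError(f"{path}: empty file")
    try:
        natoms = int(lines[0].strip())
    except ValueError as exc:
        raise XyzFormatError(f"{path}, line 1: expected an atom count, "
                             f"got {lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise XyzFormatError(
            f"{path}, line 1: count line promises {natoms} atoms but only "
            f"{max(0, len(lines) - 2)} coordinate lines follow")
    symbols, coords = [], []
    for i in range(natoms):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise XyzFormatError(f"{path}, line {lineno}: expected "
                                 f"'element x y z', got {lines[i + 2]!r}")
        try:
            xyz = [float(x) for x in parts[1:4]]
        except ValueError as exc:
            raise XyzFormatError(f"{path}, line {lineno}: bad coordinate "
                                 f"in {lines[i + 2]!r}") from exc
        symbols.append(parts[0])
        coords.append(xyz)
    coords_arr = (np.asarray(coords, dtype=float).reshape(-1, 3)
                  * BOHR_PER_ANGSTROM)
    return Structure(symbols=symbols, coordinates=coords_arr,
                     comment=lines[1] if len(lines) > 1 else "")


def write_xyz(structure: Structure, path) -> None:
    """Write standard XYZ (angstrom, 12 decimal places, deterministic)."""
    ang = structure.coordinates / BOHR_PER_ANGSTROM
    out = [str(len(structure.symbols)), structure.comment]
    for sym, row in zip(structure.symbols, ang):
        out.append(f"{sym:<4s} {row[0]:20.12f} {row[1]:20.12f} {row[2]:20.12f}")
    Path(path).write_text("\n".join(out) + "\n")
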