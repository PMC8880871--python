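"""Bonded harmonic forces.

Each bond contributes U = ½ k (r − r0)² with r the pair separation; forces
are equal and opposite along the pair axis, so the total force over all
particles is identically zero (momentum conservation).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..errors import DegenerateGeometryError
from .system import ToySystem


def bonded_forces(system: ToySystem) -> Tuple[np.ndarray, float]:
    """Per-particle force vectors and the total bonded potential energy.

    Raises :class:`DegenerateGeometryError` for a coincident bonded pair
    (the restoring direction is undefined at r = 0).
    """
    x = np.asarray(system.positions, float)
    forces = np.zeros_like(x)
    potential = 0.0
    for b in system.bonds:
        rvec = x[b.j] - x[b.i]
        r = float(np.linalg.norm(rvec))
        if r == 0.0:
            raise DegenerateGeometryError(
                f"bond ({b.i}, {b.j}): coincident particles"
            )
        stretch = r - b.r0
        u = rvec / r
        f = b.k * stretch * u       # force on i, toward j when stretched
        forces[b.i] += f
        forces[b.j] -= f
        potential += 0.5 * b.k * stretch * stretch
    return forces, potential


def pair_distance(positions: np.ndarray, i: int, j: int) -> float:
    d = float(np.linalg.norm(np.asarray(positions)[j] - np.asarray(positions)[i]))
    if d == 0.0:
        raise DegenerateGeometryError(f"pair ({i}, {j}): coincident particles")
    return d
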