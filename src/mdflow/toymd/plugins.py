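"""The runtime extension contract: custom code inside the integration loop.

A plugin is bound to one particle pair and sees only the positions of that
pair (the restraint use case).  Two hooks:

* ``force(step, r_i, r_j)`` — pure, returns the force on *i* (the force on
  *j* is the negative); evaluated at **both** force evaluations of a velocity
  Verlet step, so it must be a function of positions only;
* ``on_step(step, r_i, r_j, resources)`` — once per completed step; may call
  ``resources.ensemble_reduce(value)`` (a barrier across an in-flight
  coupled ensemble, returning the member-mean identically to every member)
  and ``resources.signal_stop(scope)`` with scope ``"member"`` or
  ``"ensemble"``.  Stops take effect at the next step boundary.

:class:`RestraintPlugin` is the declarative harmonic flat-target form used
by restrained-ensemble workflows; arbitrary code subclasses
:class:`PairPlugin` directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, Optional, Tuple

import numpy as np

from ..errors import InvariantViolationError

MEMBER = "member"
ENSEMBLE = "ensemble"


class PairPlugin:
    """Base class: user code executed during the MD integration loop."""

    pair: Tuple[int, int] = (0, 1)

    def bind(self, n_particles: int) -> None:
        i, j = self.pair
        if i == j or not (0 <= i < n_particles) or not (0 <= j < n_particles):
            raise InvariantViolationError(
                f"plugin pair {self.pair} invalid for {n_particles} particles"
            )

    def force(self, step: int, r_i: np.ndarray, r_j: np.ndarray) -> np.ndarray:
        """Force contribution on particle i (j receives the negative)."""
        return np.zeros(3)

    def potential(self, r_i: np.ndarray, r_j: np.ndarray) -> float:
        return 0.0

    def on_step(self, step: int, r_i: np.ndarray, r_j: np.ndarray,
                resources) -> None:
        """Per-step control hook: reduce, signal stop, record state."""


@dataclass
class RestraintPlugin(PairPlugin):
    """Harmonic pair restraint with optional stop signal and ensemble reduce.

    Force magnitude k_restraint·(d − target) restoring the pair separation
    toward *target*.  With ``stop_tolerance > 0`` the plugin signals a stop
    (of ``stop_scope``) once |d − target| < stop_tolerance.  With
    ``reduce_mode="mean_distance"`` the plugin contributes its distance to an
    ensemble mean every output interval (a barrier in coupled ensembles).
    """

    pair: Tuple[int, int] = (0, 1)
    k_restraint: float = 1.0
    target: float = 1.0
    stop_tolerance: float = 0.0      # 0 disables stopping
    stop_scope: str = MEMBER
    reduce_mode: str = "none"        # "none" | "mean_distance"

    def __post_init__(self):
        if self.k_restraint < 0:
            raise InvariantViolationError("k_restraint must be >= 0")
        if not self.target > 0:
            raise InvariantViolationError("target must be > 0")
        if self.stop_tolerance < 0:
            raise InvariantViolationError("stop_tolerance must be >= 0")
        if self.stop_scope not in (MEMBER, ENSEMBLE):
            raise InvariantViolationError(f"unknown stop scope {self.stop_scope!r}")
        if self.reduce_mode not in ("none", "mean_distance"):
            raise InvariantViolationError(f"unknown reduce mode {self.reduce_mode!r}")

    # -- hooks -------------------------------------------------------------
    def _distance(self, r_i, r_j) -> Tuple[float, np.ndarray]:
        rvec = np.asarray(r_j, float) - np.asarray(r_i, float)
        d = float(np.linalg.norm(rvec))
        return d, rvec

    def force(self, step, r_i, r_j):
        d, rvec = self._distance(r_i, r_j)
        if d == 0.0:
            return np.zeros(3)
        return self.k_restraint * (d - self.target) * (rvec / d)

    def potential(self, r_i, r_j):
        d, _ = self._distance(r_i, r_j)
        return 0.5 * self.k_restraint * (d - self.target) ** 2

    def on_step(self, step, r_i, r_j, resources):
        d, _ = self._distance(r_i, r_j)
        if self.reduce_mode == "mean_distance" and (step + 1) % resources.output_interval == 0:
            resources.ensemble_reduce(d)
        if self.stop_tolerance > 0 and abs(d - self.target) < self.stop_tolerance:
            resources.signal_stop(self.stop_scope)

    # -- persistence (mdrun node payloads are serializable) ---------------
    def to_json(self) -> Dict[str, Any]:
        return {
            "pair": list(self.pair),
            "k_restraint": self.k_restraint,
            "target": self.target,
            "stop_tolerance": self.stop_tolerance,
            "stop_scope": self.stop_scope,
            "reduce_mode": self.reduce_mode,
        }

    @staticmethod
    def from_json(doc: Dict[str, Any]) -> "RestraintPlugin":
        return RestraintPlugin(
            pair=tuple(doc["pair"]),
            k_restraint=doc["k_restraint"],
            target=doc["target"],
            stop_tolerance=doc.get("stop_tolerance", 0.0),
            stop_scope=doc.get("stop_scope", MEMBER),
            reduce_mode=doc.get("reduce_mode", "none"),
        )
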