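"""Toy molecular systems and run input, with JSON persistence.

Reduced units throughout: masses, lengths and times are dimensionless.  A
:class:`ToySystem` is a set of point particles with harmonic bonds — no
nonbonded interactions, periodic boundaries or constraints; the engine
exists to exercise the workflow and plugin contracts, not to do chemistry.

The on-disk format is a JSON document::

    {"system": {"masses": [...], "positions": [[x,y,z], ...],
                "velocities": [[x,y,z], ...], "bonds": [[i, j, k, r0], ...]},
     "params": {"dt": ..., "nsteps": ..., "friction_gamma": ...,
                "output_interval": ..., "seed": ..., "init_temperature": ...}}
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Sequence, Tuple

import numpy as np

from ..errors import InvariantViolationError, MalformedInputError


@dataclass
class Bond:
    """Harmonic bond between particles *i* and *j*:
    U = ½ k (|r_ij| − r0)²."""

    i: int
    j: int
    k: float
    r0: float


@dataclass
class ToySystem:
    masses: np.ndarray          # (n,)
    positions: np.ndarray       # (n, 3)
    velocities: np.ndarray      # (n, 3)
    bonds: List[Bond] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    def validate(self, path: str = "system") -> None:
        n = self.n_particles
        for name, arr, shape in (
            ("masses", self.masses, (n,)),
            ("positions", self.positions, (n, 3)),
            ("velocities", self.velocities, (n, 3)),
        ):
            if np.asarray(arr).shape != shape:
                raise InvariantViolationError(
                    f"{path}.{name}: expected shape {shape}, got {np.asarray(arr).shape}"
                )
        for idx, m in enumerate(self.masses):
            if not m > 0:
                raise InvariantViolationError(f"{path}.masses[{idx}]: must be > 0, got {m}")
        for bidx, b in enumerate(self.bonds):
            where = f"{path}.bonds[{bidx}]"
            if b.i == b.j:
                raise InvariantViolationError(f"{where}: i == j == {b.i}")
            for label, idx in (("i", b.i), ("j", b.j)):
                if not (0 <= idx < n):
                    raise InvariantViolationError(f"{where}.{label}: index {idx} out of range")
            if b.k < 0:
                raise InvariantViolationError(f"{where}.k: must be >= 0, got {b.k}")
            if not b.r0 > 0:
                raise InvariantViolationError(f"{where}.r0: must be > 0, got {b.r0}")

    def copy(self) -> "ToySystem":
        return ToySystem(
            masses=self.masses.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            bonds=[Bond(b.i, b.j, b.k, b.r0) for b in self.bonds],
        )

    def to_json(self) -> Dict[str, Any]:
        return {
            "masses": np.asarray(self.masses, float).tolist(),
            "positions": np.asarray(self.positions, float).tolist(),
            "velocities": np.asarray(self.velocities, float).tolist(),
            "bonds": [[b.i, b.j, b.k, b.r0] for b in self.bonds],
        }

    @staticmethod
    def from_json(doc: Dict[str, Any], path: str = "system") -> "ToySystem":
        try:
            system = ToySystem(
                masses=np.asarray(doc["masses"], float),
                positions=np.asarray(doc["positions"], float),
                velocities=np.asarray(doc["velocities"], float),
                bonds=[Bond(int(b[0]), int(b[1]), float(b[2]), float(b[3]))
                       for b in doc.get("bonds", [])],
            )
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise MalformedInputError(f"{path}: {exc}") from exc
        system.validate(path)
        return system


@dataclass
class SimulationParams:
    """Integrator settings, the analog of run parameters in a binary
    run-input file.

    ``init_temperature > 0`` redraws initial velocities from a
    Maxwell-Boltzmann distribution at that temperature (k_B = 1) using
    ``seed``; at 0 (the default) the file velocities are used verbatim and
    the dynamics are fully deterministic.
    """

    dt: float = 0.001
    nsteps: int = 10000
    friction_gamma: float = 0.0
    output_interval: int = 10
    seed: int = 0
    init_temperature: float = 0.0

    def validate(self, path: str = "params") -> None:
        if not self.dt > 0:
            raise InvariantViolationError(f"{path}.dt: must be > 0, got {self.dt}")
        if self.nsteps < 0:
            raise InvariantViolationError(f"{path}.nsteps: must be >= 0, got {self.nsteps}")
        if self.friction_gamma < 0:
            raise InvariantViolationError(
                f"{path}.friction_gamma: must be >= 0, got {self.friction_gamma}"
            )
        if self.output_interval < 1:
            raise InvariantViolationError(
                f"{path}.output_interval: must be >= 1, got {self.output_interval}"
            )
        if self.init_temperature < 0:
            raise InvariantViolationError(
                f"{path}.init_temperature: must be >= 0, got {self.init_temperature}"
            )

    def to_json(self) -> Dict[str, Any]:
        return {
            "dt": self.dt,
            "nsteps": self.nsteps,
            "friction_gamma": self.friction_gamma,
            "output_interval": self.output_interval,
            "seed": self.seed,
            "init_temperature": self.init_temperature,
        }

    @staticmethod
    def from_json(doc: Dict[str, Any], path: str = "params") -> "SimulationParams":
        known = {f: doc[f] for f in (
            "dt", "nsteps", "friction_gamma", "output_interval", "seed",
            "init_temperature",
        ) if f in doc}
        unknown = set(doc) - set(known)
        if unknown:
            raise MalformedInputError(f"{path}: unknown fields {sorted(unknown)}")
        try:
            params = SimulationParams(**known)
        except TypeError as exc:
            raise MalformedInputError(f"{path}: {exc}") from exc
        params.validate(path)
        return params


@dataclass
class SimulationInput:
    """Everything needed to run one simulation: a system and its params."""

    system: ToySystem
    params: SimulationParams

    def validate(self) -> None:
        self.system.validate()
        self.params.validate()

    def copy(self) -> "SimulationInput":
        return SimulationInput(self.system.copy(), copy.copy(self.params))

    def to_json(self) -> Dict[str, Any]:
        return {"system": self.system.to_json(), "params": self.params.to_json()}

    @staticmethod
    def from_json(doc: Dict[str, Any]) -> "SimulationInput":
        if not isinstance(doc, dict) or set(doc) != {"system", "params"}:
            raise MalformedInputError(
                "input document must have exactly the keys {'system', 'params'}"
            )
        return SimulationInput(
            system=ToySystem.from_json(doc["system"]),
            params=SimulationParams.from_json(doc["params"]),
        )


def load_input(path: str) -> SimulationInput:
    """Read and validate a simulation input file."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MalformedInputError(f"{path}: not valid JSON: {exc}") from exc
    return SimulationInput.from_json(doc)


def save_input(sim_input: SimulationInput, path: str) -> str:
    sim_input.validate()
    with open(path, "w") as fh:
        json.dump(sim_input.to_json(), fh, indent=2)
    return path


def make_dimer(separation: float, k_bond: float = 1.0, r0: float = 1.0,
               **param_overrides: Any) -> SimulationInput:
    """Two unit-mass particles on the x axis at ±separation/2, at rest,
    joined by one harmonic bond — the workhorse test system.

    Keyword arguments override :class:`SimulationParams` fields
    (``dt``, ``nsteps``, ``friction_gamma``, ``output_interval``, ``seed``,
    ``init_temperature``).
    """
    if not separation > 0:
        raise InvariantViolationError("separation must be > 0")
    system = ToySystem(
        masses=np.array([1.0, 1.0]),
        positions=np.array([[-separation / 2, 0.0, 0.0],
                            [separation / 2, 0.0, 0.0]]),
        velocities=np.zeros((2, 3)),
        bonds=[Bond(0, 1, k_bond, r0)],
    )
    params = SimulationParams(**param_overrides)
    sim = SimulationInput(system=system, params=params)
    sim.validate()
    return sim


# ------------------------------------------------------------------ overrides

_PARAM_FIELDS = {
    "dt": float, "nsteps": int, "friction_gamma": float,
    "output_interval": int, "seed": int, "init_temperature": float,
}
_SYSTEM_FIELDS = ("masses", "positions", "velocities", "bonds")


def apply_overrides(sim_input: SimulationInput,
                    overrides: Dict[str, Any]) -> SimulationInput:
    """Return a copy of *sim_input* differing only at the overridden
    dotted parameter paths (``params.nsteps``, ``system.positions``...);
    the original is untouched, enabling forked trajectories."""
    from ..errors import UnknownParameterPathError

    out = sim_input.copy()
    for path, value in overrides.items():
        parts = path.split(".")
        if len(parts) == 2 and parts[0] == "params" and parts[1] in _PARAM_FIELDS:
            caster = _PARAM_FIELDS[parts[1]]
            try:
                setattr(out.params, parts[1], caster(value))
            except (TypeError, ValueError) as exc:
                raise InvariantViolationError(f"{path}: {exc}") from exc
        elif len(parts) == 2 and parts[0] == "system" and parts[1] in _SYSTEM_FIELDS:
            doc = out.system.to_json()
            doc[parts[1]] = value
            out.system = ToySystem.from_json(doc)
        else:
            raise UnknownParameterPathError(f"unknown parameter path {path!r}")
    out.validate()
    return out
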