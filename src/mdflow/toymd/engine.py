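"""The velocity-Verlet integration loop with in-loop plugin extension, and
the co-execution machinery for coupled ensembles.

Integration (reduced units): positions advance by ``v·dt + f/(2m)·dt²`` and
velocities by the mean of the old and new forces times ``dt/(2m)``.  The
total force is the bonded harmonic force plus every plugin's contribution,
plus a deterministic damping term ``−γ·m·v`` when ``friction_gamma > 0``
(no stochastic kicks — the restraint equilibria stay in closed form).

Ensemble members are *uncoupled* by default and run sequentially.  An
ensemble becomes *coupled* — one thread per member, advancing in lockstep
with a per-step barrier — when any plugin declares an ensemble-scope stop or
an ensemble reduction.  ``ensemble_reduce`` is then a true barrier: every
member contributes its value for the same epoch (epochs are implicit call
counters) and all members receive the identical member-index-ordered mean.
A member that calls reduce a different number of times than its peers, or
exits while a reduce is pending, aborts the ensemble with a
:class:`ReduceEpochMismatchError`.  An ensemble-scope stop raised by any
member halts every member at its next step boundary (latency ≤ 1 step).
"""

from __future__ import annotations

import json
import os
import threading
from typing import Any, Dict, List, Optional, Sequence

import numpy as np

from ..errors import (
    NumericOverflowError,
    PluginError,
    ReduceEpochMismatchError,
    UpstreamFailureError,
)
from .forces import bonded_forces
from .plugins import ENSEMBLE, PairPlugin
from .system import SimulationInput

TRAJECTORY_FILENAME = "traj.xyz"
ENERGIES_FILENAME = "energies.jsonl"
FINAL_SYSTEM_FILENAME = "final_system.json"
REDUCE_LOG_FILENAME = "reduce.jsonl"


# --------------------------------------------------------------------------
# Ensemble synchronization
# --------------------------------------------------------------------------


class _CoupledSync:
    """Unified barrier for a coupled ensemble.

    Members block either at a step boundary or inside a reduce; when every
    active member is blocked, the sync either releases the step generation,
    completes the reduce epoch, or — if members disagree on what they are
    waiting for — fails everyone with an epoch mismatch.
    """

    def __init__(self, n: int):
        self.n = n
        self.cv = threading.Condition()
        self.active = set(range(n))
        self.blocked: Dict[int, tuple] = {}
        self.step_gen = 0
        self.reduce_results: Dict[int, Any] = {}
        self.stop = False
        self.error: Optional[BaseException] = None

    # cv must be held
    def _fail(self, err: BaseException) -> None:
        self.error = err
        self.blocked.clear()
        self.cv.notify_all()

    # cv must be held
    def _release_if_complete(self) -> None:
        if self.error is not None or not self.active:
            return
        if set(self.blocked) != self.active:
            return
        kinds = {b[0] for b in self.blocked.values()}
        if kinds == {"step"}:
            self.step_gen += 1
            self.blocked.clear()
            self.cv.notify_all()
        elif kinds == {"reduce"}:
            epochs = {b[1] for b in self.blocked.values()}
            if len(epochs) != 1:
                self._fail(ReduceEpochMismatchError(
                    f"members disagree on reduce epoch: {sorted(epochs)}"
                ))
                return
            epoch = epochs.pop()
            values = [np.asarray(self.blocked[m][2], float)
                      for m in sorted(self.blocked)]
            self.reduce_results[epoch] = np.mean(values, axis=0)
            self.blocked.clear()
            self.cv.notify_all()
        else:
            self._fail(ReduceEpochMismatchError(
                "some members reached a step boundary while others wait in "
                "ensemble_reduce"
            ))

    def step_wait(self, member: int) -> None:
        with self.cv:
            if self.error is not None:
                raise self.error
            gen = self.step_gen
            self.blocked[member] = ("step",)
            self._release_if_complete()
            while self.step_gen == gen and self.error is None:
                self.cv.wait()
            if self.error is not None:
                raise self.error

    def reduce(self, member: int, epoch: int, value: Any) -> Any:
        with self.cv:
            if self.error is not None:
                raise self.error
            if len(self.active) != self.n:
                self._fail(ReduceEpochMismatchError(
                    f"member {member} called ensemble_reduce after another "
                    "member finished"
                ))
                raise self.error
            self.blocked[member] = ("reduce", epoch, value)
            self._release_if_complete()
            while epoch not in self.reduce_results and self.error is None:
                self.cv.wait()
            if self.error is not None:
                raise self.error
            result = self.reduce_results[epoch]
            return float(result) if np.ndim(result) == 0 else result.tolist()

    def leave(self, member: int) -> None:
        with self.cv:
            self.active.discard(member)
            self.blocked.pop(member, None)
            if any(b[0] == "reduce" for b in self.blocked.values()):
                self._fail(ReduceEpochMismatchError(
                    f"member {member} finished while a reduce epoch was pending"
                ))
                return
            self._release_if_complete()

    def signal_stop(self) -> None:
        with self.cv:
            self.stop = True


class SessionResources:
    """Run-time facilities a simulation exposes to its plugins: ensemble
    reduction (barrier mean) and stop signals."""

    def __init__(self, member: int, output_interval: int,
                 sync: Optional[_CoupledSync] = None):
        self.member = member
        self.output_interval = output_interval
        self._sync = sync
        self._epoch = 0
        self._member_stop = False
        self.signaled = False
        self.reduce_log: List[Dict[str, Any]] = []

    def ensemble_reduce(self, value):
        """Barrier reduction: every member of the epoch contributes and all
        receive the identical mean (scalar or elementwise vector)."""
        epoch = self._epoch
        self._epoch += 1
        if self._sync is None:
            arr = np.asarray(value, float)
            reduced = float(arr) if arr.ndim == 0 else arr.tolist()
        else:
            reduced = self._sync.reduce(self.member, epoch, value)
        self.reduce_log.append({"epoch": epoch, "value": value, "reduced": reduced})
        return reduced

    def signal_stop(self, scope: str = "member") -> None:
        self.signaled = True
        if scope == ENSEMBLE and self._sync is not None:
            self._sync.signal_stop()
        else:
            self._member_stop = True

    # -- engine internals --------------------------------------------------
    def _should_stop(self) -> bool:
        if self._member_stop:
            return True
        return self._sync is not None and self._sync.stop

    def _step_boundary(self) -> None:
        if self._sync is not None:
            self._sync.step_wait(self.member)

    def _finish(self) -> None:
        if self._sync is not None:
            self._sync.leave(self.member)


# --------------------------------------------------------------------------
# The integrator
# --------------------------------------------------------------------------


def _write_xyz_frame(fh, step: int, positions: np.ndarray) -> None:
    fh.write(f"{len(positions)}\n")
    fh.write(f"step {step}\n")
    for p in positions:
        fh.write(f"X {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def run_md(
    sim_input: SimulationInput,
    plugins: Sequence[PairPlugin],
    resources: SessionResources,
    workdir: str,
    node_id: str = "mdrun",
) -> Dict[str, Any]:
    """Integrate one member; returns trajectory/final-system paths and the
    steps_run / converged summary.

    ``converged`` reports whether a stop was signaled *by this member*.
    """
    sim_input.validate()
    os.makedirs(workdir, exist_ok=True)
    system = sim_input.system.copy()
    params = sim_input.params
    n = system.n_particles
    for plugin in plugins:
        plugin.bind(n)

    x = np.asarray(system.positions, float).copy()
    v = np.asarray(system.velocities, float).copy()
    m = np.asarray(system.masses, float).reshape(n, 1)
    dt = params.dt
    gamma = params.friction_gamma

    if params.init_temperature > 0:
        rng = np.random.default_rng(params.seed)
        sigma = np.sqrt(params.init_temperature / m)  # k_B = 1
        v = rng.normal(0.0, 1.0, size=(n, 3)) * sigma

    def conservative(step: int):
        system.positions = x
        forces, potential = bonded_forces(system)
        for p in plugins:
            i, j = p.pair
            try:
                f = np.asarray(p.force(step, x[i], x[j]), float)
                potential += float(p.potential(x[i], x[j]))
            except Exception as exc:  # noqa: BLE001
                raise PluginError(node_id, resources.member, step, exc) from exc
            forces[i] += f
            forces[j] -= f
        return forces, potential

    traj_path = os.path.join(workdir, TRAJECTORY_FILENAME)
    energies_path = os.path.join(workdir, ENERGIES_FILENAME)
    steps_run = 0
    converged = False
    try:
        with open(traj_path, "w") as traj, open(energies_path, "w") as energies:

            def record(step: int, potential: float) -> None:
                kinetic = 0.5 * float(np.sum(m * v * v))
                _write_xyz_frame(traj, step, x)
                energies.write(json.dumps({
                    "step": step,
                    "time": step * dt,
                    "potential": potential,
                    "kinetic": kinetic,
                    "total": potential + kinetic,
                }) + "\n")

            f_cons, potential = conservative(0)
            f = f_cons - gamma * m * v
            record(0, potential)

            for step in range(params.nsteps):
                # overflow surfaces as the NumericOverflowError below, not
                # as numpy warnings mid-blowup
                with np.errstate(over="ignore", invalid="ignore"):
                    x += v * dt + f * (dt * dt) / (2.0 * m)
                    if not np.all(np.isfinite(x)):
                        raise NumericOverflowError(
                            f"non-finite coordinates at step {step} "
                            "(time step too large?)"
                        )
                    f_cons, potential = conservative(step)
                    v_half = v + f * dt / (2.0 * m)
                    f_new = f_cons - gamma * m * v_half
                    v = v_half + f_new * dt / (2.0 * m)
                    f = f_cons - gamma * m * v
                steps_run = step + 1
                if steps_run % params.output_interval == 0:
                    record(steps_run, potential)
                for p in plugins:
                    i, j = p.pair
                    try:
                        p.on_step(step, x[i], x[j], resources)
                    except (ReduceEpochMismatchError, PluginError):
                        raise
                    except Exception as exc:  # noqa: BLE001
                        raise PluginError(node_id, resources.member, step, exc) from exc
                resources._step_boundary()
                if resources._should_stop():
                    converged = resources.signaled
                    break
    finally:
        resources._finish()

    system.positions = x
    system.velocities = v
    final_input = SimulationInput(system=system, params=params)
    final_path = os.path.join(workdir, FINAL_SYSTEM_FILENAME)
    with open(final_path, "w") as fh:
        json.dump(final_input.to_json(), fh, indent=2)
    if resources.reduce_log:
        with open(os.path.join(workdir, REDUCE_LOG_FILENAME), "w") as fh:
            for entry in resources.reduce_log:
                fh.write(json.dumps(entry) + "\n")

    return {
        "trajectory_file": traj_path,
        "final_system": final_input.system,
        "steps_run": steps_run,
        "converged": converged,
    }


# --------------------------------------------------------------------------
# Ensemble co-execution
# --------------------------------------------------------------------------


def _is_coupled(plugins_per_member: Sequence[Sequence[PairPlugin]]) -> bool:
    for plugins in plugins_per_member:
        for p in plugins:
            if getattr(p, "reduce_mode", "none") != "none":
                return True
            if getattr(p, "stop_scope", "member") == ENSEMBLE:
                return True
    return False


def run_ensemble(
    inputs_per_member: Sequence[SimulationInput],
    plugins_per_member: Sequence[Sequence[PairPlugin]],
    workdirs: Sequence[str],
    node_id: str = "mdrun",
) -> List[Dict[str, Any]]:
    """Run all members of one simulation node.

    Uncoupled ensembles (no reduce, no ensemble-scope stop) execute
    sequentially in member order; coupled ensembles co-execute with one
    thread per member under lockstep barrier semantics.
    """
    width = len(inputs_per_member)
    coupled = width > 1 and _is_coupled(plugins_per_member)

    if not coupled:
        outputs = []
        for member in range(width):
            resources = SessionResources(
                member, inputs_per_member[member].params.output_interval
            )
            outputs.append(run_md(
                inputs_per_member[member], plugins_per_member[member],
                resources, workdirs[member], node_id=node_id,
            ))
        return outputs

    sync = _CoupledSync(width)
    outputs: List[Optional[Dict[str, Any]]] = [None] * width
    failures: List[tuple] = []
    lock = threading.Lock()

    def worker(member: int) -> None:
        resources = SessionResources(
            member, inputs_per_member[member].params.output_interval, sync
        )
        try:
            out = run_md(
                inputs_per_member[member], plugins_per_member[member],
                resources, workdirs[member], node_id=node_id,
            )
            outputs[member] = out
        except BaseException as exc:  # noqa: BLE001 - member failure aborts all
            with lock:
                failures.append((member, exc))
            with sync.cv:
                if sync.error is None:
                    sync._fail(exc)

    threads = [threading.Thread(target=worker, args=(member,), daemon=True)
               for member in range(width)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()

    if failures:
        # fail-fast: the originating failure is the one recorded on the sync
        origin = [mf for mf in failures if mf[1] is sync.error]
        member, exc = min(origin or failures, key=lambda mf: mf[0])
        raise UpstreamFailureError(node_id, member, exc)
    return outputs  # type: ignore[return-value]
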