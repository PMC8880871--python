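"""The toy MD engine: forces, integration physics, I/O, plugin contract."""

import json
import os

import numpy as np
import pytest

from mdflow.errors import (
    DegenerateGeometryError,
    InvariantViolationError,
    NumericOverflowError,
    ReduceEpochMismatchError,
    UnknownParameterPathError,
    UpstreamFailureError,
)
from mdflow.ops import make_constant
from mdflow.toymd import (
    Bond,
    RestraintPlugin,
    SessionResources,
    SimulationInput,
    ToySystem,
    bonded_forces,
    load_input,
    make_dimer,
    mdrun,
    modify_input,
    pair_distance,
    read_input,
    run_md,
    save_input,
)


def random_system(rng, n=5, n_bonds=4):
    pairs = set()
    while len(pairs) < n_bonds:
        i, j = rng.integers(0, n, 2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    return ToySystem(
        masses=rng.uniform(0.5, 2.0, n),
        positions=rng.normal(0, 1, (n, 3)),
        velocities=rng.normal(0, 0.1, (n, 3)),
        bonds=[Bond(i, j, float(rng.uniform(0.5, 3)), float(rng.uniform(0.5, 2)))
               for i, j in pairs],
    )


# ------------------------------------------------------------------- forces


def test_bond_at_rest_length_zero_force(ctx):
    sim = make_dimer(1.0, k_bond=1.0, r0=1.0)
    forces, potential = bonded_forces(sim.system)
    assert np.allclose(forces, 0)
    assert potential == 0.0


def test_displaced_dimer_initial_potential():
    sim = make_dimer(1.2, k_bond=1.0, r0=1.0)
    _, potential = bonded_forces(sim.system)
    assert potential == pytest.approx(0.5 * 0.2 ** 2)


@pytest.mark.parametrize("seed", range(10))
def test_newtons_third_law_net_force_zero(seed):
    system = random_system(np.random.default_rng(seed))
    forces, _ = bonded_forces(system)
    assert np.allclose(forces.sum(axis=0), 0, atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_potential_matches_scalar_oracle(seed):
    system = random_system(np.random.default_rng(seed))
    _, potential = bonded_forces(system)
    # independent scalar evaluation
    x = system.positions
    expected = sum(
        0.5 * b.k * (np.linalg.norm(x[b.j] - x[b.i]) - b.r0) ** 2
        for b in system.bonds
    )
    assert potential == pytest.approx(expected, rel=1e-12)


def test_coincident_particles_degenerate():
    system = ToySystem(
        masses=np.ones(2),
        positions=np.zeros((2, 3)),
        velocities=np.zeros((2, 3)),
        bonds=[Bond(0, 1, 1.0, 1.0)],
    )
    with pytest.raises(DegenerateGeometryError):
        bonded_forces(system)


# ----------------------------------------------------------------------- I/O


def test_input_write_read_round_trip(tmp_path):
    sim = make_dimer(1.3, 2.0, 0.9, dt=0.002, nsteps=42, friction_gamma=0.5)
    path = save_input(sim, str(tmp_path / "in.json"))
    loaded = load_input(path)
    assert loaded.to_json() == sim.to_json()


def test_negative_mass_names_the_field(tmp_path):
    sim = make_dimer(1.0)
    doc = sim.to_json()
    doc["system"]["masses"][1] = -1.0
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(InvariantViolationError, match=r"masses\[1\]"):
        load_input(str(path))


def test_read_input_node_parses_fixture(ctx, tmp_path):
    path = save_input(make_dimer(1.0), str(tmp_path / "dimer.json"))
    node = read_input(path)
    sim = node.output.input.result()
    assert sim.system.n_particles == 2
    assert len(sim.system.bonds) == 1


def test_modify_input_overrides_one_path(ctx):
    base = make_dimer(1.0)
    node = modify_input(make_constant(base), {"params.nsteps": 100})
    out = node.output.input.result()
    assert out.params.nsteps == 100
    assert out.params.dt == base.params.dt
    assert base.params.nsteps != 100  # the original is untouched


def test_modify_input_seed_array_fans_out(ctx):
    node = modify_input(make_constant(make_dimer(1.0)),
                        {"params.seed": [1, 2, 3]})
    assert node.width == 3
    outs = node.output.input.result()
    assert [s.params.seed for s in outs] == [1, 2, 3]
    assert len({json.dumps({k: v for k, v in s.to_json()["system"].items()})
                for s in outs}) == 1  # members differ only in seed


def test_modify_input_unknown_path(ctx):
    with pytest.raises(UnknownParameterPathError):
        modify_input(make_constant(make_dimer(1.0)), {"params.foo": 1})


# ------------------------------------------------------------------- physics


def energies_of(traj_path):
    side = os.path.join(os.path.dirname(traj_path), "energies.jsonl")
    return [json.loads(line) for line in open(side)]


def total_drift(sim, tmp_path, tag):
    wd = tmp_path / tag
    wd.mkdir()
    out = run_md(sim, [], SessionResources(0, sim.params.output_interval), str(wd))
    energies = [e["total"] for e in energies_of(out["trajectory_file"])]
    return max(abs(e - energies[0]) for e in energies) / abs(energies[0])


def test_energy_conservation_and_second_order_convergence(tmp_path):
    drift = total_drift(
        make_dimer(1.2, dt=0.001, nsteps=10_000, output_interval=10),
        tmp_path, "dt",
    )
    assert drift <= 1e-6
    half = total_drift(
        make_dimer(1.2, dt=0.0005, nsteps=20_000, output_interval=20),
        tmp_path, "dt_half",
    )
    assert half <= drift / 2  # order-2 integrator: halving dt at least halves drift


def test_momentum_conserved_without_friction(tmp_path):
    sim = make_dimer(1.2, dt=0.001, nsteps=2_000)
    out = run_md(sim, [], SessionResources(0, 10), str(tmp_path / "p"))
    final = out["final_system"]
    p = (np.asarray(final.velocities) *
         np.asarray(final.masses)[:, None]).sum(axis=0)
    assert np.allclose(p, 0, atol=1e-12)


def read_separations(traj_path):
    seps = []
    with open(traj_path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        atoms = [list(map(float, a.split()[1:])) for a in lines[i + 2:i + 2 + n]]
        seps.append(abs(atoms[1][0] - atoms[0][0]))
        i += 2 + n
    return np.array(seps)


def test_oscillation_period_matches_reduced_mass_closed_form(tmp_path):
    sim = make_dimer(1.2, k_bond=1.0, r0=1.0, dt=0.001, nsteps=20_000,
                     output_interval=1)
    out = run_md(sim, [], SessionResources(0, 1), str(tmp_path / "osc"))
    seps = read_separations(out["trajectory_file"])
    centered = seps - seps.mean()
    crossings = np.where(np.diff(np.sign(centered)) > 0)[0]
    period = float(np.diff(crossings).mean()) * sim.params.dt
    expected = 2 * np.pi / np.sqrt(2 * 1.0 / 1.0)  # 2π/√(2k/m), μ = m/2
    assert period == pytest.approx(expected, rel=0.01)


def test_damped_restraint_equilibrium_closed_form(tmp_path):
    k_b, r0, k_r, target = 1.0, 1.0, 4.0, 2.0
    sim = make_dimer(1.0, k_bond=k_b, r0=r0, dt=0.001, nsteps=20_000,
                     friction_gamma=1.0, output_interval=10)
    plugin = RestraintPlugin(pair=(0, 1), k_restraint=k_r, target=target)
    out = run_md(sim, [plugin], SessionResources(0, 10), str(tmp_path / "eq"))
    seps = read_separations(out["trajectory_file"])
    late = seps[int(0.8 * len(seps)):].mean()  # time-averaged late-time separation
    expected = (k_b * r0 + k_r * target) / (k_b + k_r)
    assert late == pytest.approx(expected, rel=0.02)


def test_numeric_overflow_for_huge_time_step(tmp_path):
    sim = make_dimer(1.5, k_bond=1e6, dt=10.0, nsteps=1000, output_interval=100)
    with pytest.raises(NumericOverflowError):
        run_md(sim, [], SessionResources(0, 100), str(tmp_path / "boom"))


# ----------------------------------------------------------- plugin contract


def test_member_scope_stop_contract(tmp_path):
    tol = 0.05
    sim = make_dimer(1.0, dt=0.001, nsteps=5_000, friction_gamma=1.0)
    plugin = RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=1.2,
                             stop_tolerance=tol)
    out = run_md(sim, [plugin], SessionResources(0, 10), str(tmp_path / "stop"))
    assert out["converged"] is True
    assert out["steps_run"] < sim.params.nsteps
    d = pair_distance(np.asarray(out["final_system"].positions), 0, 1)
    # within tolerance plus one-step drift
    assert abs(d - 1.2) < tol + 0.05


def test_empty_plugin_list_bitwise_identical_trajectory(tmp_path):
    sim = make_dimer(1.2, dt=0.001, nsteps=1_000, output_interval=10)
    out_a = run_md(sim, [], SessionResources(0, 10), str(tmp_path / "a"))
    out_b = run_md(sim, [RestraintPlugin(pair=(0, 1), k_restraint=0.0,
                                          target=1.0)],
                   SessionResources(0, 10), str(tmp_path / "b"))
    plain = run_md(sim, [], SessionResources(0, 10), str(tmp_path / "c"))
    bytes_a = open(out_a["trajectory_file"], "rb").read()
    assert bytes_a == open(plain["trajectory_file"], "rb").read()
    # zero-stiffness plugin exercises the plugin path with zero force
    assert bytes_a == open(out_b["trajectory_file"], "rb").read()


def test_seed_controls_thermal_velocities(tmp_path):
    base = make_dimer(1.2, dt=0.001, nsteps=200, output_interval=20,
                      init_temperature=0.5)
    outs = {}
    for tag, seed in (("s1", 1), ("s1b", 1), ("s2", 2)):
        sim = base.copy()
        sim.params.seed = seed
        outs[tag] = open(run_md(sim, [], SessionResources(0, 20),
                                str(tmp_path / tag))["trajectory_file"],
                         "rb").read()
    assert outs["s1"] == outs["s1b"]
    assert outs["s1"] != outs["s2"]


# ------------------------------------------------------- coupled co-execution


def coupled_mdrun(ctx, plugins, nsteps=200, output_interval=50):
    base = make_dimer(1.0, dt=0.001, nsteps=nsteps, friction_gamma=0.5,
                      output_interval=output_interval)
    return mdrun(make_constant(base, context=ctx), plugins=plugins,
                 context=ctx).run()


def test_reduce_mean_matches_offline_log(ctx):
    plugins = [
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=t,
                         reduce_mode="mean_distance")]
        for t in (1.5, 2.0, 2.5)
    ]
    node = coupled_mdrun(ctx, plugins)
    logs = []
    for member in range(3):
        wd = os.path.join(ctx.session.workdir_root, node.node_id, str(member))
        with open(os.path.join(wd, "reduce.jsonl")) as fh:
            logs.append([json.loads(line) for line in fh])
    assert len({len(lg) for lg in logs}) == 1 and len(logs[0]) > 0
    for epoch in range(len(logs[0])):
        contributions = [lg[epoch]["value"] for lg in logs]
        observed = {lg[epoch]["reduced"] for lg in logs}
        assert len(observed) == 1  # identical in every member
        assert observed.pop() == pytest.approx(np.mean(contributions), abs=0)


def test_ensemble_scope_stop_halts_all_within_one_step(ctx):
    plugins = [
        [RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=1.2,
                         stop_tolerance=0.05, stop_scope="ensemble")],
        [RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=3.0)],
        [RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=3.5)],
    ]
    node = coupled_mdrun(ctx, plugins, nsteps=5_000, output_interval=10)
    steps = node.output.steps_run.result()
    converged = node.output.converged.result()
    assert converged == [True, False, False]
    assert all(s < 5_000 for s in steps)
    assert max(steps) - min(steps) <= 1


def test_member_scope_stop_halts_only_that_member(ctx):
    plugins = [
        [RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=1.2,
                         stop_tolerance=0.05, stop_scope="member")],
        [RestraintPlugin(pair=(0, 1), k_restraint=50.0, target=3.0)],
    ]
    node = coupled_mdrun(ctx, plugins, nsteps=3_000, output_interval=10)
    steps = node.output.steps_run.result()
    assert steps[0] < 3_000
    assert steps[1] == 3_000


def test_reduce_in_single_member_is_epoch_mismatch(ctx):
    plugins = [
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=2.0)],
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=2.0,
                         reduce_mode="mean_distance")],
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=2.0)],
    ]
    with pytest.raises(UpstreamFailureError) as err:
        coupled_mdrun(ctx, plugins, nsteps=100, output_interval=10)
    assert isinstance(err.value.cause, ReduceEpochMismatchError)


def test_mdrun_plugin_payload_serializes(ctx):
    node = coupled_mdrun(ctx, [
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=1.5)],
        [RestraintPlugin(pair=(0, 1), k_restraint=5.0, target=2.5)],
    ], nsteps=10)
    doc = ctx.graph.serialize()
    assert "mdrun" in doc and "k_restraint" in doc
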