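"""Ensemble simulations from an array of inputs.

modify_input with an array of seeds fans one run input out to a width-4
ensemble; mdrun then runs the whole batch, one working directory per
member.  With a Maxwell-Boltzmann initial temperature, each seed yields a
distinct trajectory.
"""

import tempfile

from mdflow import Context, make_constant, make_dimer, mdrun, modify_input

with Context(workdir=tempfile.mkdtemp()) as ctx:
    base = make_dimer(1.2, k_bond=1.0, r0=1.0, dt=0.001, nsteps=500,
                      output_interval=50, init_temperature=0.5)
    ensemble = modify_input(make_constant(base),
                            {"params.seed": [1, 2, 3, 4]})
    node = mdrun(ensemble).run()

    trajectories = node.output.trajectory_file.result()
    print(f"ensemble width: {node.width}")
    for member, path in enumerate(trajectories):
        print(f"  member {member}: {path}")

# Four trajectory files in four separate member directories — the ensemble
# dimension is carried by the graph, not by user-side bookkeeping.
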