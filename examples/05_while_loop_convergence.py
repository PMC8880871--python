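"""Dynamic workflow extension: a while_loop over a fused subgraph.

The subgraph carries named state (a counter here); each iteration
instantiates fresh body nodes appended to the executed graph — visible in
the session log — and propagates updated state to the next iteration.
The loop is pre-test and guarded by max_iteration.
"""

from mdflow import Context, INTEGER, function_wrapper, subgraph, var, while_loop


@function_wrapper(output={"y": INTEGER})
def increment(x):
    return x + 1


with Context() as ctx:
    sg = subgraph(variables={"n": 0})
    with sg:
        sg.n = increment(x=sg.n).output.y

    loop = while_loop(sg, var("n") < 4, max_iteration=100)
    print("final n        :", loop.final["n"].result())
    print("iterations_run :", loop.iterations_run.result())
    print("graph grew to  :", ctx.session.executed_nodes())

# Four iterations ran (n: 0 -> 4); each '...itK.increment-0' node in the log
# is one dynamically appended body instantiation.
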