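"""Serialize a work graph to JSON, reload it, and export Graphviz DOT.

Graphs round-trip structurally — node ids, specs, bound constants, edges
and widths are preserved — including nested while_loop/subgraph documents.
Wrapped user procedures are recorded by name only and must be re-registered
before loading.
"""

from mdflow import Context, deserialize, make_constant, make_dimer, mdrun, modify_input

with Context() as build:
    ensemble = modify_input(make_constant(make_dimer(1.0).to_json()),
                            {"params.seed": [1, 2]})
    mdrun(ensemble)
    document = build.graph.serialize()
    dot = build.graph.to_dot()

print("serialized document:")
print(document[:400], "...")
print()
print("DOT export:")
print(dot)

with Context() as reload_ctx:
    restored = deserialize(document, reload_ctx)
    print()
    print("round-trip preserved  :", restored.serialize() == document)
    print("restored mdrun width  :", restored.nodes["mdrun-0"].width)
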