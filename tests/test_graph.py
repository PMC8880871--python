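"""Work-graph construction, widths, ordering, validation, serialization."""

import json

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdflow.context import Context
from mdflow.errors import (
    CycleError,
    KindMismatchError,
    MissingRequiredInputError,
    SchemaVersionError,
    UnknownOperationError,
    UnknownPortError,
    WidthMismatchError,
)
from mdflow.fixtures import RandomDagSpec, generate_random_dag, _noop_spec
from mdflow.graph import DataEdge, deserialize, infer_width
from mdflow.kinds import BOOLEAN, INTEGER
from mdflow.ops import ensemble_input, logical_not, make_constant


def as_nx(graph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.source[0], e.sink[0]) for e in graph.edges)
    return g


# ----------------------------------------------------------------- add_node


def test_constant_node_has_width_one_and_no_edges(ctx):
    fut = make_constant(42)
    assert fut.width == 1
    assert ctx.graph.edges == []


def test_chain_creates_map_edge_and_orders_producer_first(ctx):
    b = logical_not(make_constant(True))
    order = ctx.graph.topological_order()
    assert order.index("make_constant-0") < order.index("logical_not-0")
    (edge,) = ctx.graph.edges
    assert edge.mode == "map"


def test_kind_mismatch_on_bad_binding(ctx):
    spec = _noop_spec(1)  # integer input port
    boolean = make_constant(True)
    with pytest.raises(KindMismatchError):
        ctx.graph.add_node(spec, {"in0": boolean}, context=ctx)


def test_unknown_port_and_missing_required(ctx):
    spec = _noop_spec(1)
    with pytest.raises(UnknownPortError):
        ctx.graph.add_node(spec, {"nope": 1}, context=ctx)
    with pytest.raises(MissingRequiredInputError):
        ctx.graph.add_node(spec, {}, context=ctx)


def test_foreign_future_rejected(ctx, make_ctx):
    other = make_ctx()
    foreign = make_constant(1, context=other)
    spec = _noop_spec(1)
    with pytest.raises(Exception):
        ctx.graph.add_node(spec, {"in0": foreign}, context=ctx)


def test_node_ids_are_deterministic_per_opname(ctx):
    make_constant(1)
    make_constant(2)
    assert list(ctx.graph.nodes)[:2] == ["make_constant-0", "make_constant-1"]


# --------------------------------------------------------------- infer_width


@pytest.mark.parametrize("widths, expected", [
    ((1, 1), 1),
    ((1, 3), 3),
    ((3, 3, 1), 3),
    ((5,), 5),
])
def test_infer_width_broadcast(widths, expected):
    assert infer_width(widths) == expected


def test_infer_width_incompatible():
    with pytest.raises(WidthMismatchError):
        infer_width((2, 3))


@given(st.lists(st.sampled_from([1, 1, 1, 4]), min_size=1, max_size=6))
@settings(max_examples=50, derandomize=True)
def test_infer_width_invariant_under_permutation(widths):
    # commutative/associative over the argument multiset
    assert infer_width(widths) == infer_width(sorted(widths, reverse=True))


def test_ensemble_widths_propagate(ctx):
    e = ensemble_input([True, False, True])
    out = logical_not(e)
    assert out.width == 3
    assert out.result() == [False, True, False]


# ---------------------------------------------------------- topological order


def test_diamond_tie_break_is_insertion_order(ctx):
    spec0, spec1, spec2 = _noop_spec(0), _noop_spec(1), _noop_spec(2)
    a = ctx.graph.add_node(spec0, {}, context=ctx, node_id="A")
    b = ctx.graph.add_node(spec1, {"in0": a.output_future("value")},
                           context=ctx, node_id="B")
    c = ctx.graph.add_node(spec1, {"in0": a.output_future("value")},
                           context=ctx, node_id="C")
    d = ctx.graph.add_node(
        spec2,
        {"in0": b.output_future("value"), "in1": c.output_future("value")},
        context=ctx, node_id="D",
    )
    assert ctx.graph.topological_order() == ["A", "B", "C", "D"]


@pytest.mark.parametrize("seed", range(20))
def test_random_dag_order_satisfies_every_edge(seed, make_ctx):
    graph = generate_random_dag(RandomDagSpec(12, 0.35, seed), make_ctx())
    order = graph.topological_order()
    assert sorted(order) == sorted(graph.nodes)
    position = {n: i for i, n in enumerate(order)}
    for e in graph.edges:  # exhaustive edge scan
        assert position[e.source[0]] < position[e.sink[0]]


def test_cycle_raises_in_topological_order(ctx):
    a = make_constant(1)
    b = logical_not(make_constant(True))
    # manually inject a back-edge to corrupt the graph
    ctx.graph.edges.append(DataEdge(("logical_not-0", "value"),
                                    ("make_constant-1", "value")))
    ctx.graph.edges.append(DataEdge(("make_constant-1", "value"),
                                    ("logical_not-0", "value")))
    with pytest.raises(CycleError):
        ctx.graph.topological_order()


# ------------------------------------------------------------------ validate


def test_empty_graph_validates_clean(ctx):
    assert ctx.graph.validate() == []


def test_injected_back_edge_is_diagnosed_with_cycle_members(ctx):
    fut = logical_not(make_constant(True))
    ctx.graph.edges.append(DataEdge(("logical_not-0", "value"),
                                    ("make_constant-0", "value")))
    diags = ctx.graph.validate()
    cycle = [d for d in diags if d.code == "cycle"]
    assert cycle and set(cycle[0].nodes) == {"make_constant-0", "logical_not-0"}


@pytest.mark.parametrize("seed", range(50))
def test_random_valid_dags_validate_clean(seed, make_ctx):
    graph = generate_random_dag(RandomDagSpec(10, 0.3, seed), make_ctx())
    assert graph.validate() == []
    # independent cycle search cross-check
    assert nx.is_directed_acyclic_graph(as_nx(graph))


# -------------------------------------------------------------- serialization


def test_empty_graph_round_trips(make_ctx):
    c1, c2 = make_ctx(), make_ctx()
    doc = c1.graph.serialize()
    deserialize(doc, c2)
    assert c2.graph.serialize() == doc


def test_chain_round_trips_with_identical_topology(make_ctx):
    c1 = make_ctx()
    graph = generate_random_dag(RandomDagSpec(8, 0.4, 3), c1)
    doc = graph.serialize()
    c2 = make_ctx()
    restored = deserialize(doc, c2)
    assert restored.serialize() == doc
    assert restored.topological_order() == graph.topological_order()


def test_unknown_operation_name_rejected(make_ctx):
    c1 = make_ctx()
    generate_random_dag(RandomDagSpec(3, 0.3, 0), c1)
    doc = json.loads(c1.graph.serialize())
    doc["nodes"][0]["op"] = "no_such_operation"
    with pytest.raises(UnknownOperationError):
        deserialize(json.dumps(doc), make_ctx())


def test_schema_version_mismatch_rejected(make_ctx):
    c1 = make_ctx()
    doc = json.loads(c1.graph.serialize())
    doc["schema_version"] = 999
    with pytest.raises(SchemaVersionError):
        deserialize(json.dumps(doc), make_ctx())


def test_dot_export_mentions_every_node_and_edge(make_ctx):
    c1 = make_ctx()
    graph = generate_random_dag(RandomDagSpec(6, 0.5, 1), c1)
    dot = graph.to_dot()
    for node_id in graph.nodes:
        assert node_id in dot
    assert dot.count('" -> "') == len(graph.edges)
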