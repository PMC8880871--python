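"""Deferred minimal execution, caching, exactly-once, fork semantics."""

import networkx as nx
import pytest

from mdflow.errors import UpstreamFailureError
from mdflow.fixtures import RandomDagSpec, _noop_spec, generate_random_dag
from mdflow.ops import logical_not, make_constant
from mdflow.wrappers import function_wrapper
from mdflow.kinds import INTEGER


def nx_ancestors(graph, node_id):
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.source[0], e.sink[0]) for e in graph.edges)
    return nx.ancestors(g, node_id)


def test_independent_chain_stays_pending(ctx):
    chain1 = logical_not(logical_not(make_constant(True)))
    chain2 = logical_not(make_constant(False))
    chain1.result()
    executed = set(ctx.session.executed_nodes())
    assert chain2.node_id not in executed
    assert "make_constant-1" not in executed
    assert not chain2.resolved


def test_second_result_executes_zero_nodes(ctx):
    fut = logical_not(make_constant(True))
    fut.result()
    log_len = len(ctx.session.log)
    fut.result()
    assert len(ctx.session.log) == log_len


def test_diamond_shared_ancestor_executes_once(ctx):
    a = ctx.graph.add_node(_noop_spec(0), {}, context=ctx, node_id="A")
    a_out = a.output_future("value")
    b = ctx.graph.add_node(_noop_spec(1), {"in0": a_out}, context=ctx, node_id="B")
    c = ctx.graph.add_node(_noop_spec(1), {"in0": a_out}, context=ctx, node_id="C")
    d = ctx.graph.add_node(
        _noop_spec(2),
        {"in0": b.output_future("value"), "in1": c.output_future("value")},
        context=ctx, node_id="D",
    )
    d.output_future("value").result()
    assert [r.node_id for r in ctx.session.log].count("A") == 1


def test_fork_without_reexecution(ctx):
    """Resolving a second branch off a shared segment never re-runs it."""
    a = make_constant(True)
    b = logical_not(a)
    b.result()
    a_runs = len([r for r in ctx.session.log if r.node_id == a.node_id])
    c = logical_not(a)  # fork a new branch off the resolved segment
    c.result()
    assert len([r for r in ctx.session.log if r.node_id == a.node_id]) == a_runs == 1


@pytest.mark.parametrize("seed", range(25))
def test_minimal_execution_equals_ancestor_set(seed, make_ctx):
    """Executed set after result() == brute-force ancestor set, exactly."""
    build = make_ctx(seed)
    graph = generate_random_dag(RandomDagSpec(10, 0.3, seed), build)
    for node_id in graph.nodes:
        run = make_ctx(seed)
        g = generate_random_dag(RandomDagSpec(10, 0.3, seed), run)
        g.nodes[node_id].output_future("value").result()
        executed = set(run.session.executed_nodes())
        assert executed == nx_ancestors(g, node_id) | {node_id}


def test_exactly_once_under_arbitrary_result_sequences(ctx):
    graph = generate_random_dag(RandomDagSpec(8, 0.4, 2), ctx)
    ids = list(graph.nodes)
    for node_id in ids + ids[::-1] + ids:
        graph.nodes[node_id].run()
    counts = {}
    for r in ctx.session.log:
        counts[(r.node_id, r.member)] = counts.get((r.node_id, r.member), 0) + 1
    assert all(v == 1 for v in counts.values())


def test_execution_order_restricted_to_ancestors_is_topological(ctx):
    graph = generate_random_dag(RandomDagSpec(12, 0.35, 5), ctx)
    tail = list(graph.nodes)[-1]
    graph.nodes[tail].run()
    order = ctx.session.executed_nodes()
    position = {n: i for i, n in enumerate(order)}
    for e in graph.edges:
        if e.source[0] in position and e.sink[0] in position:
            assert position[e.source[0]] < position[e.sink[0]]


def test_upstream_failure_names_failing_node(ctx):
    @function_wrapper(output={"y": INTEGER})
    def bad(x):
        raise ValueError("broken operation")

    node = bad(x=1)
    downstream = bad(x=node.output.y)
    with pytest.raises(UpstreamFailureError) as err:
        downstream.output.y.result()
    assert err.value.node_id == node.node_id
    # the node is marked failed; resolving again re-raises without re-running
    log_len = len(ctx.session.log)
    with pytest.raises(UpstreamFailureError):
        downstream.output.y.result()
    assert len(ctx.session.log) == log_len


def test_session_seed_derivation_stable_and_bounded(ctx):
    from mdflow.executor import ExecContext

    a = ExecContext(ctx.session, "node-A", 0)
    b = ExecContext(ctx.session, "node-A", 1)
    assert a.seed != b.seed
    assert a.seed == ExecContext(ctx.session, "node-A", 0).seed
    assert 0 <= a.seed < 2 ** 31


def test_structured_log_written_as_json_lines(ctx, tmp_path):
    logical_not(make_constant(True)).result()
    path = tmp_path / "log.jsonl"
    ctx.session.write_log(str(path))
    import json

    records = [json.loads(line) for line in path.read_text().splitlines()]
    assert [r["node_id"] for r in records] == ctx.session.executed_nodes()
    assert all(r["order_index"] == i for i, r in enumerate(records))
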