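"""Deferred data-flow basics: futures, minimal execution, caching.

Operations added to a context build a work graph; nothing runs until
result() is called on a future, and then only that future's ancestors run.
"""

from mdflow import Context, concatenate_lists, join_arrays, logical_not, make_constant

with Context() as ctx:
    a = make_constant([1, 2])
    b = join_arrays(a, make_constant([3, 4]))
    c = concatenate_lists([[10], [20, 30], []])
    unused = logical_not(make_constant(True))  # never resolved below

    print("join_arrays([1,2],[3,4])    ->", b.result())
    print("concatenate_lists fold     ->", c.result())
    print("executed nodes so far      ->", ctx.session.executed_nodes())
    print("unused branch resolved?    ->", unused.resolved)

# The executed list omits the unused logical_not branch: result() runs
# exactly the ancestors of what was asked for, and repeated calls are free
# (the session caches every (node, member) exactly once).
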