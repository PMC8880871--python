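"""Turn an ordinary Python procedure into a graph operation.

function_wrapper declares the output kinds; input kinds are inferred from
whatever you bind.  Binding a width-3 ensemble invokes the procedure once
per member.
"""

from mdflow import Context, INTEGER, function_wrapper
from mdflow.ops import ensemble_input


@function_wrapper(output={"squared": INTEGER, "doubled": INTEGER})
def powers(x, output=None):
    output.squared = x * x
    output.doubled = 2 * x


with Context():
    node = powers(x=5)
    print("powers(5):    squared =", node.output.squared.result(),
          " doubled =", node.output.doubled.result())

    ensemble = powers(x=ensemble_input([1, 2, 3]))
    print("ensemble x=[1,2,3]: squared =", ensemble.output.squared.result())

# The ensemble call printed one squared value per member: the procedure ran
# three times, each member cached independently.
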