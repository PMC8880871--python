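"""Wrap external command-line tools and chain them through file futures.

The second copy consumes the first copy's declared output file as a future,
so the executor is forced to run them in dependency order; a nonzero exit
code is data you can branch on, not an exception.
"""

import tempfile

from mdflow import Context, cli, commandline_operation, fixture_command

src = tempfile.NamedTemporaryFile(suffix=".txt", delete=False)
src.write(b"tool-chain payload")
src.close()

copy = fixture_command("copy")
with Context() as ctx:
    first = commandline_operation(
        copy[0], copy[1:], input_files={"-i": src.name},
        output_files={"-o": "stage1.dat"}, name="copy",
    )
    second = commandline_operation(
        copy[0], copy[1:], input_files={"-i": first.output.file["-o"]},
        output_files={"-o": "stage2.dat"}, name="copy",
    )
    final = second.output.file["-o"].result()
    print("final file:", final)
    print("content   :", open(final).read())
    print("order     :", ctx.session.executed_nodes())

fail = fixture_command("fail")
result = cli(fail + ["3"])
print("failing tool returncode (data, not an exception):", result.returncode)
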