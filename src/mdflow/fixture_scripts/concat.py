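"""Fixture tool: write the bytes of -a FIRST followed by -b SECOND to -o OUT."""
import sys


def _flag(name):
    return sys.argv[sys.argv.index(name) + 1]


if __name__ == "__main__":
    with open(_flag("-o"), "wb") as out:
        for part in ("-a", "-b"):
            with open(_flag(part), "rb") as fh:
                out.write(fh.read())
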