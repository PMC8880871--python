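"""Fixture tool: byte-copy -i SRC to -o DST."""
import sys


def _flag(name):
    return sys.argv[sys.argv.index(name) + 1]


if __name__ == "__main__":
    with open(_flag("-i"), "rb") as src, open(_flag("-o"), "wb") as dst:
        dst.write(src.read())
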