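"""Fixture tool: exit with the code given as the first argument (default 1)."""
import sys

if __name__ == "__main__":
    sys.stderr.write("failing on purpose\n")
    sys.exit(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
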