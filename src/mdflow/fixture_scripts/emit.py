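"""Fixture tool: print the first argument to stdout, exit 0."""
import sys

if __name__ == "__main__":
    print(sys.argv[1] if len(sys.argv) > 1 else "")
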