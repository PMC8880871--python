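import pytest

from mdflow.context import Context


@pytest.fixture
def ctx(tmp_path):
    """A fresh active context whose session works under tmp_path."""
    with Context(workdir=str(tmp_path / "wd")) as c:
        yield c


@pytest.fixture
def make_ctx(tmp_path):
    """Factory for additional isolated contexts (not pushed as active)."""
    counter = [0]

    def _make(seed: int = 0) -> Context:
        counter[0] += 1
        return Context(workdir=str(tmp_path / f"wd{counter[0]}"), seed=seed)

    return _make
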