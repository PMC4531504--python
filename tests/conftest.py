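import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles as _oracles

from hspscan import fixtures as fx

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rand1k():
    """A fixed random 1 kb sequence."""
    return fx.random_sequence(1000, seed=71, id="rand1k")


@pytest.fixture
def fasta_file(tmp_path):
    """Factory: write FASTA text, return its path."""

    def write(text: str, name: str = "seq.fa") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
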