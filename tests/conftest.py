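import pytest

from plastidbarcoder import synth


@pytest.fixture(scope="session")
def genome_5kb():
    """Repeat-structure-free 5 kb plastome-like sequence."""
    return synth.generate_plastome(
        synth.GenomeSpec(length=5_000, ir_length=0, seed=101))


@pytest.fixture(scope="session")
def genome_ir():
    """12 kb genome with a 2 kb inverted repeat pair."""
    return synth.generate_plastome(
        synth.GenomeSpec(length=12_000, ir_length=2_000, seed=102))
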