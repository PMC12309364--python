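import pytest

from g4tune import (
    G4MotifSpec,
    GeneratorConfig,
    Level,
    assign_loops,
    enumerate_library,
)


@pytest.fixture
def motif13_spec_dna():
    """The (G4 N3)3 G4 reference architecture, DNA level."""
    return G4MotifSpec(Level.DNA, 4, 4, (3, 3, 3))


@pytest.fixture
def motif13_spec_rna():
    return G4MotifSpec(Level.RNA, 4, 4, (3, 3, 3))


@pytest.fixture
def motif13_dna(motif13_spec_dna):
    return assign_loops(motif13_spec_dna, "fixed", "ATC")


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture
def dna_specs():
    """The 40 default-design specs at the DNA level."""
    return [s for s in enumerate_library() if s.level is Level.DNA]
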