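import numpy as np
import pytest

from stoch_m6a.io_formats import CoverageTrack, TranscriptAnnotation
from stoch_m6a.synthetic_data import (
    SimulationConfig,
    simulate_coverage,
    simulate_transcriptome,
)


@pytest.fixture
def annotation():
    return TranscriptAnnotation("geneA", "chr1", 1000, 1200, "+")


@pytest.fixture
def track():
    def make(depth, tid="geneA", role="IP", rep="rep1"):
        return CoverageTrack(tid, role, rep, np.asarray(depth, dtype=float))

    return make


@pytest.fixture(scope="session")
def recovery_simulation():
    """The planted-enrichment study: 200 transcripts, 50 single-window peaks
    at 8-fold enrichment over 20x input depth, two replicates, seed 7."""
    config = SimulationConfig(seed=7)
    annotations, sequences, truth = simulate_transcriptome(config)
    coverage = simulate_coverage(annotations, truth, config)
    return config, annotations, sequences, truth, coverage


@pytest.fixture(scope="session")
def null_simulation():
    """Same study with enrichment factor 1: IP and input are exchangeable."""
    config = SimulationConfig(seed=7, enrichment_factor=1.0)
    annotations, sequences, truth = simulate_transcriptome(config)
    coverage = simulate_coverage(annotations, truth, config)
    return config, annotations, sequences, truth, coverage
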