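import numpy as np
import pytest
from hypothesis import settings

from amperr.model import ReferenceAmplicon
from amperr.pipeline import PipelineConfig, run_pipeline
from amperr.simulate import AmpliconSpec, SimulationConfig, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_runs=2, reads_per_amplicon=80, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def pipeline_result():
    """A medium simulated study run through the whole pipeline once."""
    cfg = PipelineConfig(
        simulation=SimulationConfig(n_runs=3, reads_per_amplicon=150, seed=11),
        seed=11,
    )
    return run_pipeline(cfg)


@pytest.fixture
def bare_amplicon():
    """Amplicon without primers/flanks: exon covers the whole sequence."""

    def make(sequence, exon=None, amplicon_id="amp"):
        return ReferenceAmplicon(
            amplicon_id=amplicon_id,
            locus="L",
            sequence=sequence,
            exon=exon or (0, len(sequence)),
            primer_fwd="",
            primer_rev="",
        )

    return make


@pytest.fixture
def make_read():
    from amperr.model import Read

    def make(sequence, quals=None, read_id="r1", run_id="run1", amplicon_id="amp"):
        if quals is None:
            quals = np.full(len(sequence), 30, dtype=np.int64)
        return Read(read_id, run_id, amplicon_id, sequence, np.asarray(quals))

    return make
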