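import pytest

from ribopause.simulate import SimConfig, generate_transcriptome
from ribopause.transcripts import TranscriptModel


@pytest.fixture
def tiny_transcript():
    """Minimal valid CDS with no UTRs: ATG AAA GAA TAA."""
    return TranscriptModel("t1", "ATGAAAGAATAA", 0, 12)


@pytest.fixture
def small_cfg():
    """A fast, noiseless simulation configuration."""
    return SimConfig(
        n_transcripts=10,
        cds_length_range=(90, 150),
        depth=2000,
        offnoise_rate=0.0,
        abundance_sigma=0.5,
        seed=7,
    )


@pytest.fixture
def small_transcriptome(small_cfg):
    return generate_transcriptome(small_cfg)
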