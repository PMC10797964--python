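import pytest

from ncmap.intervals import (
    GenomicInterval,
    TranscriptModel,
    tracks_from_transcripts,
)
from ncmap.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded noiseless simulation shared across tests."""
    cfg = SimulationConfig(
        seed=7,
        n_planted=12,
        n_planted_mmrp=4,
        n_retained=3,
        background_depth=4.0,
    )
    return simulate_all(cfg)


@pytest.fixture()
def toy_genome_sizes():
    return {"chr1": 1000, "chr2": 500}


@pytest.fixture()
def single_exon_model():
    # + strand transcript, tx 0-100, cds 20-80, one exon 0-100
    return TranscriptModel(
        gene="g", name="t", chrom="chr1", strand="+",
        tx_start=0, tx_end=100, cds_start=20, cds_end=80,
        exon_starts=[0], exon_ends=[100],
    )


@pytest.fixture()
def minus_exon_model():
    return TranscriptModel(
        gene="g", name="t", chrom="chr1", strand="-",
        tx_start=0, tx_end=100, cds_start=20, cds_end=80,
        exon_starts=[0], exon_ends=[100],
    )


@pytest.fixture()
def toy_tracks(single_exon_model, toy_genome_sizes):
    return tracks_from_transcripts([single_exon_model], toy_genome_sizes)


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)
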