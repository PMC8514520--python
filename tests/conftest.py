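import numpy as np
import pytest

from pirnasig import (
    GenomicInterval,
    ReadRecord,
    ReadSet,
    SyntheticConfig,
    TranscriptModel,
    make_transcriptome,
)


@pytest.fixture
def toy_model():
    """Plus-strand 1-exon transcript: exon [100, 200), ORF [130, 190) genomic."""
    return TranscriptModel(
        "toy1",
        "toyg1",
        "chr1",
        "+",
        (GenomicInterval("chr1", 100, 200, "+"),),
        30,
        90,
    )


@pytest.fixture
def two_exon_minus_model():
    """Minus-strand 2-exon transcript; transcript coordinate 0 at genomic 299."""
    return TranscriptModel(
        "toy2",
        "toyg2",
        "chr1",
        "-",
        (
            GenomicInterval("chr1", 100, 160, "-"),
            GenomicInterval("chr1", 200, 300, "-"),
        ),
        20,
        140,
    )


@pytest.fixture
def readset_factory():
    def make(records, label="test", category="other", denom=None):
        rs = ReadSet(label, list(records), category=category)
        rs.norm_denominator = denom
        return rs

    return make


@pytest.fixture(scope="session")
def small_transcriptome():
    cfg = SyntheticConfig(seed=11, n_transcripts=8, preset="control")
    return cfg, make_transcriptome(cfg)


def uniform_readset(rng, n, ref_length, label="u", strand="+", length=26):
    """n reads with 5' ends uniform over a reference."""
    positions = rng.integers(0, ref_length, size=n)
    return ReadSet(
        label,
        [ReadRecord("ref", strand, int(p), length, space="genome") for p in positions],
    )
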