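import numpy as np
import pytest

from pirnasig import (
    GenomicInterval,
    ReadRecord,
    ReadSet,
    TranscriptModel,
    exon_intron_enrichment,
    junction_read_assignment,
    metagene,
    quantify,
    region_ratio,
    te_content,
)
from pirnasig.errors import ConfigError, NormalizationError
from pirnasig.quant import abundance_frame
from pirnasig.transcripts import ORF, UTR3, UTR5, JunctionSequence


def _rs(records, denom=None, label="q"):
    rs = ReadSet(label, records)
    rs.norm_denominator = denom
    return rs


@pytest.fixture
def kb_model():
    """1-exon transcript: 1 kb 5'UTR, 1 kb ORF (incl. stop), 2 kb 3'UTR."""
    return TranscriptModel(
        "kb1", "kb1", "chr1", "+", (GenomicInterval("chr1", 0, 4000, "+"),), 1000, 2000
    )


# --- quantify ---------------------------------------------------------------


def test_rpkm_pseudocount_zero_reads(kb_model):
    records = quantify(_rs([], denom=1e6), [kb_model])
    utr5 = next(r for r in records if r.region == UTR5)
    assert utr5.raw_count == 0
    assert utr5.rpkm == pytest.approx(0.001)  # (0 + 0.001) / (1 kb * 1)


def test_ppm_and_rpkm_arithmetic(kb_model):
    reads = [ReadRecord("kb1", "+", 2500, 26, count=100)]
    records = quantify(_rs(reads, denom=1e6), [kb_model])
    utr3 = next(r for r in records if r.region == UTR3)
    assert utr3.ppm == pytest.approx(100.0)
    assert utr3.rpkm == pytest.approx(50.0005)


def test_read_assigned_by_five_prime_only(kb_model):
    # 5' at the last ORF base, body extends into the 3'UTR -> ORF
    reads = [ReadRecord("kb1", "+", 1999, 30)]
    records = quantify(_rs(reads, denom=1e6), [kb_model])
    assert next(r for r in records if r.region == ORF).raw_count == 1
    assert next(r for r in records if r.region == UTR3).raw_count == 0
    assert kb_model.region_of(1999) == ORF


def test_regions_sum_to_whole(kb_model):
    rng = np.random.default_rng(2)
    reads = [
        ReadRecord("kb1", "+", int(p), 26, count=int(c))
        for p, c in zip(rng.integers(0, 4000, 200), rng.integers(1, 5, 200))
    ]
    records = quantify(_rs(reads, denom=1e6), [kb_model])
    per_region = sum(r.raw_count for r in records if r.region != "whole")
    whole = next(r for r in records if r.region == "whole").raw_count
    assert per_region == whole == sum(r.count for r in reads)


def test_ppm_linear_in_counts(kb_model):
    r1 = quantify(_rs([ReadRecord("kb1", "+", 2500, 26, count=10)], denom=1e6), [kb_model])
    r2 = quantify(_rs([ReadRecord("kb1", "+", 2500, 26, count=30)], denom=1e6), [kb_model])
    utr3_1 = next(r for r in r1 if r.region == UTR3)
    utr3_2 = next(r for r in r2 if r.region == UTR3)
    assert utr3_2.ppm == pytest.approx(3 * utr3_1.ppm)
    assert utr3_2.rpkm > utr3_1.rpkm


def test_quantify_requires_normalization(kb_model):
    with pytest.raises(NormalizationError):
        quantify(_rs([ReadRecord("kb1", "+", 0, 26)]), [kb_model])


def test_unknown_transcript_skipped(kb_model, caplog):
    reads = [ReadRecord("nope", "+", 0, 26), ReadRecord("kb1", "+", 0, 26)]
    records = quantify(_rs(reads, denom=1e6), [kb_model])
    assert next(r for r in records if r.region == "whole").raw_count == 1


def test_abundance_frame_columns(kb_model):
    df = abundance_frame(quantify(_rs([], denom=1e6), [kb_model]))
    assert set(df.columns) == {"transcript_id", "region", "raw_count", "ppm", "rpkm", "length"}


# --- exon/intron enrichment -------------------------------------------------


@pytest.fixture
def intron_model():
    """Exon 1 kb total, intron 9 kb."""
    return TranscriptModel(
        "em1",
        "em1",
        "chr1",
        "+",
        (GenomicInterval("chr1", 0, 500, "+"), GenomicInterval("chr1", 9500, 10000, "+")),
        100,
        900,
    )


def test_equal_density_fold_one(intron_model):
    # 1 read per 100 nt in both compartments
    reads = [ReadRecord("chr1", "+", p, 26, space="genome") for p in range(0, 500, 100)]
    reads += [ReadRecord("chr1", "+", p, 26, space="genome") for p in range(9500, 10000, 100)]
    reads += [ReadRecord("chr1", "+", p, 26, space="genome") for p in range(500, 9500, 100)]
    result = exon_intron_enrichment(_rs(reads), [intron_model])
    assert result["fold_enrichment"] == pytest.approx(1.0)


def test_fold_891(intron_model):
    reads = [ReadRecord("chr1", "+", p % 500, 26, count=1, space="genome") for p in range(99)]
    reads += [ReadRecord("chr1", "+", 5000, 26, space="genome")]
    result = exon_intron_enrichment(_rs(reads), [intron_model])
    assert result["exon_nt"] == 1000 and result["intron_nt"] == 9000
    assert result["fold_enrichment"] == pytest.approx((99 / 1000) / (1 / 9000))
    assert result["fold_enrichment"] == pytest.approx(891.0)


def test_all_exonic_flagged_and_monotone(intron_model):
    def fold(n):
        reads = [ReadRecord("chr1", "+", 10, 26, count=n, space="genome")]
        return exon_intron_enrichment(_rs(reads), [intron_model])

    r1, r2 = fold(10), fold(100)
    assert r1["pseudocount_flagged"] and r2["pseudocount_flagged"]
    assert r2["fold_enrichment"] > r1["fold_enrichment"]


def test_no_intron_models_rejected(kb_model):
    with pytest.raises(ConfigError):
        exon_intron_enrichment(_rs([]), [kb_model])


# --- junction assignment ----------------------------------------------------


def test_junction_spanning_read_assigned():
    junc = JunctionSequence("j1", "A" * 30 + "C" * 30, 30)
    read = ReadRecord("x", "+", 0, 28, sequence="A" * 14 + "C" * 14)
    result = junction_read_assignment(_rs([read]), [junc])
    assert result.counts["j1"] == 1
    assert result.n_unassigned == 0


def test_read_inside_one_flank_not_assigned():
    junc = JunctionSequence("j1", "A" * 30 + "C" * 30, 30)
    read = ReadRecord("x", "+", 0, 20, sequence="A" * 20)  # fits fully in upstream flank
    result = junction_read_assignment(_rs([read]), [junc])
    assert result.counts["j1"] == 0
    assert result.n_unassigned == 1


def test_junction_counts_match_substring_oracle():
    rng = np.random.default_rng(8)
    j1 = "".join(rng.choice(list("ACGT"), size=60))
    j2 = "".join(rng.choice(list("ACGT"), size=60))
    junctions = [JunctionSequence("j1", j1, 30), JunctionSequence("j2", j2, 30)]
    seqs = [j1[20:40], j2[25:45], j1[0:20], "ACGTACGTACGTACGT", j2[16:44]]
    reads = [ReadRecord("x", "+", 0, len(s), sequence=s) for s in seqs]
    result = junction_read_assignment(_rs(reads), junctions)

    def oracle(seq, junc):
        for off in range(len(junc.sequence) - len(seq) + 1):
            if junc.sequence[off : off + len(seq)] == seq and off < junc.boundary < off + len(seq):
                return True
        return False

    for junc in junctions:
        expected = sum(1 for s in seqs if oracle(s, junc))
        assert result.counts[junc.junction_id] == expected


def test_multi_junction_read_flagged():
    shared = "ACGTACGTACGTACGTACGTACGTACGT"
    j1 = JunctionSequence("j1", shared, 14)
    j2 = JunctionSequence("j2", "TTTT" + shared + "GGGG", 18)
    read = ReadRecord("x", "+", 0, 20, sequence=shared[4:24])
    result = junction_read_assignment(_rs([read]), [j1, j2])
    assert result.counts["j1"] == 1 and result.counts["j2"] == 1
    assert result.multi_junction_reads == [0]


# --- metagene ---------------------------------------------------------------


def _cov_model(tid, utr5, orf, utr3):
    total = utr5 + orf + utr3
    return TranscriptModel(
        tid, tid, "chr1", "+", (GenomicInterval("chr1", 0, total, "+"),), utr5, utr5 + orf
    )


def test_metagene_single_transcript_identity():
    m = _cov_model("m1", 10, 30, 20)
    reads = [ReadRecord("m1", "+", p, 5) for p in (2, 15, 15, 45)]
    profile = metagene([_rs(reads)], [m], trim=0.10)
    assert profile.values.size == 60
    assert profile.n_transcripts == 1
    cov = np.zeros(60)
    for r in reads:
        cov[r.five_prime] += 1
    assert np.allclose(profile.values, cov)  # own coverage, no rescale needed


def test_metagene_constant_coverage():
    models = [_cov_model(f"m{i}", 10, 30, 20) for i in range(5)]
    reads = [ReadRecord(m.transcript_id, "+", p, 5) for m in models for p in range(60)]
    profile = metagene([_rs(reads)], models, trim=0.10)
    assert np.allclose(profile.values, 1.0)


def test_metagene_outlier_trimmed_matches_sort_slice_oracle():
    models = [_cov_model(f"m{i}", 0, 30, 30) for i in range(10)]
    reads = []
    for i, m in enumerate(models):
        mult = 100 if i == 0 else 1
        reads += [ReadRecord(m.transcript_id, "+", p, 5, count=mult) for p in range(60)]
    profile = metagene([_rs(reads)], models, trim=0.10)
    stack = np.vstack([np.full(60, 100.0)] + [np.full(60, 1.0)] * 9)
    k = int(np.floor(10 * 0.10))
    oracle = np.sort(stack, axis=0)[k : 10 - k].mean(axis=0)
    assert np.allclose(profile.values, oracle)
    assert np.all(profile.values < 100)  # outlier excluded everywhere


def test_metagene_trim_zero_is_plain_mean():
    models = [_cov_model(f"m{i}", 0, 30, 30) for i in range(4)]
    reads = [ReadRecord(models[0].transcript_id, "+", 10, 5, count=8)]
    profile = metagene([_rs(reads)], models, trim=0.0)
    assert profile.values[10] == pytest.approx(2.0)  # 8 / 4 transcripts


def test_metagene_trim_bounds():
    with pytest.raises(ConfigError):
        metagene([_rs([])], [_cov_model("m", 5, 30, 5)], trim=0.5)


def test_metagene_values_between_min_max():
    rng = np.random.default_rng(4)
    models = [_cov_model(f"m{i}", 10, 30, 20) for i in range(8)]
    reads = [
        ReadRecord(m.transcript_id, "+", int(p), 5)
        for m in models
        for p in rng.integers(0, 60, size=30)
    ]
    profile = metagene([_rs(reads)], models, trim=0.10)
    assert np.all(profile.values >= 0)


# --- region ratio -----------------------------------------------------------


def test_region_ratio_equal_ppm(kb_model):
    reads = [ReadRecord("kb1", "+", 2500, 26, count=10)]
    num = _rs(list(reads), denom=1e6)
    den = _rs([ReadRecord("kb1", "+", 2600, 26, count=10)], denom=1e6)
    df = region_ratio(num, den, [kb_model], UTR3)
    assert df.iloc[0]["ratio"] == pytest.approx(1.0)
    assert df.iloc[0]["log2_ratio"] == pytest.approx(0.0)


def test_region_ratio_zero_denominator_flagged(kb_model):
    num = _rs([ReadRecord("kb1", "+", 2500, 26, count=10)], denom=1e6)
    den = _rs([], denom=1e6)
    df = region_ratio(num, den, [kb_model], UTR3)
    assert df.iloc[0]["ratio"] == pytest.approx(10.001 / 0.001)
    assert bool(df.iloc[0]["pseudocount_flagged"])


def test_region_ratio_three_transcripts_hand_arithmetic():
    models = [
        TranscriptModel(t, t, "chr1", "+", (GenomicInterval("chr1", 0, 300, "+"),), 50, 200)
        for t in ("a", "b", "c")
    ]
    num = _rs(
        [ReadRecord("a", "+", 250, 26, count=2), ReadRecord("b", "+", 250, 26, count=4)],
        denom=1e6,
    )
    den = _rs(
        [ReadRecord("a", "+", 250, 26, count=1), ReadRecord("b", "+", 250, 26, count=8),
         ReadRecord("c", "+", 250, 26, count=1)],
        denom=1e6,
    )
    df = region_ratio(num, den, models, UTR3).set_index("transcript_id")
    assert df.loc["a", "ratio"] == pytest.approx(2.001 / 1.001)
    assert df.loc["b", "ratio"] == pytest.approx(4.001 / 8.001)
    assert df.loc["c", "ratio"] == pytest.approx(0.001 / 1.001)


# --- TE content -------------------------------------------------------------


@pytest.fixture
def te_model():
    return TranscriptModel(
        "te1",
        "te1",
        "chr1",
        "+",
        (GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 200, 300, "+")),
        0,
        60,
    )


def test_te_no_overlap(te_model):
    tes = [GenomicInterval("chr2", 0, 50, "+", "SINE")]
    records = te_content([te_model], tes)
    assert all(r.sense_fraction == 0 and r.antisense_fraction == 0 for r in records)


def test_te_full_exon_sense(te_model):
    tes = [GenomicInterval("chr1", 0, 100, "+", "SINE")]
    rec = next(r for r in te_content([te_model], tes) if r.compartment == "exon")
    assert rec.sense_fraction == pytest.approx(100 / 200)
    assert rec.antisense_fraction == 0


def test_te_antisense_relative_to_transcript(te_model):
    tes = [GenomicInterval("chr1", 200, 250, "-", "LINE")]
    rec = next(r for r in te_content([te_model], tes) if r.compartment == "exon")
    assert rec.antisense_fraction == pytest.approx(50 / 200)
    assert rec.sense_fraction == 0


def test_te_overlapping_merged_union_oracle(te_model):
    tes = [
        GenomicInterval("chr1", 10, 50, "+", "SINE"),
        GenomicInterval("chr1", 30, 80, "+", "SINE"),
    ]
    rec = next(r for r in te_content([te_model], tes) if r.compartment == "exon")
    assert rec.sense_fraction == pytest.approx(70 / 200)  # union [10, 80)


def test_te_split_invariance(te_model):
    whole = [GenomicInterval("chr1", 20, 90, "+", "SINE")]
    split = [
        GenomicInterval("chr1", 20, 55, "+", "SINE"),
        GenomicInterval("chr1", 55, 90, "+", "SINE"),
    ]
    r1 = te_content([te_model], whole)
    r2 = te_content([te_model], split)
    for a, b in zip(r1, r2):
        assert a.sense_fraction == pytest.approx(b.sense_fraction)
        assert a.antisense_fraction == pytest.approx(b.antisense_fraction)


def test_te_intron_compartment(te_model):
    tes = [GenomicInterval("chr1", 120, 180, "+", "LTR")]
    rec = next(r for r in te_content([te_model], tes) if r.compartment == "intron")
    assert rec.sense_fraction == pytest.approx(60 / 100)
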