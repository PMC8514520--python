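"""Seeded generator of transcript models, sequences, and read libraries with
the statistical structure the analyses assume.

Background sequence is i.i.d. uniform over A/C/G/T so closed-form
expectations (e.g. recovered first-nucleotide bias) are exact.  Every
generator is deterministic under (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptySetError, StratumExhaustedError
from .transcripts import (
    ORF,
    UTR3,
    UTR5,
    GenomicInterval,
    ReadRecord,
    ReadSet,
    TranscriptModel,
)

NUCS = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = np.array(
    ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT" if "".join((a, b, c)) not in _STOP_CODONS]
)

#: Region-length medians (5'UTR, ORF, 3'UTR) per preset.  The ORF median is
#: rounded down to a codon multiple.
PRESET_MEDIANS = {
    "uppl": (346, 1314, 4583),
    "control": (77, 945, 392),
}


@dataclass
class TEInsert:
    family: str = "SINE"
    length: int = 150
    strand: str = "sense"  # relative to the transcript: sense / antisense
    region: str = UTR3


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_transcripts: int = 30
    preset: str = "uppl"
    utr5_median: int | None = None
    orf_median: int | None = None
    utr3_median: int | None = None
    length_sigma: float = 0.25  # lognormal sigma around the preset medians
    multi_exon: bool = False
    intron_length: int = 100
    pi_density: dict = field(default_factory=lambda: {UTR5: 0.1, ORF: 1.0, UTR3: 31.0})
    p_1U: float = 0.85
    pirna_length: tuple[int, int] = (24, 32)
    rpf_length: tuple[int, int] = (26, 32)
    rpf_frame_fidelity: float = 0.9
    coincidence_rate: float = 0.5  # rho: 3'UTR RPF 5' ends copied from piRNA 5' ends
    pingpong_fraction: float = 0.5  # phi
    slicer_offset: int = 10  # canonical ping-pong 5'-5' overlap
    te_insert: TEInsert | None = None
    coupling: str = "coupled"  # coupled / decoupled
    noise_sd: float = 0.3  # coupling-noise sd (pirna stage)
    rpf_noise_sd: float = 0.5  # intrinsic rna->rpf noise, independent of noise_sd

    def __post_init__(self):
        if self.preset not in PRESET_MEDIANS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        defaults = PRESET_MEDIANS[self.preset]
        if self.utr5_median is None:
            self.utr5_median = defaults[0]
        if self.orf_median is None:
            self.orf_median = defaults[1]
        if self.utr3_median is None:
            self.utr3_median = defaults[2]
        for name in ("p_1U", "rpf_frame_fidelity", "coincidence_rate", "pingpong_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.coupling not in ("coupled", "decoupled"):
            raise ConfigError(f"coupling must be coupled/decoupled, got {self.coupling!r}")


@dataclass
class SyntheticTranscriptome:
    models: list[TranscriptModel]
    transcript_seqs: dict[str, str]
    genome_seqs: dict[str, str]
    te_intervals: list[GenomicInterval]

    def model(self, tid: str) -> TranscriptModel:
        return next(m for m in self.models if m.transcript_id == tid)


def _te_consensus(family: str, length: int = 300) -> str:
    """Deterministic pseudo-consensus sequence for a TE family."""
    rng = np.random.default_rng(zlib.crc32(family.encode()))
    return "".join(rng.choice(NUCS, size=length))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCS, size=n)) if n else ""


def _orf_seq(rng: np.random.Generator, orf_len: int) -> str:
    """ATG + non-stop codons + one stop codon; no in-frame internal stop."""
    n_codons = orf_len // 3
    internal = rng.choice(_NONSTOP_CODONS, size=max(0, n_codons - 2))
    stop = rng.choice(np.array(sorted(_STOP_CODONS)))
    return "ATG" + "".join(internal) + stop


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _sample_region_length(rng: np.random.Generator, median: int, sigma: float, minimum: int) -> int:
    val = int(round(float(np.exp(rng.normal(np.log(max(median, 1)), sigma)))))
    return max(minimum, val)


def make_transcriptome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticTranscriptome:
    """Simulate transcript models, spliced/genomic sequences, and TE inserts.

    Each transcript sits on its own chromosome.  Region lengths are lognormal
    around the preset medians; ORF lengths are codon multiples with the stop
    codon only at the end.  TE inserts replace a slice of the configured
    region with (reverse-complemented if antisense) consensus sequence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    models: list[TranscriptModel] = []
    transcript_seqs: dict[str, str] = {}
    genome_seqs: dict[str, str] = {}
    te_intervals: list[GenomicInterval] = []
    te_cons = _te_consensus(config.te_insert.family) if config.te_insert else None

    for i in range(config.n_transcripts):
        tid = f"t{i + 1:04d}"
        chrom = f"chr_{tid}"
        utr5 = _sample_region_length(rng, config.utr5_median, config.length_sigma, 20)
        orf = _sample_region_length(rng, config.orf_median, config.length_sigma, 30)
        orf = 3 * max(10, round(orf / 3))
        utr3 = _sample_region_length(rng, config.utr3_median, config.length_sigma, 60)
        seq = _random_seq(rng, utr5) + _orf_seq(rng, orf) + _random_seq(rng, utr3)
        spliced_len = utr5 + orf + utr3

        te_t_span = None
        if config.te_insert:
            ins = config.te_insert
            r0, r1 = {
                UTR5: (0, utr5),
                ORF: (utr5, utr5 + orf),
                UTR3: (utr5 + orf, spliced_len),
            }[ins.region]
            if ins.length > r1 - r0:
                raise ConfigError(
                    f"TE insert length {ins.length} exceeds region {ins.region} ({r1 - r0} nt)"
                )
            if ins.length > len(te_cons):
                raise ConfigError("TE insert longer than consensus")
            pos = int(rng.integers(r0, r1 - ins.length + 1))
            start = int(rng.integers(0, len(te_cons) - ins.length + 1))
            piece = te_cons[start : start + ins.length]
            if ins.strand == "antisense":
                piece = _revcomp(piece)
            seq = seq[:pos] + piece + seq[pos + ins.length :]
            te_t_span = (pos, pos + ins.length, ins.strand)

        strand = "+" if not config.multi_exon else str(rng.choice(np.array(["+", "-"])))
        if config.multi_exon and spliced_len > 300:
            n_exons = int(rng.integers(2, 4))
            cuts = sorted(rng.choice(np.arange(50, spliced_len - 50), size=n_exons - 1, replace=False))
        else:
            n_exons, cuts = 1, []
        # exon sizes in transcript order
        bounds = [0, *[int(c) for c in cuts], spliced_len]
        sizes = [b1 - b0 for b0, b1 in zip(bounds, bounds[1:])]
        g_sizes = sizes if strand == "+" else list(reversed(sizes))
        exons, g = [], 0
        for size in g_sizes:
            exons.append(GenomicInterval(chrom, g, g + size, strand))
            g += size + (config.intron_length if len(g_sizes) > 1 else 0)
        model = TranscriptModel(
            tid, f"g{i + 1:04d}", chrom, strand, tuple(exons), utr5, utr5 + orf
        )
        # genome sequence consistent with the spliced sequence
        genome_len = exons[-1].end
        genome = list(_random_seq(rng, genome_len))
        for ex in exons:
            t0 = model.genomic_to_transcript(ex.start if strand == "+" else ex.end - 1)
            t1 = t0 + len(ex)
            piece = seq[t0:t1]
            if strand == "-":
                piece = _revcomp(piece)
            genome[ex.start : ex.end] = list(piece)
        genome_seqs[chrom] = "".join(genome)
        transcript_seqs[tid] = seq
        models.append(model)
        if te_t_span is not None:
            t0, t1, rel_strand = te_t_span
            g_strand = strand if rel_strand == "sense" else ("-" if strand == "+" else "+")
            for piece_iv in model.transcript_interval_to_genomic(t0, t1):
                te_intervals.append(
                    GenomicInterval(chrom, piece_iv.start, piece_iv.end, g_strand, config.te_insert.family)
                )
    return SyntheticTranscriptome(models, transcript_seqs, genome_seqs, te_intervals)


def _t_positions(seq: str, r0: int, r1: int) -> np.ndarray:
    arr = np.frombuffer(seq[r0:r1].encode(), dtype="S1")
    return r0 + np.nonzero(arr == b"T")[0]


def make_pirna_reads(
    config: SyntheticConfig,
    transcriptome: SyntheticTranscriptome,
    n_reads: int = 10000,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """piRNA-like reads: region densities per config, 1U bias with probability
    p_1U, lengths uniform over ``pirna_length``."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lmin, lmax = config.pirna_length
    bins = []  # (model, seq, r0, r1, weight, t_positions)
    for m in transcriptome.models:
        seq = transcriptome.transcript_seqs[m.transcript_id]
        for region, (r0, r1) in (
            (UTR5, (0, m.cds_start_t)),
            (ORF, (m.cds_start_t, m.cds_end_t)),
            (UTR3, (m.cds_end_t, m.spliced_length)),
        ):
            if r1 - r0 < lmin:
                continue
            weight = config.pi_density.get(region, 0.0) * (r1 - r0)
            if weight <= 0:
                continue
            tpos = _t_positions(seq, r0, r1)
            if tpos.size == 0 and config.p_1U == 1.0:
                raise StratumExhaustedError("U", f"no U position in {m.transcript_id} {region}")
            bins.append((m, seq, r0, r1, weight, tpos))
    if not bins:
        raise ConfigError("no region admits reads of the configured length")
    weights = np.array([b[4] for b in bins])
    counts = rng.multinomial(n_reads, weights / weights.sum())
    records = []
    for (m, seq, r0, r1, _w, tpos), k in zip(bins, counts):
        if k == 0:
            continue
        max_fp = m.spliced_length - lmin  # every read of >= lmin nt fits
        lengths = rng.integers(lmin, lmax + 1, size=k)
        use_u = rng.random(k) < config.p_1U
        hi_any = min(r1, max_fp + 1)
        n_t_ok = int(np.searchsorted(tpos, max_fp, side="right")) if tpos.size else 0
        for j in range(k):
            if use_u[j] and n_t_ok > 0:
                fp = int(tpos[int(rng.integers(0, n_t_ok))])
            else:
                fp = int(rng.integers(r0, hi_any))
            length = int(min(lengths[j], m.spliced_length - fp))
            records.append(
                ReadRecord(
                    ref_id=m.transcript_id,
                    strand="+",
                    five_prime=fp,
                    length=length,
                    count=1,
                    sequence=seq[fp : fp + length],
                    chemistry="P5",
                    space="transcript",
                )
            )
    return ReadSet(label="synthetic-piRNA", records=records, category="piRNA")


def make_rpf_reads(
    config: SyntheticConfig,
    transcriptome: SyntheticTranscriptome,
    pirnas: ReadSet | None = None,
    n_orf: int = 10000,
    n_utr3: int = 10000,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Ribosome-footprint-like reads.

    ORF reads sit at codon starts with probability ``rpf_frame_fidelity``
    (chemistry OH5).  3'UTR reads copy their 5' end from a sampled 3'UTR
    piRNA with probability ``coincidence_rate`` (chemistry P5), otherwise
    uniform (OH5).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    lmin, lmax = config.rpf_length
    by_id = {m.transcript_id: m for m in transcriptome.models}
    records = []

    orf_models = [m for m in transcriptome.models if m.orf_length >= lmin]
    if orf_models and n_orf:
        w = np.array([m.orf_length for m in orf_models], dtype=float)
        counts = rng.multinomial(n_orf, w / w.sum())
        for m, k in zip(orf_models, counts):
            seq = transcriptome.transcript_seqs[m.transcript_id]
            hi = min(m.cds_end_t, m.spliced_length - lmin)
            codon_starts = np.arange(m.cds_start_t, hi, 3)
            for _ in range(int(k)):
                length = int(rng.integers(lmin, lmax + 1))
                if rng.random() < config.rpf_frame_fidelity and codon_starts.size:
                    fp = int(codon_starts[int(rng.integers(0, codon_starts.size))])
                else:
                    fp = int(rng.integers(m.cds_start_t, hi))
                length = int(min(length, m.spliced_length - fp))
                records.append(
                    ReadRecord(
                        ref_id=m.transcript_id,
                        strand="+",
                        five_prime=fp,
                        length=length,
                        count=1,
                        sequence=seq[fp : fp + length],
                        chemistry="OH5",
                        space="transcript",
                    )
                )

    if n_utr3:
        utr3_pirnas = []
        if pirnas is not None:
            for r in pirnas.records:
                m = by_id.get(r.ref_id)
                if m is not None and r.five_prime >= m.cds_end_t:
                    utr3_pirnas.append((r.ref_id, r.five_prime))
        if config.coincidence_rate > 0 and not utr3_pirnas:
            raise EmptySetError("coincidence_rate > 0 requires 3'UTR piRNA reads")
        utr3_models = [m for m in transcriptome.models if m.utr3_length >= lmin]
        w = np.array([m.utr3_length for m in utr3_models], dtype=float)
        for _ in range(n_utr3):
            if rng.random() < config.coincidence_rate:
                tid, fp = utr3_pirnas[int(rng.integers(0, len(utr3_pirnas)))]
                m = by_id[tid]
                chemistry = "P5"
            else:
                m = utr3_models[int(rng.choice(len(utr3_models), p=w / w.sum()))]
                tid = m.transcript_id
                fp = int(rng.integers(m.cds_end_t, m.spliced_length - lmin + 1))
                chemistry = "OH5"
            length = int(min(rng.integers(lmin, lmax + 1), m.spliced_length - fp))
            seq = transcriptome.transcript_seqs[tid]
            records.append(
                ReadRecord(
                    ref_id=tid,
                    strand="+",
                    five_prime=fp,
                    length=length,
                    count=1,
                    sequence=seq[fp : fp + length],
                    chemistry=chemistry,
                    space="transcript",
                )
            )
    return ReadSet(label="synthetic-RPF", records=records, category="RPF")


def make_pingpong_reads(
    config: SyntheticConfig,
    reference_length: int = 10000,
    n_plus: int = 2000,
    n_minus: int = 2000,
    rng: np.random.Generator | None = None,
    ref_id: str = "TE_consensus",
) -> tuple[ReadSet, ReadSet]:
    """Opposite-strand read pairs with a planted 5'-5' overlap signature.

    A fraction ``pingpong_fraction`` of minus reads place their 5' end so the
    overlap with a sampled plus read equals ``slicer_offset``; the rest are
    uniform.  Minus-read five_prime is the plus-strand coordinate of the
    5'-most base.
    """
    if reference_length < 200:
        raise ConfigError("reference_length must be >= 200")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    lmin, lmax = config.pirna_length
    plus_fps = rng.integers(0, reference_length - lmax, size=n_plus)
    plus_records = [
        ReadRecord(ref_id, "+", int(fp), int(rng.integers(lmin, lmax + 1)), space="genome")
        for fp in plus_fps
    ]
    minus_records = []
    planted = rng.random(n_minus) < config.pingpong_fraction
    for i in range(n_minus):
        if planted[i]:
            fp = int(plus_fps[int(rng.integers(0, n_plus))]) + config.slicer_offset - 1
        else:
            fp = int(rng.integers(lmax - 1, reference_length))
        length = int(min(rng.integers(lmin, lmax + 1), fp + 1))
        minus_records.append(ReadRecord(ref_id, "-", fp, length, space="genome"))
    plus = ReadSet("synthetic-pp-plus", plus_records, category="piRNA")
    minus = ReadSet("synthetic-pp-minus", minus_records, category="piRNA")
    return plus, minus


def make_abundance_triplets(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    alpha: float = 0.5,
    beta: float = 2.0,
) -> pd.DataFrame:
    """Per-transcript (rna, rpf, pirna) abundances.

    rna is lognormal; rpf = alpha * rna * exp(eps1) with eps1 at the fixed
    ``rpf_noise_sd``.  Coupled mode routes piRNA through ribosome occupancy
    (pirna = beta * rpf * exp(eps2)); decoupled mode ties piRNA to rna only.
    ``noise_sd`` scales eps2/eps3, so the coupled partial correlation tends
    to 1 as noise_sd tends to 0.
    """
    if config.n_transcripts < 10:
        raise ConfigError("need n_transcripts >= 10")
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    n = config.n_transcripts
    rna = np.exp(rng.normal(3.0, 1.0, size=n))
    rpf = alpha * rna * np.exp(rng.normal(0.0, config.rpf_noise_sd, size=n))
    if config.coupling == "coupled":
        pirna = beta * rpf * np.exp(rng.normal(0.0, config.noise_sd, size=n))
    else:
        pirna = beta * alpha * rna * np.exp(rng.normal(0.0, config.noise_sd, size=n))
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i + 1:04d}" for i in range(n)],
            "rna": rna,
            "rpf": rpf,
            "pirna": pirna,
        }
    )


# --- parameter-recovery estimators (inverse checks for the generators) ------


def recover_p1u(reads: ReadSet, transcriptome: SyntheticTranscriptome, config: SyntheticConfig) -> float:
    """Estimate p_1U from observed first-nt U frequency, correcting for the
    background U content of the sampled regions."""
    total = u_count = 0.0
    for r in reads.records:
        if not r.sequence:
            continue
        total += r.count
        if r.sequence[0] in "TU":
            u_count += r.count
    if total == 0:
        raise EmptySetError("no sequences")
    f_u = u_count / total
    bg_num = bg_den = 0.0
    for m in transcriptome.models:
        seq = transcriptome.transcript_seqs[m.transcript_id]
        for region, (r0, r1) in (
            (UTR5, (0, m.cds_start_t)),
            (ORF, (m.cds_start_t, m.cds_end_t)),
            (UTR3, (m.cds_end_t, m.spliced_length)),
        ):
            w = config.pi_density.get(region, 0.0) * (r1 - r0)
            if w <= 0 or r1 == r0:
                continue
            bg_num += w * (seq[r0:r1].count("T") / (r1 - r0))
            bg_den += w
    bg_u = bg_num / bg_den
    return (f_u - bg_u) / (1.0 - bg_u)


def recover_frame_fidelity(rpf: ReadSet, transcriptome: SyntheticTranscriptome) -> float:
    """Estimate frame fidelity from the in-frame fraction of ORF reads."""
    by_id = {m.transcript_id: m for m in transcriptome.models}
    total = in_frame = 0.0
    for r in rpf.records:
        m = by_id.get(r.ref_id)
        if m is None or not m.cds_start_t <= r.five_prime < m.cds_end_t:
            continue
        total += r.count
        if (r.five_prime - m.cds_start_t) % 3 == 0:
            in_frame += r.count
    if total == 0:
        raise EmptySetError("no ORF reads")
    return (in_frame / total - 1.0 / 3.0) / (2.0 / 3.0)


def recover_coincidence_rate(
    rpf: ReadSet, pirnas: ReadSet, transcriptome: SyntheticTranscriptome
) -> float:
    """Estimate rho from the chance-corrected fraction of 3'UTR RPF 5' ends
    that sit exactly on a piRNA 5' end."""
    by_id = {m.transcript_id: m for m in transcriptome.models}
    pirna_pos: dict[str, set[int]] = {}
    for r in pirnas.records:
        m = by_id.get(r.ref_id)
        if m is not None and r.five_prime >= m.cds_end_t:
            pirna_pos.setdefault(r.ref_id, set()).add(r.five_prime)
    total = hits = 0.0
    for r in rpf.records:
        m = by_id.get(r.ref_id)
        if m is None or r.five_prime < m.cds_end_t:
            continue
        total += r.count
        if r.five_prime in pirna_pos.get(r.ref_id, ()):
            hits += r.count
    if total == 0:
        raise EmptySetError("no 3'UTR RPF reads")
    n_distinct = sum(len(v) for v in pirna_pos.values())
    utr3_nt = sum(m.utr3_length for m in transcriptome.models if m.transcript_id in pirna_pos)
    q = n_distinct / utr3_nt if utr3_nt else 0.0
    p_hat = hits / total
    return (p_hat - q) / (1.0 - q)


def recover_pingpong_fraction(
    plus: ReadSet, minus: ReadSet, reference_length: int, slicer_offset: int = 10,
    min_minus_fp: int | None = None,
) -> float:
    """Estimate phi from the chance-corrected fraction of minus reads whose
    5' end sits exactly ``slicer_offset - 1`` nt downstream of a plus 5' end."""
    targets = {r.five_prime + slicer_offset - 1 for r in plus.records}
    total = hits = 0.0
    for r in minus.records:
        total += r.count
        if r.five_prime in targets:
            hits += r.count
    if total == 0:
        raise EmptySetError("no minus reads")
    lo = min_minus_fp if min_minus_fp is not None else 31
    q = len(targets) / max(1, reference_length - lo)
    return (hits / total - q) / (1.0 - q)


# --- writers ---------------------------------------------------------------


def write_bed12(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.exons[0].start, m.exons[-1].end
            sizes = ",".join(str(len(ex)) for ex in m.exons) + ","
            starts = ",".join(str(ex.start - start) for ex in m.exons) + ","
            if m.is_coding:
                g_a = m.transcript_to_genomic(m.cds_start_t)
                g_b = m.transcript_to_genomic(m.cds_end_t - 1)
                thick_start, thick_end = min(g_a, g_b), max(g_a, g_b) + 1
            else:
                thick_start = thick_end = start
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            m.chrom,
                            start,
                            end,
                            m.transcript_id,
                            0,
                            m.strand,
                            thick_start,
                            thick_end,
                            "0,0,0",
                            len(m.exons),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )


def write_bed6(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(map(str, [iv.chrom, iv.start, iv.end, iv.name or ".", 0, iv.strand]))
                + "\n"
            )
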