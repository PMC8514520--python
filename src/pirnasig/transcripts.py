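"""Transcript models, coordinate mapping, read containers, filtering, and normalization.

All internal coordinates are 0-based half-open. BED is consumed natively;
GTF's 1-based inclusive coordinates are converted on read. Transcript
coordinate 0 is the 5'-most spliced base: for minus-strand transcripts that
is the genomically rightmost base of the last exon.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import BoundsError, ConfigError, NormalizationError, ParseError

logger = logging.getLogger(__name__)

UTR5 = "UTR5"
ORF = "ORF"
UTR3 = "UTR3"
REGIONS = (UTR5, ORF, UTR3)

READ_TSV_COLUMNS = ("ref_id", "strand", "five_prime", "length", "count", "sequence", "chemistry")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded interval on a named reference."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure plus ORF boundaries partitioning a spliced transcript.

    ``cds_start_t``/``cds_end_t`` are transcript coordinates (half-open); the
    ORF includes the stop codon.  ``cds_start_t == cds_end_t`` marks a
    non-coding model, which region operations reject.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start_t: int
    cds_end_t: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError("all exons must share the transcript chrom")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons must be sorted by genomic start and non-overlapping")
            prev_end = ex.end
        if not (0 <= self.cds_start_t <= self.cds_end_t <= self.spliced_length):
            raise ValueError(
                f"CDS [{self.cds_start_t}, {self.cds_end_t}) outside "
                f"[0, {self.spliced_length})"
            )

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_end_t > self.cds_start_t

    @property
    def utr5_length(self) -> int:
        return self.cds_start_t

    @property
    def orf_length(self) -> int:
        return self.cds_end_t - self.cds_start_t

    @property
    def utr3_length(self) -> int:
        return self.spliced_length - self.cds_end_t

    def region_length(self, region: str) -> int:
        if region == UTR5:
            return self.utr5_length
        if region == ORF:
            return self.orf_length
        if region == UTR3:
            return self.utr3_length
        if region == "whole":
            return self.spliced_length
        raise ConfigError(f"unknown region {region!r}")

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for up, dn in zip(self.exons, self.exons[1:]):
            if dn.start > up.end:
                out.append(GenomicInterval(self.chrom, up.end, dn.start, self.strand))
        return tuple(out)

    # --- coordinate mapping -------------------------------------------------

    def _exon_offsets(self) -> list[tuple[GenomicInterval, int]]:
        """Exons in transcript orientation paired with their transcript offset."""
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        offsets, cum = [], 0
        for ex in exons:
            offsets.append((ex, cum))
            cum += len(ex)
        return offsets

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to a transcript coordinate, or None if intronic/outside."""
        for ex, off in self._exon_offsets():
            if ex.start <= gpos < ex.end:
                if self.strand == "+":
                    return off + (gpos - ex.start)
                return off + (ex.end - 1 - gpos)
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.spliced_length:
            raise BoundsError(f"tpos {tpos} outside [0, {self.spliced_length})")
        for ex, off in self._exon_offsets():
            if off <= tpos < off + len(ex):
                if self.strand == "+":
                    return ex.start + (tpos - off)
                return ex.end - 1 - (tpos - off)
        raise AssertionError("unreachable")

    def transcript_interval_to_genomic(self, t0: int, t1: int) -> list[GenomicInterval]:
        """Project a half-open transcript interval onto genomic exon pieces."""
        if not (0 <= t0 < t1 <= self.spliced_length):
            raise BoundsError(f"interval [{t0}, {t1}) outside [0, {self.spliced_length})")
        pieces = []
        for ex, off in self._exon_offsets():
            lo, hi = max(t0, off), min(t1, off + len(ex))
            if lo >= hi:
                continue
            if self.strand == "+":
                pieces.append(GenomicInterval(self.chrom, ex.start + lo - off, ex.start + hi - off, self.strand))
            else:
                pieces.append(GenomicInterval(self.chrom, ex.end - (hi - off), ex.end - (lo - off), self.strand))
        return sorted(pieces, key=lambda p: p.start)

    def region_of(self, tpos: int) -> str:
        """Region containing a transcript position under the half-open partition."""
        if not 0 <= tpos < self.spliced_length:
            raise BoundsError(f"tpos {tpos} outside [0, {self.spliced_length})")
        if not self.is_coding:
            raise ConfigError(f"transcript {self.transcript_id} is non-coding; regions undefined")
        if tpos < self.cds_start_t:
            return UTR5
        if tpos < self.cds_end_t:
            return ORF
        return UTR3


def region_of(model: TranscriptModel, tpos: int) -> str:
    return model.region_of(tpos)


def genomic_to_transcript(model: TranscriptModel, gpos: int) -> int | None:
    return model.genomic_to_transcript(gpos)


def transcript_to_genomic(model: TranscriptModel, tpos: int) -> int:
    return model.transcript_to_genomic(tpos)


# --- reads -----------------------------------------------------------------


@dataclass
class ReadRecord:
    """A collapsed 5'-end-anchored read alignment.

    ``five_prime`` is the 0-based coordinate of the 5'-most nucleotide.  For
    minus-strand reads this is the genomically rightmost template base,
    expressed in plus-strand coordinates; the read body extends to lower
    coordinates.
    """

    ref_id: str
    strand: str
    five_prime: int
    length: int
    count: int = 1
    sequence: str | None = None
    chemistry: str = "unknown"
    space: str = "transcript"
    n_hits: int = 1

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.chemistry not in ("P5", "OH5", "unknown"):
            raise ValueError(f"chemistry must be P5/OH5/unknown, got {self.chemistry!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != length field {self.length}"
            )


@dataclass
class ReadSet:
    """A collection of collapsed reads plus library normalization state."""

    label: str
    records: list[ReadRecord] = field(default_factory=list)
    category: str = "other"
    norm_denominator: float | None = None

    CATEGORIES = ("piRNA", "RPF", "degradome", "RNAseq", "other")

    def __post_init__(self):
        if self.category not in self.CATEGORIES:
            raise ConfigError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def ppm(self, count: float) -> float:
        if self.norm_denominator is None:
            raise NormalizationError(f"read set {self.label!r} has no norm_denominator")
        return count / self.norm_denominator * 1e6

    def subset(self, predicate, label: str | None = None) -> "ReadSet":
        return ReadSet(
            label=label or self.label,
            records=[r for r in self.records if predicate(r)],
            category=self.category,
            norm_denominator=self.norm_denominator,
        )


# --- annotation readers -----------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_transcripts(path: str | Path, fmt: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from BED12 or GTF (Ensembl dialect).

    ``fmt`` may be "BED12" or "GTF"; if omitted it is guessed from the file
    extension.  Models without a CDS are returned flagged non-coding
    (``cds_start_t == cds_end_t == 0``).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "GTF" if suffix in (".gtf", ".gff") else "BED12"
    fmt = fmt.upper()
    if fmt == "BED12":
        return _load_bed12(path)
    if fmt == "GTF":
        return _load_gtf(path)
    raise ConfigError(f"unknown annotation format {fmt!r}")


def _load_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            )
            if exons[0].start != start or exons[-1].end != end:
                raise ParseError(f"{path}:{lineno}: blocks do not span chromStart..chromEnd")
            model = _with_cds_from_genomic(
                TranscriptModel(name, name, chrom, strand, exons, 0, 0),
                thick_start,
                thick_end,
                f"{path}:{lineno}",
            )
            models.append(model)
    return models


def _with_cds_from_genomic(
    model: TranscriptModel, g_start: int, g_end: int, where: str
) -> TranscriptModel:
    if g_start >= g_end:  # non-coding
        return model
    t_a = model.genomic_to_transcript(g_start)
    t_b = model.genomic_to_transcript(g_end - 1)
    if t_a is None or t_b is None:
        raise ParseError(f"{where}: CDS boundary [{g_start}, {g_end}) not exonic")
    lo, hi = min(t_a, t_b), max(t_a, t_b) + 1
    return replace(model, cds_start_t=lo, cds_end_t=hi)


def _load_gtf(path: Path) -> list[TranscriptModel]:
    exons: dict[str, list[GenomicInterval]] = {}
    cds_span: dict[str, tuple[int, int]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene_id)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            if tid not in meta:
                meta[tid] = (chrom, strand, attr.get("gene_id", tid))
                order.append(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append(GenomicInterval(chrom, start, end, strand))
            else:  # CDS or stop_codon: union both so the ORF includes the stop
                if tid in cds_span:
                    lo, hi = cds_span[tid]
                    cds_span[tid] = (min(lo, start), max(hi, end))
                else:
                    cds_span[tid] = (start, end)
    models = []
    for tid in order:
        chrom, strand, gene_id = meta[tid]
        if tid not in exons:
            raise ParseError(f"{path}: transcript {tid!r} has no exon features")
        exon_tuple = tuple(sorted(exons[tid], key=lambda e: e.start))
        model = TranscriptModel(tid, gene_id, chrom, strand, exon_tuple, 0, 0)
        if tid in cds_span:
            lo, hi = cds_span[tid]
            model = _with_cds_from_genomic(model, lo, hi, f"{path} transcript {tid}")
        models.append(model)
    return models


# --- sequences --------------------------------------------------------------


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an uppercase id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def spliced_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in transcript orientation."""
    if model.chrom not in genome:
        raise KeyError(f"chrom {model.chrom!r} not in genome FASTA")
    chrom_seq = genome[model.chrom]
    parts = [chrom_seq[ex.start : ex.end] for ex in model.exons]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


@dataclass(frozen=True)
class JunctionSequence:
    junction_id: str
    sequence: str
    boundary: int  # offset of the exon-exon boundary within `sequence`


def junction_sequences(
    model: TranscriptModel, genome: Mapping[str, str], flank_nt: int = 30
) -> list[JunctionSequence]:
    """Exon-exon junction sequences in transcript orientation.

    Each record carries the last ``min(flank_nt, exon length)`` nt of the
    upstream exon concatenated with the first ``min(flank_nt, exon length)``
    nt of the downstream exon.
    """
    if flank_nt < 1:
        raise ConfigError("flank_nt must be >= 1")
    spliced = spliced_sequence(model, genome)
    exons_t = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    out, boundary = [], 0
    for i, (up, dn) in enumerate(zip(exons_t, exons_t[1:]), start=1):
        boundary += len(up)
        f1 = min(flank_nt, len(up))
        f2 = min(flank_nt, len(dn))
        seq = spliced[boundary - f1 : boundary + f2]
        out.append(JunctionSequence(f"{model.transcript_id}:J{i}", seq, f1))
    return out


# --- read readers/writers ---------------------------------------------------


def load_reads_tsv(
    path: str | Path,
    label: str | None = None,
    category: str = "other",
    space: str = "transcript",
) -> ReadSet:
    """Read a tab-delimited read table (header line required).

    Required columns: ref_id, strand, five_prime, length.  Optional: count,
    sequence, chemistry, n_hits, space.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ref_id": str})
    required = {"ref_id", "strand", "five_prime", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", None)
        if seq is not None and (not isinstance(seq, str) or seq == ""):
            seq = None
        records.append(
            ReadRecord(
                ref_id=str(row.ref_id),
                strand=str(row.strand),
                five_prime=int(row.five_prime),
                length=int(row.length),
                count=int(getattr(row, "count", 1)),
                sequence=seq,
                chemistry=str(getattr(row, "chemistry", "unknown")),
                space=str(getattr(row, "space", space)),
                n_hits=int(getattr(row, "n_hits", 1)),
            )
        )
    return ReadSet(label=label or Path(path).stem, records=records, category=category)


def load_reads_bed6(
    path: str | Path, label: str | None = None, category: str = "other", space: str = "genome"
) -> ReadSet:
    """Read aligned read 5'-end records from BED6 (score column = count)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                count = max(1, int(float(score_s))) if score_s not in (".", "") else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            five_prime = start if strand == "+" else end - 1
            records.append(
                ReadRecord(
                    ref_id=chrom,
                    strand=strand,
                    five_prime=five_prime,
                    length=end - start,
                    count=count,
                    space=space,
                )
            )
    return ReadSet(label=label or Path(path).stem, records=records, category=category)


def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    rows = [
        {
            "ref_id": r.ref_id,
            "strand": r.strand,
            "five_prime": r.five_prime,
            "length": r.length,
            "count": r.count,
            "sequence": r.sequence if r.sequence is not None else "",
            "chemistry": r.chemistry,
        }
        for r in reads.records
    ]
    pd.DataFrame(rows, columns=list(READ_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


# --- filtering and normalization -------------------------------------------

FILTER_PRESETS = {
    "piRNA": (24, None),  # keeps length > 23
    "RPF": (26, 32),
    "none": (None, None),
}


def filter_reads(
    reads: ReadSet,
    min_len: int | None = None,
    max_len: int | None = None,
    preset: str = "none",
    unique_only: bool = True,
) -> ReadSet:
    """Length/uniqueness filter. Presets: piRNA keeps >23 nt, RPF keeps 26-32 nt."""
    if preset not in FILTER_PRESETS:
        raise ConfigError(f"unknown filter preset {preset!r}")
    p_min, p_max = FILTER_PRESETS[preset]
    min_len = min_len if min_len is not None else p_min
    max_len = max_len if max_len is not None else p_max
    if min_len is not None and max_len is not None and min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")

    def keep(r: ReadRecord) -> bool:
        if unique_only and r.n_hits != 1:
            return False
        if min_len is not None and r.length < min_len:
            return False
        if max_len is not None and r.length > max_len:
            return False
        return True

    return reads.subset(keep)


NORMALIZATION_METHODS = ("miRNA_sum", "spike_in", "mRNA_CDS_sum", "mito_CDS_sum", "upper_quartile")


def normalization_factor(
    reads: ReadSet,
    method: str,
    mirna_count: float | None = None,
    spike_in_count: float | None = None,
    cds_reads: ReadSet | None = None,
    models: Sequence[TranscriptModel] | None = None,
    abundances: Sequence[float] | None = None,
) -> float:
    """Compute and attach the reads-per-million denominator for a library.

    miRNA_sum / spike_in take externally counted totals.  mRNA_CDS_sum and
    mito_CDS_sum count reads (from ``cds_reads`` or ``reads`` itself) whose 5'
    end falls in the ORF of one of ``models``.  upper_quartile uses the 75th
    percentile of the nonzero per-transcript abundance vector.
    """
    if method not in NORMALIZATION_METHODS:
        raise ConfigError(f"unknown normalization method {method!r}")
    if method == "miRNA_sum":
        denom = mirna_count
        if denom is None:
            raise ConfigError("miRNA_sum requires mirna_count")
    elif method == "spike_in":
        denom = spike_in_count
        if denom is None:
            raise ConfigError("spike_in requires spike_in_count")
    elif method in ("mRNA_CDS_sum", "mito_CDS_sum"):
        if models is None:
            raise ConfigError(f"{method} requires models")
        source = cds_reads if cds_reads is not None else reads
        by_id = {m.transcript_id: m for m in models}
        denom = 0.0
        for r in source.records:
            m = by_id.get(r.ref_id)
            if m is None or not m.is_coding:
                continue
            if 0 <= r.five_prime < m.spliced_length and m.region_of(r.five_prime) == ORF:
                denom += r.count
    else:  # upper_quartile
        if abundances is None:
            raise ConfigError("upper_quartile requires abundances")
        nonzero = [a for a in abundances if a > 0]
        if not nonzero:
            raise NormalizationError("all abundances are zero")
        nonzero.sort()
        import numpy as np

        denom = float(np.percentile(nonzero, 75))
    if not denom or denom <= 0:
        raise NormalizationError(f"zero denominator under method {method!r}")
    reads.norm_denominator = float(denom)
    return float(denom)


# --- interval helpers shared with quantification ---------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intervals_total(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def point_in_intervals(merged: Sequence[tuple[int, int]], pos: int) -> bool:
    """Membership test against a merged, sorted interval list."""
    i = bisect_right(merged, (pos, float("inf"))) - 1
    return i >= 0 and merged[i][0] <= pos < merged[i][1]
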