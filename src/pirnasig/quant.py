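"""Region-aware read quantification (ppm/rpkm), exon/intron enrichment,
junction-read assignment, metagene trimmed-mean profiles, region-ratio
comparisons, and TE content of transcripts.

Reads are assigned to exactly one region by their 5' end.  rpkm adds the
0.001 pseudocount to the read count: (count + 0.001) / (kb * denom / 1e6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, NormalizationError
from .transcripts import (
    ORF,
    REGIONS,
    UTR3,
    UTR5,
    GenomicInterval,
    JunctionSequence,
    ReadSet,
    TranscriptModel,
    intervals_total,
    merge_intervals,
    point_in_intervals,
)

logger = logging.getLogger(__name__)

RPKM_PSEUDOCOUNT = 0.001


@dataclass
class AbundanceRecord:
    transcript_id: str
    region: str  # UTR5 / ORF / UTR3 / whole
    raw_count: float
    ppm: float
    rpkm: float
    length: int


def _models_by_id(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    return {m.transcript_id: m for m in models}


def quantify(
    reads: ReadSet,
    models: Sequence[TranscriptModel],
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> list[AbundanceRecord]:
    """Per-transcript, per-region abundance (raw count, ppm, rpkm).

    Reads must be in transcript space with a normalization denominator set.
    Reads on transcripts absent from ``models`` are skipped with a log line.
    Records are emitted for every coding model and every nonzero-length
    region plus the whole transcript, including zero-read ones.
    """
    if reads.norm_denominator is None:
        raise NormalizationError("quantify requires a normalized read set")
    by_id = _models_by_id(models)
    tallies: dict[str, dict[str, float]] = {
        tid: {region: 0.0 for region in REGIONS} for tid, m in by_id.items() if m.is_coding
    }
    n_skipped = 0
    for r in reads.records:
        model = by_id.get(r.ref_id)
        if model is None or not model.is_coding:
            n_skipped += 1
            continue
        if not 0 <= r.five_prime < model.spliced_length:
            n_skipped += 1
            continue
        tallies[r.ref_id][model.region_of(r.five_prime)] += r.count
    if n_skipped:
        logger.info("quantify: skipped %d reads on unknown/non-coding transcripts", n_skipped)

    denom = reads.norm_denominator
    out = []
    for tid, per_region in tallies.items():
        model = by_id[tid]
        whole = sum(per_region.values())
        for region in (*REGIONS, "whole"):
            length = model.region_length(region)
            if length == 0:
                continue
            raw = whole if region == "whole" else per_region[region]
            ppm = raw / denom * 1e6
            rpkm = (raw + pseudocount) / ((length / 1000.0) * (denom / 1e6))
            out.append(AbundanceRecord(tid, region, raw, ppm, rpkm, length))
    return out


def abundance_frame(records: Sequence[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "region": r.region,
                "raw_count": r.raw_count,
                "ppm": r.ppm,
                "rpkm": r.rpkm,
                "length": r.length,
            }
            for r in records
        ]
    )


def exon_intron_enrichment(
    genome_reads: ReadSet,
    models: Sequence[TranscriptModel],
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> dict:
    """Length-corrected exonic vs intronic read density over primary transcripts.

    Densities are computed over the per-chromosome union of each compartment;
    models without introns are excluded (logged).  With zero intron reads the
    fold change uses a ``pseudocount`` read and is flagged.
    """
    exon_iv: dict[str, list[tuple[int, int]]] = {}
    intron_iv: dict[str, list[tuple[int, int]]] = {}
    n_used = 0
    for m in models:
        if not m.introns:
            logger.info("exon_intron_enrichment: %s has no introns; excluded", m.transcript_id)
            continue
        n_used += 1
        exon_iv.setdefault(m.chrom, []).extend((ex.start, ex.end) for ex in m.exons)
        intron_iv.setdefault(m.chrom, []).extend((iv.start, iv.end) for iv in m.introns)
    if n_used == 0:
        raise ConfigError("no model with introns available")
    exon_merged = {c: merge_intervals(v) for c, v in exon_iv.items()}
    intron_merged = {c: merge_intervals(v) for c, v in intron_iv.items()}
    exon_nt = sum(intervals_total(v) for v in exon_merged.values())
    intron_nt = sum(intervals_total(v) for v in intron_merged.values())

    exon_reads = intron_reads = 0.0
    for r in genome_reads.records:
        if r.ref_id in exon_merged and point_in_intervals(exon_merged[r.ref_id], r.five_prime):
            exon_reads += r.count
        elif r.ref_id in intron_merged and point_in_intervals(intron_merged[r.ref_id], r.five_prime):
            intron_reads += r.count
    total = exon_reads + intron_reads
    flagged = intron_reads == 0
    intron_eff = intron_reads if intron_reads > 0 else pseudocount
    fold = (exon_reads / exon_nt) / (intron_eff / intron_nt)
    return {
        "frac_exon": exon_reads / total if total else float("nan"),
        "frac_intron": intron_reads / total if total else float("nan"),
        "fold_enrichment": fold,
        "exon_nt": exon_nt,
        "intron_nt": intron_nt,
        "exon_reads": exon_reads,
        "intron_reads": intron_reads,
        "pseudocount_flagged": flagged,
    }


@dataclass
class JunctionAssignment:
    counts: dict[str, float]  # junction_id -> count-weighted assigned reads
    offsets: dict[str, list[int]]  # junction_id -> match offsets relative to boundary
    n_unassigned: int
    multi_junction_reads: list[int] = field(default_factory=list)  # record indices


def _occurrences(needle: str, haystack: str, max_mismatch: int = 0) -> list[int]:
    if max_mismatch == 0:
        out, start = [], haystack.find(needle)
        while start != -1:
            out.append(start)
            start = haystack.find(needle, start + 1)
        return out
    out = []
    for off in range(len(haystack) - len(needle) + 1):
        mism = sum(1 for x, y in zip(needle, haystack[off : off + len(needle)]) if x != y)
        if mism <= max_mismatch:
            out.append(off)
    return out


def junction_read_assignment(
    reads: ReadSet,
    junctions: Sequence[JunctionSequence],
    max_mismatch: int = 0,
) -> JunctionAssignment:
    """Assign genome-unmapped reads to exon-exon junction sequences.

    A read is assigned iff its sequence occurs in a junction sequence at an
    offset spanning the boundary by >= 1 nt on both sides.  Reads matching
    several junctions count once per distinct junction and are flagged.
    """
    counts = {j.junction_id: 0.0 for j in junctions}
    offsets: dict[str, list[int]] = {j.junction_id: [] for j in junctions}
    multi, n_unassigned = [], 0
    for idx, r in enumerate(reads.records):
        if not r.sequence:
            n_unassigned += 1
            continue
        seq = r.sequence.upper()
        hits = []
        for j in junctions:
            for off in _occurrences(seq, j.sequence.upper(), max_mismatch):
                if off < j.boundary and off + len(seq) > j.boundary:
                    hits.append((j.junction_id, off))
                    break  # one hit per junction
        if not hits:
            n_unassigned += 1
            continue
        if len(hits) > 1:
            multi.append(idx)
        for jid, off in hits:
            counts[jid] += r.count
            offsets[jid].append(off - junctions[[j.junction_id for j in junctions].index(jid)].boundary)
    return JunctionAssignment(counts, offsets, n_unassigned, multi)


@dataclass
class MetageneProfile:
    values: np.ndarray  # trimmed-mean coverage over the concatenated grid
    region_bins: dict[str, int]  # bins (median lengths) per region
    n_transcripts: int
    trim: float

    @property
    def boundaries(self) -> tuple[int, int]:
        """(end of 5'UTR bins, end of ORF bins) on the concatenated axis."""
        b1 = self.region_bins[UTR5]
        return b1, b1 + self.region_bins[ORF]

    def to_frame(self) -> pd.DataFrame:
        regions = []
        for region in REGIONS:
            regions.extend([region] * self.region_bins[region])
        return pd.DataFrame({"bin": np.arange(self.values.size), "region": regions, "value": self.values})


def _rescale(vec: np.ndarray, n_bins: int) -> np.ndarray:
    if n_bins == 0:
        return np.zeros(0)
    if vec.size == 0:
        return np.zeros(n_bins)
    if vec.size == 1:
        return np.full(n_bins, float(vec[0]))
    src = np.linspace(0.0, 1.0, vec.size)
    dst = np.linspace(0.0, 1.0, n_bins)
    return np.interp(dst, src, vec)


def metagene(
    sets: Sequence[ReadSet],
    models: Sequence[TranscriptModel],
    trim: float = 0.10,
) -> MetageneProfile:
    """Length-rescaled, 10%-trimmed-mean 5'-end coverage across a cohort.

    Each transcript's per-region per-nt 5'-end coverage is linearly rescaled
    to the cohort's median region length; the per-bin value is the mean after
    dropping the top and bottom ``trim`` fraction of transcripts.
    """
    if not 0 <= trim < 0.5:
        raise ConfigError("trim must be in [0, 0.5)")
    coding = [m for m in models if m.is_coding]
    if not coding:
        raise ConfigError("metagene requires at least one coding transcript")
    medians = {
        UTR5: int(round(float(np.median([m.utr5_length for m in coding])))),
        ORF: int(round(float(np.median([m.orf_length for m in coding])))),
        UTR3: int(round(float(np.median([m.utr3_length for m in coding])))),
    }
    by_id = _models_by_id(coding)
    coverage = {tid: np.zeros(m.spliced_length) for tid, m in by_id.items()}
    for rs in sets:
        for r in rs.records:
            cov = coverage.get(r.ref_id)
            if cov is not None and 0 <= r.five_prime < cov.size:
                cov[r.five_prime] += r.count
    rows = []
    for tid, m in by_id.items():
        cov = coverage[tid]
        parts = [
            _rescale(cov[: m.cds_start_t], medians[UTR5]),
            _rescale(cov[m.cds_start_t : m.cds_end_t], medians[ORF]),
            _rescale(cov[m.cds_end_t :], medians[UTR3]),
        ]
        rows.append(np.concatenate(parts))
    stack = np.vstack(rows)
    values = scipy.stats.trim_mean(stack, trim, axis=0) if trim > 0 else stack.mean(axis=0)
    return MetageneProfile(np.asarray(values, dtype=float), medians, len(rows), trim)


def region_ratio(
    numerator: ReadSet,
    denominator: ReadSet,
    models: Sequence[TranscriptModel],
    region: str,
    pseudocount: float = RPKM_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-transcript ppm ratio of two libraries within one region.

    ratio = (ppm_num + pc) / (ppm_den + pc); log2 is reported alongside.
    Transcripts lacking the region are skipped with a log line.
    """
    if region not in REGIONS and region != "whole":
        raise ConfigError(f"unknown region {region!r}")
    num_records = {(r.transcript_id, r.region): r for r in quantify(numerator, models)}
    den_records = {(r.transcript_id, r.region): r for r in quantify(denominator, models)}
    rows = []
    for m in models:
        if not m.is_coding:
            continue
        if m.region_length(region) == 0:
            logger.info("region_ratio: %s lacks region %s; skipped", m.transcript_id, region)
            continue
        num = num_records.get((m.transcript_id, region))
        den = den_records.get((m.transcript_id, region))
        ppm_n = num.ppm if num else 0.0
        ppm_d = den.ppm if den else 0.0
        ratio = (ppm_n + pseudocount) / (ppm_d + pseudocount)
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "region": region,
                "ppm_num": ppm_n,
                "ppm_den": ppm_d,
                "ratio": ratio,
                "log2_ratio": float(np.log2(ratio)),
                "pseudocount_flagged": ppm_d == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TEContentRecord:
    transcript_id: str
    compartment: str  # exon / intron
    sense_fraction: float
    antisense_fraction: float


def _overlap_nt(
    compartment: Sequence[GenomicInterval], tes: Sequence[tuple[int, int]]
) -> int:
    merged = merge_intervals(tes)
    total = 0
    for iv in compartment:
        for s, e in merged:
            lo, hi = max(iv.start, s), min(iv.end, e)
            if lo < hi:
                total += hi - lo
    return total


def te_content(
    models: Sequence[TranscriptModel],
    te_intervals: Sequence[GenomicInterval],
) -> list[TEContentRecord]:
    """Fraction of exonic and intronic nucleotides covered by sense/antisense TEs.

    Sense means the TE annotation strand equals the transcript strand.
    Overlapping same-strand TE annotations are merged before counting.
    """
    by_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for te in te_intervals:
        by_chrom.setdefault((te.chrom, te.strand), []).append((te.start, te.end))
    out = []
    for m in models:
        sense_strand = m.strand
        anti_strand = "-" if m.strand == "+" else "+"
        for compartment, intervals in (("exon", m.exons), ("intron", m.introns)):
            comp_nt = sum(len(iv) for iv in intervals)
            if comp_nt == 0:
                continue
            sense_nt = _overlap_nt(intervals, by_chrom.get((m.chrom, sense_strand), []))
            anti_nt = _overlap_nt(intervals, by_chrom.get((m.chrom, anti_strand), []))
            out.append(
                TEContentRecord(
                    m.transcript_id, compartment, sense_nt / comp_nt, anti_nt / comp_nt
                )
            )
    return out
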