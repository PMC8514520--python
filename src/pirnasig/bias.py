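"""Position-specific nucleotide composition at read 5' ends and
first-nucleotide-matched simulated control reads.

Information content per position is 2 - H bits with H the Shannon entropy
over {A, C, G, U} (T is reported as U).  The u1 position (1 nt upstream of
the 5' end) is taken from the precursor sequence, never from the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptySetError, StratumExhaustedError
from .transcripts import ReadRecord, ReadSet

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@dataclass
class BiasMatrix:
    """Per-position nucleotide counts, frequencies, and information content."""

    positions: list[str]  # ["u1", "p1", ..., "pK"]
    counts: np.ndarray  # (n_positions, 4), count-weighted
    n_skipped: int = 0

    @property
    def freq(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def info_bits(self) -> np.ndarray:
        freq = self.freq
        out = np.full(len(self.positions), np.nan)
        for i, row in enumerate(freq):
            if np.any(np.isnan(row)):
                continue
            p = row[row > 0]
            entropy = float(-(p * np.log2(p)).sum())
            out[i] = 2.0 - entropy
        return out

    def info_at(self, position: str) -> float:
        return float(self.info_bits[self.positions.index(position)])

    def freq_at(self, position: str, nucleotide: str) -> float:
        i = self.positions.index(position)
        return float(self.freq[i, _NT_INDEX[nucleotide.upper()]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(NUCLEOTIDES))
        df.insert(0, "position", self.positions)
        df["bits"] = self.info_bits
        return df


def nucleotide_bias(
    reads: ReadSet,
    precursors: Mapping[str, str] | None = None,
    k: int = 10,
) -> BiasMatrix:
    """Count-weighted nucleotide composition at 1 nt upstream (u1) and read
    positions p1..pK.

    Reads without a sequence are sliced from ``precursors`` when possible,
    otherwise skipped (tallied).  u1 is always read from the precursor; reads
    starting at precursor position 0 contribute no u1 observation.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    positions = ["u1"] + [f"p{i}" for i in range(1, k + 1)]
    counts = np.zeros((k + 1, 4))
    n_skipped = 0
    n_used = 0
    for r in reads.records:
        seq = r.sequence
        precursor = precursors.get(r.ref_id) if precursors else None
        if seq is None and precursor is not None and r.five_prime + r.length <= len(precursor):
            seq = precursor[r.five_prime : r.five_prime + r.length]
        if seq is None:
            n_skipped += 1
            continue
        n_used += 1
        seq = seq.upper()
        if precursor is not None and r.five_prime > 0:
            up = precursor[r.five_prime - 1].upper()
            if up in _NT_INDEX:
                counts[0, _NT_INDEX[up]] += r.count
        for i in range(min(k, len(seq))):
            base = seq[i]
            if base in _NT_INDEX:
                counts[i + 1, _NT_INDEX[base]] += r.count
    if n_used == 0:
        raise EmptySetError("no read carried or could be assigned a sequence")
    if n_skipped:
        logger.info("nucleotide_bias: skipped %d reads without sequence", n_skipped)
    return BiasMatrix(positions, counts, n_skipped)


def largest_remainder_allocation(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer allocation of n among categories by the largest-remainder rule.

    Ties in fractional part are broken by category order in ``proportions``.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    total = sum(proportions.values())
    if total <= 0:
        raise ConfigError("proportions must sum to a positive value")
    keys = list(proportions)
    quotas = {key: n * proportions[key] / total for key in keys}
    alloc = {key: int(np.floor(quotas[key])) for key in keys}
    remainder = n - sum(alloc.values())
    order = sorted(range(len(keys)), key=lambda i: (-(quotas[keys[i]] - alloc[keys[i]]), i))
    for i in order[:remainder]:
        alloc[keys[i]] += 1
    return alloc


@dataclass
class ControlReadPool:
    """First-nucleotide-matched reads sampled from the precursor k-mer pool."""

    reads: ReadSet
    allocation: dict[str, int]
    read_length: int
    seed: int | None
    source_ids: list[str] = field(default_factory=list)


def first_nt_composition(reads: ReadSet) -> dict[str, float]:
    """Count-weighted first-nucleotide proportions of a read set (T as U)."""
    counts = {nt: 0.0 for nt in NUCLEOTIDES}
    total = 0.0
    for r in reads.records:
        if not r.sequence:
            continue
        base = r.sequence[0].upper()
        if base in _NT_INDEX:
            counts[NUCLEOTIDES[_NT_INDEX[base]]] += r.count
            total += r.count
    if total == 0:
        raise EmptySetError("no read carries a usable first nucleotide")
    return {nt: c / total for nt, c in counts.items()}


def simulate_control_reads(
    precursors: Mapping[str, str],
    real: ReadSet,
    n: int,
    read_length: int = 28,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ControlReadPool:
    """Sample sliding-window k-mers from precursors matching the real reads'
    first-nucleotide composition.

    The pool holds every substring of ``read_length`` at 1-nt steps.  The n
    samples are stratified by first nucleotide with exact largest-remainder
    allocation to the real composition, drawn uniformly with replacement
    within each stratum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for pid, seq in precursors.items():
        if len(seq) < read_length:
            raise ConfigError(
                f"precursor {pid!r} ({len(seq)} nt) shorter than read_length {read_length}"
            )
    strata: dict[str, list[tuple[str, int]]] = {nt: [] for nt in NUCLEOTIDES}
    for pid, seq in precursors.items():
        upper = seq.upper()
        for off in range(len(upper) - read_length + 1):
            base = upper[off]
            if base in _NT_INDEX:
                strata[NUCLEOTIDES[_NT_INDEX[base]]].append((pid, off))
    composition = first_nt_composition(real)
    allocation = largest_remainder_allocation(n, composition)
    records = []
    for nt in NUCLEOTIDES:
        quota = allocation[nt]
        if quota == 0:
            continue
        pool = strata[nt]
        if not pool:
            raise StratumExhaustedError(nt)
        picks = rng.integers(0, len(pool), size=quota)
        for i in picks:
            pid, off = pool[int(i)]
            records.append(
                ReadRecord(
                    ref_id=pid,
                    strand="+",
                    five_prime=off,
                    length=read_length,
                    count=1,
                    sequence=precursors[pid][off : off + read_length].upper(),
                    chemistry="unknown",
                    space="transcript",
                )
            )
    reads = ReadSet(label=f"{real.label}-controls", records=records, category="other")
    return ControlReadPool(reads, allocation, read_length, seed, sorted(precursors))
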